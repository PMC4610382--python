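import numpy as np
import pytest
from hypothesis import settings

import refugesim as rs

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def half_landscape():
    """Half the landscape planted as refuge."""
    return rs.Landscape.exposed_refuge(0.5)


@pytest.fixture
def no_tradeoff():
    """Idealized cost-free resistance: susceptible dies when exposed only."""
    return rs.make_preset_topology("no_tradeoff")


@pytest.fixture
def strong_tradeoff():
    """Idealized strong symmetric trade-off: each homozygote survives in
    exactly one region."""
    return rs.make_preset_topology("strong_tradeoff")


@pytest.fixture
def rng():
    return np.random.default_rng(20150813)
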