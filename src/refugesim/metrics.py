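"""Landscape-wide mortality as a function of the resistant fraction, and
the linear mortality-to-yield mapping.

This is the headline calculus of the refuge-strategy trade-off argument:
sum survival over genotype frequencies and habitat area fractions, and ask
how much mortality the strategy still delivers once resistance has spread.
Under the idealized no-trade-off topology with half the landscape as
refuge, mortality collapses from 50% to 0 as the resistant fraction goes
from 0 to 1; under the idealized strong trade-off it stays pinned at 50%
no matter how far adaptation proceeds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import Landscape, TradeoffTopology, hardy_weinberg

__all__ = ["YieldModel", "landscape_mortality", "mortality_curve",
           "yield_index", "plot_mortality_curves"]


@dataclass(frozen=True)
class YieldModel:
    """Linear mapping from pest mortality to a [0, 1] yield index.

    ``yield = 1 - max_loss * (1 - M)``: yield loss is proportional to pest
    survivorship, with ``max_loss`` the proportional loss when no pests die
    at all.  The default 0.36 is the upper bound of the commonly cited
    9-36% range of crop-yield threat from animal pests.  Compensatory
    (nonlinear) yield responses are deliberately out of scope; the model is
    pluggable but ships linear only.
    """

    max_loss: float = 0.36

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_loss <= 1.0:
            raise ValueError("max_loss must be in [0, 1]")


def yield_index(M: float, ym: YieldModel | None = None) -> float:
    """Yield index in [0, 1] for landscape mortality ``M``."""
    if not 0.0 <= M <= 1.0:
        raise ValueError("mortality must be in [0, 1]")
    ym = ym if ym is not None else YieldModel()
    return 1.0 - ym.max_loss * (1.0 - M)


def _resistant_freqs(phi: float, allele_frequency: bool) -> np.ndarray:
    if not 0.0 <= phi <= 1.0:
        raise ValueError("resistant fraction must be in [0, 1]")
    if allele_frequency:
        return hardy_weinberg(phi)
    # Genotype-level interpretation: phi of the population is the resistant
    # homozygote, the remainder susceptible homozygote.
    return np.array([phi, 0.0, 1.0 - phi])


def landscape_mortality(phi: float, topology: TradeoffTopology,
                        landscape: Landscape, h_dom: float = 0.0, *,
                        allele_frequency: bool = False) -> float:
    """Landscape-wide mortality at resistant fraction ``phi``.

    ``M = 1 - sum_g freq_g sum_k f_k s_g,k`` -- one minus mean survival
    averaged over genotype frequencies and habitat area fractions.

    By default ``phi`` is the fraction of the population carrying the
    resistant genotype, with the remainder susceptible; pass
    ``allele_frequency=True`` to interpret ``phi`` as a resistance allele
    frequency expanded to Hardy-Weinberg genotype frequencies instead
    (the interpretation needed when coupling to allele-frequency
    trajectories).
    """
    topology.check_compatible(landscape)
    freqs = _resistant_freqs(phi, allele_frequency)
    w = topology.matrix(h_dom) @ landscape.fractions
    return float(1.0 - freqs @ w)


def mortality_curve(topology: TradeoffTopology, landscape: Landscape,
                    h_dom: float = 0.0, grid: Sequence[float] = (), *,
                    allele_frequency: bool = False) -> pd.DataFrame:
    """Mortality at each resistant fraction in ``grid``.

    Returns a tidy ``(phi, mortality)`` table — the surface plotted when
    comparing trade-off topologies' robustness to adaptation.
    """
    rows = [(float(phi),
             landscape_mortality(phi, topology, landscape, h_dom,
                                 allele_frequency=allele_frequency))
            for phi in grid]
    return pd.DataFrame(rows, columns=["phi", "mortality"])


def plot_mortality_curves(curves: dict[str, pd.DataFrame], path=None):
    """Optional side-by-side comparison figure of mortality curves.

    ``curves`` maps panel labels to ``mortality_curve`` outputs.  Requires
    matplotlib; the CSV tables, not figures, are the package's contract.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(curves), figsize=(4 * len(curves), 3.2),
                             sharey=True, squeeze=False)
    for ax, (label, df) in zip(axes[0], curves.items()):
        ax.plot(df["phi"], df["mortality"])
        ax.set_xlabel("resistant fraction")
        ax.set_title(label)
        ax.set_ylim(-0.02, 1.02)
    axes[0][0].set_ylabel("landscape mortality")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
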