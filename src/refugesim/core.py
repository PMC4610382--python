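"""Shared state types for refuge-strategy selection models.

The landscape is a set of labelled habitats (canonically an "exposed"
region treated with a control agent and an untreated "refuge") with fixed
area fractions.  A fitness trade-off topology is the genotype-by-habitat
matrix of survival probabilities; the discrete-trait machinery fixes the
genotype order as (RR, RS, SS) where R is the resistance allele.  Survival
(not mortality) is the stored quantity throughout; mortality = 1 - survival.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GENOTYPES",
    "Landscape",
    "TradeoffTopology",
    "DiscretePopulation",
    "QuantPopulation",
    "Trajectory",
    "PopulationExtinct",
    "hardy_weinberg",
    "make_preset_topology",
    "PRESET_TOPOLOGIES",
]

#: Fixed genotype row order for all 3-row survival matrices.
GENOTYPES = ("RR", "RS", "SS")

_SUM_TOL = 1e-12


class PopulationExtinct(Exception):
    """Raised when every individual dies in one round of selection.

    Idealized 0/1 survival matrices can legitimately kill the whole
    population (e.g. a single exposed habitat with all-susceptible pests);
    this is a terminal model state, not a numerical bug, so drivers catch
    it and flag the trajectory rather than crashing.
    """


def hardy_weinberg(p: float) -> np.ndarray:
    """Genotype frequencies (RR, RS, SS) for allele frequency ``p`` under panmixia.

    Parameters
    ----------
    p
        Frequency of the resistance allele, in [0, 1].

    Returns
    -------
    numpy.ndarray
        ``(p**2, 2*p*(1-p), (1-p)**2)``, ordered as :data:`GENOTYPES`.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"allele frequency must be in [0, 1], got {p}")
    q = 1.0 - p
    return np.array([p * p, 2.0 * p * q, q * q])


@dataclass(frozen=True)
class Landscape:
    """Labelled habitats with fixed area fractions.

    Attributes
    ----------
    habitat_names
        Ordered habitat labels; at least two.
    fractions
        Area proportion of each habitat; entries in [0, 1] summing to 1.
    """

    habitat_names: tuple[str, ...]
    fractions: np.ndarray

    def __post_init__(self) -> None:
        names = tuple(self.habitat_names)
        fr = np.asarray(self.fractions, dtype=float)
        object.__setattr__(self, "habitat_names", names)
        object.__setattr__(self, "fractions", fr)
        if len(names) < 2:
            raise ValueError("a landscape needs at least 2 habitats")
        if fr.shape != (len(names),):
            raise ValueError("fractions must match habitat_names in length")
        if np.any(fr < 0.0) or np.any(fr > 1.0):
            raise ValueError("area fractions must lie in [0, 1]")
        if abs(fr.sum() - 1.0) > _SUM_TOL:
            raise ValueError(f"area fractions must sum to 1, got {fr.sum()!r}")

    @property
    def n_habitats(self) -> int:
        return len(self.habitat_names)

    @classmethod
    def exposed_refuge(cls, refuge_fraction: float) -> "Landscape":
        """Two-habitat landscape with refuge area fraction ``r``."""
        if not 0.0 <= refuge_fraction <= 1.0:
            raise ValueError("refuge fraction must be in [0, 1]")
        return cls(("exposed", "refuge"),
                   np.array([1.0 - refuge_fraction, refuge_fraction]))

    @property
    def refuge_fraction(self) -> float:
        """Area fraction of the habitat named 'refuge' (0 if none)."""
        if "refuge" in self.habitat_names:
            return float(self.fractions[self.habitat_names.index("refuge")])
        return 0.0

    def to_dict(self) -> dict:
        return {"habitats": list(self.habitat_names),
                "fractions": [float(f) for f in self.fractions]}

    @classmethod
    def from_dict(cls, d: Mapping) -> "Landscape":
        return cls(tuple(d["habitats"]), np.asarray(d["fractions"], dtype=float))


@dataclass(frozen=True)
class TradeoffTopology:
    """Genotype-by-habitat survival matrix.

    The two homozygote rows are always explicit.  The heterozygote row may
    be left implicit (``survival_rs is None``), in which case it is resolved
    at query time by per-habitat linear interpolation with a dominance
    coefficient: ``s_RS,k = h_dom * s_RR,k + (1 - h_dom) * s_SS,k``, so that
    h_dom = 0 encodes functionally recessive resistance (the "high dose"
    goal) and h_dom = 1 fully dominant resistance.

    Topologies need not be symmetric: real fitness trade-offs rarely are,
    and asymmetric matrices are first-class citizens beyond the idealized
    presets.
    """

    survival_rr: np.ndarray
    survival_ss: np.ndarray
    survival_rs: np.ndarray | None = None
    habitat_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        rr = np.asarray(self.survival_rr, dtype=float)
        ss = np.asarray(self.survival_ss, dtype=float)
        object.__setattr__(self, "survival_rr", rr)
        object.__setattr__(self, "survival_ss", ss)
        if rr.ndim != 1 or ss.shape != rr.shape:
            raise ValueError("homozygote survival rows must be 1-D and equal length")
        rows = [rr, ss]
        if self.survival_rs is not None:
            rs = np.asarray(self.survival_rs, dtype=float)
            object.__setattr__(self, "survival_rs", rs)
            if rs.shape != rr.shape:
                raise ValueError("RS survival row must match homozygote rows")
            rows.append(rs)
        for row in rows:
            if np.any(row < 0.0) or np.any(row > 1.0):
                raise ValueError("survival probabilities must lie in [0, 1]")
        if self.habitat_names is not None:
            names = tuple(self.habitat_names)
            object.__setattr__(self, "habitat_names", names)
            if len(names) != rr.size:
                raise ValueError("habitat_names length must match survival columns")

    @property
    def n_habitats(self) -> int:
        return int(self.survival_rr.size)

    def check_compatible(self, landscape: Landscape) -> None:
        if self.n_habitats != landscape.n_habitats:
            raise ValueError(
                f"topology has {self.n_habitats} habitat columns but landscape "
                f"has {landscape.n_habitats} habitats")

    def matrix(self, h_dom: float = 0.0) -> np.ndarray:
        """Resolved 3-by-K survival matrix in (RR, RS, SS) row order."""
        if not 0.0 <= h_dom <= 1.0:
            raise ValueError("dominance coefficient must be in [0, 1]")
        if self.survival_rs is not None:
            rs = self.survival_rs
        else:
            rs = h_dom * self.survival_rr + (1.0 - h_dom) * self.survival_ss
        return np.vstack([self.survival_rr, rs, self.survival_ss])

    def to_dict(self) -> dict:
        d: dict = {"survival": {
            "RR": [float(s) for s in self.survival_rr],
            "RS": ("dominance" if self.survival_rs is None
                   else [float(s) for s in self.survival_rs]),
            "SS": [float(s) for s in self.survival_ss],
        }}
        if self.habitat_names is not None:
            d["habitats"] = list(self.habitat_names)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "TradeoffTopology":
        surv = d["survival"]
        rs = surv.get("RS", "dominance")
        return cls(
            survival_rr=np.asarray(surv["RR"], dtype=float),
            survival_ss=np.asarray(surv["SS"], dtype=float),
            survival_rs=None if rs == "dominance" else np.asarray(rs, dtype=float),
            habitat_names=tuple(d["habitats"]) if "habitats" in d else None,
        )


#: Names accepted by :func:`make_preset_topology`.
PRESET_TOPOLOGIES = ("no_tradeoff", "strong_tradeoff")


def make_preset_topology(name: str, s_high: float = 1.0,
                         s_low: float = 0.0) -> TradeoffTopology:
    """Idealized two-habitat trade-off topologies over (exposed, refuge).

    ``no_tradeoff``: susceptible pests die when exposed but thrive in the
    refuge, while resistant pests thrive everywhere (resistance is cost
    free).  ``strong_tradeoff``: each homozygote thrives in exactly one
    region -- resistant pests survive exposure but die in the refuge, so
    neither genotype escapes mortality anywhere in the landscape.

    Parameters
    ----------
    name
        One of :data:`PRESET_TOPOLOGIES`.
    s_high, s_low
        Survival in the favourable / unfavourable region.  The defaults
        (1, 0) are the idealized complete-versus-zero-mortality extremes;
        require ``0 <= s_low < s_high <= 1``.
    """
    if name not in PRESET_TOPOLOGIES:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: {', '.join(PRESET_TOPOLOGIES)}")
    if not 0.0 <= s_low <= s_high <= 1.0:
        raise ValueError("require 0 <= s_low <= s_high <= 1")
    habitats = ("exposed", "refuge")
    ss = np.array([s_low, s_high])
    if name == "no_tradeoff":
        rr = np.array([s_high, s_high])
    else:
        rr = np.array([s_high, s_low])
    return TradeoffTopology(survival_rr=rr, survival_ss=ss,
                            habitat_names=habitats)


@dataclass(frozen=True)
class DiscretePopulation:
    """One-locus two-allele population state under panmixia.

    ``p`` is the resistance allele frequency; genotype frequencies are
    always the Hardy-Weinberg triple derived from ``p`` (panmictic mating
    across the whole landscape every generation).  ``h_dom`` is the
    dominance coefficient of resistance used to resolve heterozygote
    survival when the topology leaves the RS row implicit.
    """

    p: float
    h_dom: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("allele frequency must be in [0, 1]")
        if not 0.0 <= self.h_dom <= 1.0:
            raise ValueError("dominance coefficient must be in [0, 1]")

    @property
    def genotype_freqs(self) -> np.ndarray:
        """Hardy-Weinberg genotype frequencies (RR, RS, SS)."""
        return hardy_weinberg(self.p)


@dataclass(frozen=True)
class QuantPopulation:
    """Quantitative-trait population state.

    Attributes
    ----------
    z_bar
        Mean trait value (trait units).
    sigma2_P
        Phenotypic variance (trait units squared); strictly positive and
        held constant across generations.
    h2
        Narrow-sense heritability in [0, 1].
    """

    z_bar: float
    sigma2_P: float
    h2: float

    def __post_init__(self) -> None:
        if not self.sigma2_P > 0.0:
            raise ValueError("phenotypic variance must be positive")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("heritability must be in [0, 1]")


class Trajectory:
    """Per-generation record of a model run.

    One record per generation, indices strictly increasing from 0.  Every
    record carries the landscape-wide mortality of that generation's
    pre-selection zygote pool and satisfies
    ``landscape_mortality == 1 - mean_fitness``.
    """

    def __init__(self) -> None:
        self._records: list[dict] = []
        self.extinct: bool = False
        self.extinct_generation: int | None = None

    def append(self, **record) -> None:
        gen = record["generation"]
        if self._records and gen != self._records[-1]["generation"] + 1:
            raise ValueError("generation indices must increase by 1")
        if not self._records and gen != 0:
            raise ValueError("trajectories start at generation 0")
        self._records.append(record)

    def mark_extinct(self, generation: int) -> None:
        self.extinct = True
        self.extinct_generation = generation

    def __len__(self) -> int:
        return len(self._records)

    def __getitem__(self, i: int) -> dict:
        return self._records[i]

    def series(self, name: str) -> np.ndarray:
        """Column ``name`` across generations as an array."""
        return np.array([r[name] for r in self._records])

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-generation DataFrame."""
        return pd.DataFrame(self._records)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)
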