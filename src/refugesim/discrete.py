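"""Deterministic one-locus two-allele selection recursion across a
refuge-structured landscape.

Life cycle each generation: zygotes form at Hardy-Weinberg proportions,
disperse over habitats in proportion to area (complete panmixia of
genotypes with respect to crop regions), undergo habitat-specific
viability selection, and then mate in a single landscape-wide pool.  Two
classic population-regulation modes are provided because they diverge in
multi-habitat landscapes:

* ``hard``  -- survivors from all habitats pool directly, so each habitat's
  contribution to the mating pool scales with within-habitat survival;
* ``soft``  -- each habitat contributes offspring in proportion to its area
  regardless of how many died there (the Levene multiple-niche model).

Selection is the only force here: no mutation, no drift, no migration
between farms.  The finite-population (drift) counterpart lives in
:mod:`refugesim.synthetic`.
"""

from __future__ import annotations

import enum

import numpy as np

from .core import (DiscretePopulation, Landscape, PopulationExtinct,
                   Trajectory, TradeoffTopology, hardy_weinberg)
from .metrics import YieldModel, yield_index

__all__ = ["SelectionRegime", "genotype_fitness", "step", "step_general",
           "iterate", "time_to_threshold"]


class SelectionRegime(str, enum.Enum):
    """How population regulation interacts with habitats."""
    HARD = "hard"
    SOFT = "soft"


def genotype_fitness(topology: TradeoffTopology, landscape: Landscape,
                     h_dom: float = 0.0,
                     regime: SelectionRegime = SelectionRegime.HARD):
    """Per-genotype fitness under area-proportional habitat exposure.

    In hard mode returns the length-3 vector of area-weighted mean
    survivals ``w_g = sum_k f_k * s_g,k`` (rows RR, RS, SS).  In soft mode
    the habitats are not pooled, so the resolved 3-by-K survival matrix is
    returned for the Levene-style update.
    """
    topology.check_compatible(landscape)
    S = topology.matrix(h_dom)
    if SelectionRegime(regime) is SelectionRegime.SOFT:
        return S
    return S @ landscape.fractions


def step_general(p: float, S: np.ndarray, landscape: Landscape,
                 regime: SelectionRegime = SelectionRegime.HARD,
                 exposure: np.ndarray | None = None) -> float:
    """One generation of the recursion with an arbitrary exposure matrix.

    ``exposure[g, k]`` is the probability that a genotype-``g`` zygote
    develops in habitat ``k`` (rows sum to 1).  Under panmixia this is the
    area fractions for every genotype; habitat choice replaces it with a
    genotype-dependent occupancy (see :mod:`refugesim.extensions`).

    Hard mode: ``p' = (p^2 w_RR + p(1-p) w_RS) / w_bar`` with
    ``w_g = sum_k exposure[g,k] s_g,k``.  Soft mode: within-habitat
    post-selection allele frequencies are averaged with the habitat area
    weights; habitats where everyone died contribute nothing and the
    weights renormalize over the survivors' habitats.

    Raises :class:`~refugesim.core.PopulationExtinct` if nobody survives.
    """
    freqs = hardy_weinberg(p)
    if exposure is None:
        exposure = np.tile(landscape.fractions, (3, 1))
    regime = SelectionRegime(regime)
    if regime is SelectionRegime.HARD:
        w = np.sum(exposure * S, axis=1)
        wbar = float(freqs @ w)
        if wbar <= 0.0:
            raise PopulationExtinct("mean fitness is zero: all genotypes dead")
        return float((freqs[0] * w[0] + 0.5 * freqs[1] * w[1]) / wbar)
    # Soft (Levene): survivors within habitat k have allele frequency
    # p'_k; habitat k contributes f_k of the next mating pool.
    cohort = freqs[:, None] * exposure            # genotype-by-habitat input
    survivors = cohort * S
    totals = survivors.sum(axis=0)
    live = totals > 0.0
    if not np.any(live):
        raise PopulationExtinct("mean fitness is zero in every habitat")
    p_k = (survivors[0, live] + 0.5 * survivors[1, live]) / totals[live]
    weights = landscape.fractions[live]
    return float(p_k @ weights / weights.sum())


def step(pop: DiscretePopulation, topology: TradeoffTopology,
         landscape: Landscape,
         regime: SelectionRegime = SelectionRegime.HARD) -> DiscretePopulation:
    """Advance the population one generation; offspring re-form at
    Hardy-Weinberg from the post-selection allele frequency (panmixia)."""
    topology.check_compatible(landscape)
    S = topology.matrix(pop.h_dom)
    p_next = step_general(pop.p, S, landscape, regime)
    return DiscretePopulation(p=min(max(p_next, 0.0), 1.0), h_dom=pop.h_dom)


def realized_mean_fitness(p: float, S: np.ndarray, landscape: Landscape,
                          exposure: np.ndarray | None = None) -> float:
    """Fraction of the zygote pool that survives selection this generation.

    This is the landscape-wide survival the strategy actually achieves --
    mortality is its complement -- and is independent of the regulation
    regime (regulation redistributes offspring, not deaths).
    """
    freqs = hardy_weinberg(p)
    if exposure is None:
        exposure = np.tile(landscape.fractions, (3, 1))
    return float(freqs @ np.sum(exposure * S, axis=1))


def iterate(pop: DiscretePopulation, topology: TradeoffTopology,
            landscape: Landscape,
            regime: SelectionRegime = SelectionRegime.HARD,
            generations: int = 0,
            yield_model: YieldModel | None = None) -> Trajectory:
    """Run the recursion, recording one trajectory row per generation.

    The trajectory has ``generations + 1`` rows (generation 0 is the
    initial state).  Each row's landscape mortality is computed on that
    generation's pre-selection zygote pool.  If selection kills everyone
    the trajectory is truncated and flagged extinct instead of raising.
    """
    if generations < 0:
        raise ValueError("generations must be >= 0")
    topology.check_compatible(landscape)
    ym = yield_model if yield_model is not None else YieldModel()
    S = topology.matrix(pop.h_dom)
    traj = Trajectory()
    p = pop.p
    for gen in range(generations + 1):
        freqs = hardy_weinberg(p)
        wbar = realized_mean_fitness(p, S, landscape)
        mortality = 1.0 - wbar
        traj.append(generation=gen, p=p,
                    freq_RR=freqs[0], freq_RS=freqs[1], freq_SS=freqs[2],
                    mean_fitness=wbar, landscape_mortality=mortality,
                    yield_index=yield_index(mortality, ym))
        if gen == generations:
            break
        try:
            p = step_general(p, S, landscape, regime)
        except PopulationExtinct:
            traj.mark_extinct(gen + 1)
            break
        p = min(max(p, 0.0), 1.0)
    return traj


def time_to_threshold(trajectory: Trajectory, threshold: float) -> int | None:
    """First generation at which the allele frequency reaches ``threshold``.

    Returns ``None`` if the trajectory never reaches it.  A summary for
    comparing the pace of resistance evolution across scenarios.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    hits = np.nonzero(trajectory.series("p") >= threshold)[0]
    if hits.size == 0:
        return None
    return int(trajectory[int(hits[0])]["generation"])
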