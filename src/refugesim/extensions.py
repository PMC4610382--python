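"""Habitat choice and phenotypic plasticity: mechanisms that flatten
fitness trade-offs.

The refuge-strategy mortality guarantee rests on panmixia -- genotypes
being distributed over crop regions in proportion to area, regardless of
where they would fare best.  Two compensatory mechanisms erode it:

* **Habitat choice** (``kappa``): individuals preferentially settle in the
  habitat where their genotype survives best, creating covariation between
  pest genotype and crop region.
* **Phenotypic plasticity** (``pi``): the resistance phenotype uncouples
  from genotype, with probability ``pi`` matching whatever the local
  habitat favours.

Both flatten the genotype-by-habitat survival contrast and so reduce
overall mortality; both apply to all genotypes symmetrically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (DiscretePopulation, Landscape, TradeoffTopology,
                   hardy_weinberg)
from .discrete import SelectionRegime, step_general

__all__ = ["HabitatChoice", "Plasticity", "dispersal_matrix",
           "effective_survival", "step_with_choice", "iterate_with_choice",
           "realized_mortality"]

_TIE_TOL = 1e-12


@dataclass(frozen=True)
class HabitatChoice:
    """Assortment strength ``kappa``: 0 = uniform (area-proportional)
    dispersal, 1 = every individual settles in its genotype's best habitat."""

    kappa: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError("kappa must be in [0, 1]")


@dataclass(frozen=True)
class Plasticity:
    """Probability ``pi`` that an individual expresses the locally optimal
    phenotype regardless of its genotype."""

    pi: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("pi must be in [0, 1]")


def dispersal_matrix(choice: HabitatChoice, topology: TradeoffTopology,
                     landscape: Landscape, h_dom: float = 0.0) -> np.ndarray:
    """Per-genotype habitat occupancy distribution (rows sum to 1).

    A linear mixture between area-proportional dispersal and a point mass
    on each genotype's best habitat:

        occupancy_g = (1 - kappa) * fractions + kappa * best_g

    where ``best_g`` puts all mass on ``argmax_k s_g,k``; ties (within
    1e-12 of the row maximum) split the mass proportionally to area among
    the tied habitats, so a flat topology reduces to panmixia for any
    kappa.
    """
    topology.check_compatible(landscape)
    S = topology.matrix(h_dom)
    f = landscape.fractions
    occupancy = np.empty_like(S)
    for g in range(S.shape[0]):
        tied = S[g] >= S[g].max() - _TIE_TOL
        best = np.where(tied, f, 0.0)
        best = best / best.sum()
        occupancy[g] = (1.0 - choice.kappa) * f + choice.kappa * best
    return occupancy


def effective_survival(plast: Plasticity,
                       topology: TradeoffTopology) -> TradeoffTopology:
    """Topology with plastic phenotype expression folded in.

    With probability ``pi`` an individual expresses the habitat-best
    phenotype, so every entry mixes toward its column maximum:
    ``s~_g,k = (1 - pi) * s_g,k + pi * max_g' s_g',k``.  No entry ever
    decreases.  An implicit (dominance-resolved) RS row stays implicit:
    linear interpolation between the modified homozygote rows equals the
    modification of the interpolated row, and the column maximum over all
    three rows equals the maximum over the homozygote rows.
    """
    rows = [topology.survival_rr, topology.survival_ss]
    if topology.survival_rs is not None:
        rows.append(topology.survival_rs)
    col_max = np.max(np.vstack(rows), axis=0)
    mix = lambda row: (1.0 - plast.pi) * row + plast.pi * col_max
    return TradeoffTopology(
        survival_rr=mix(topology.survival_rr),
        survival_ss=mix(topology.survival_ss),
        survival_rs=(None if topology.survival_rs is None
                     else mix(topology.survival_rs)),
        habitat_names=topology.habitat_names,
    )


def step_with_choice(pop: DiscretePopulation, topology: TradeoffTopology,
                     landscape: Landscape, choice: HabitatChoice,
                     regime: SelectionRegime = SelectionRegime.HARD
                     ) -> DiscretePopulation:
    """One generation of the discrete recursion with habitat choice:
    identical to the panmictic step except that each genotype's habitat
    exposure follows its occupancy distribution instead of area fractions."""
    topology.check_compatible(landscape)
    S = topology.matrix(pop.h_dom)
    occupancy = dispersal_matrix(choice, topology, landscape, pop.h_dom)
    p_next = step_general(pop.p, S, landscape, regime, exposure=occupancy)
    return DiscretePopulation(p=min(max(p_next, 0.0), 1.0), h_dom=pop.h_dom)


def iterate_with_choice(pop: DiscretePopulation, topology: TradeoffTopology,
                        landscape: Landscape, choice: HabitatChoice,
                        regime: SelectionRegime = SelectionRegime.HARD,
                        generations: int = 0,
                        yield_model=None):
    """Trajectory driver mirroring the panmictic ``iterate`` but with
    genotype-dependent habitat occupancy; per-generation mortality is the
    realized (occupancy-weighted) zygote mortality."""
    from .core import PopulationExtinct, Trajectory
    from .metrics import YieldModel, yield_index

    if generations < 0:
        raise ValueError("generations must be >= 0")
    topology.check_compatible(landscape)
    ym = yield_model if yield_model is not None else YieldModel()
    S = topology.matrix(pop.h_dom)
    occupancy = dispersal_matrix(choice, topology, landscape, pop.h_dom)
    traj = Trajectory()
    p = pop.p
    for gen in range(generations + 1):
        freqs = hardy_weinberg(p)
        wbar = float(freqs @ np.sum(occupancy * S, axis=1))
        mortality = 1.0 - wbar
        traj.append(generation=gen, p=p,
                    freq_RR=freqs[0], freq_RS=freqs[1], freq_SS=freqs[2],
                    mean_fitness=wbar, landscape_mortality=mortality,
                    yield_index=yield_index(mortality, ym))
        if gen == generations:
            break
        try:
            p = step_general(p, S, landscape, regime, exposure=occupancy)
        except PopulationExtinct:
            traj.mark_extinct(gen + 1)
            break
        p = min(max(p, 0.0), 1.0)
    return traj


def realized_mortality(phi: float, topology: TradeoffTopology,
                       landscape: Landscape, h_dom: float = 0.0,
                       choice: HabitatChoice | None = None,
                       plast: Plasticity | None = None, *,
                       allele_frequency: bool = False) -> float:
    """Landscape mortality with choice and/or plasticity in effect.

    The genotype pool is ``phi`` resistant homozygotes and the rest
    susceptible (or Hardy-Weinberg at allele frequency ``phi``); plasticity
    modifies the survival matrix, choice modifies the exposure weights, and
    mortality is one minus the resulting mean survival.
    """
    if not 0.0 <= phi <= 1.0:
        raise ValueError("resistant fraction must be in [0, 1]")
    topo = effective_survival(plast, topology) if plast is not None else topology
    topo.check_compatible(landscape)
    S = topo.matrix(h_dom)
    if choice is not None:
        exposure = dispersal_matrix(choice, topo, landscape, h_dom)
    else:
        exposure = np.tile(landscape.fractions, (3, 1))
    if allele_frequency:
        freqs = hardy_weinberg(phi)
    else:
        freqs = np.array([phi, 0.0, 1.0 - phi])
    return float(1.0 - freqs @ np.sum(exposure * S, axis=1))
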