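"""Finite-population Wright-Fisher generator and survival-parameter
recovery.

The stochastic counterpart of the deterministic recursion, and the
analysis pipeline's stand-in for field data: each generation, N zygotes
are drawn multinomially at Hardy-Weinberg proportions, assigned to
habitats with probability equal to area fraction, and survive
independently with their genotype-by-habitat survival probability; the
survivors' allele frequency parameterizes the next generation's draw
(constant census size N).  Runs record the habitat-stratified genotype
cohorts -- the counts a field sampling design stratified by crop region
would observe -- which is what makes per-habitat survival estimable
downstream (landscape-pooled allele frequencies determine survival only up
to a common scale, and only as area-weighted genotype means).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear

from .core import (DiscretePopulation, Landscape, TradeoffTopology,
                   hardy_weinberg)
from .discrete import step_general

__all__ = ["StochasticRun", "SurvivalFit", "simulate_wf",
           "deterministic_cohorts", "fit_survival", "replicate_mean_p",
           "runs_to_frame"]


@dataclass
class StochasticRun:
    """One Wright-Fisher replicate.

    ``p`` holds the allele frequency at generations 0..G (NaN after
    extinction).  ``exposed[t, g, k]`` and ``survived[t, g, k]`` are the
    genotype-g counts entering and surviving selection in habitat k during
    generation t.  Counts are floats so that exact deterministic
    expectations (see :func:`deterministic_cohorts`) share the container.
    """

    N: int | None
    seed: int | None
    p: np.ndarray
    exposed: np.ndarray
    survived: np.ndarray
    extinct: bool = False
    extinct_generation: int | None = None

    @property
    def generations(self) -> int:
        return self.exposed.shape[0]


def simulate_wf(N: int, p0: float, topology: TradeoffTopology,
                landscape: Landscape, h_dom: float = 0.0,
                generations: int = 50, seed: int = 0,
                replicates: int = 1) -> list[StochasticRun]:
    """Simulate Wright-Fisher replicates of the refuge-landscape life cycle.

    Per-replicate RNG streams are spawned deterministically from the one
    global ``seed``, so a whole experiment reproduces byte-identically from
    a single integer.  Extinction (zero survivors landscape-wide) is a
    recorded outcome, not an error: the run is flagged and its remaining
    frequencies are NaN.
    """
    if N < 2:
        raise ValueError("census size N must be >= 2")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must be in [0, 1]")
    topology.check_compatible(landscape)
    S = topology.matrix(h_dom)
    n_hab = landscape.n_habitats
    streams = np.random.SeedSequence(seed).spawn(replicates)
    runs: list[StochasticRun] = []
    for rep in range(replicates):
        rng = np.random.default_rng(streams[rep])
        p = np.full(generations + 1, np.nan)
        exposed = np.zeros((generations, 3, n_hab))
        survived = np.zeros((generations, 3, n_hab))
        p[0] = p0
        extinct = False
        extinct_gen: int | None = None
        for t in range(generations):
            zygotes = rng.multinomial(N, hardy_weinberg(p[t]))
            for g in range(3):
                exposed[t, g] = rng.multinomial(zygotes[g],
                                                landscape.fractions)
            survived[t] = rng.binomial(exposed[t].astype(np.int64), S)
            by_genotype = survived[t].sum(axis=1)
            total = by_genotype.sum()
            if total == 0:
                extinct = True
                extinct_gen = t + 1
                break
            p[t + 1] = (2.0 * by_genotype[0] + by_genotype[1]) / (2.0 * total)
        runs.append(StochasticRun(N=N, seed=seed, p=p, exposed=exposed,
                                  survived=survived, extinct=extinct,
                                  extinct_generation=extinct_gen))
    return runs


def deterministic_cohorts(pop: DiscretePopulation, topology: TradeoffTopology,
                          landscape: Landscape,
                          generations: int = 10) -> StochasticRun:
    """Noise-free expected cohorts of the deterministic recursion.

    Runs the hard-selection recursion and records the exact expected
    genotype-by-habitat cohort fractions each generation (census scale 1).
    Feeding this into :func:`fit_survival` must recover the generating
    survival entries exactly -- the pipeline's self-consistency oracle.
    """
    topology.check_compatible(landscape)
    S = topology.matrix(pop.h_dom)
    p = np.full(generations + 1, np.nan)
    exposed = np.zeros((generations, 3, landscape.n_habitats))
    survived = np.zeros_like(exposed)
    p[0] = pop.p
    for t in range(generations):
        freqs = hardy_weinberg(p[t])
        exposed[t] = freqs[:, None] * landscape.fractions
        survived[t] = exposed[t] * S
        p[t + 1] = step_general(p[t], S, landscape)
    return StochasticRun(N=None, seed=None, p=p, exposed=exposed,
                         survived=survived)


@dataclass
class SurvivalFit:
    """Recovered homozygote survival entries.

    ``estimates`` is a 2-by-K array, rows (RR, SS); entries with no
    informative exposure anywhere in the data are NaN and flagged in
    ``inestimable`` rather than silently returned.
    """

    estimates: np.ndarray
    inestimable: np.ndarray
    habitat_names: tuple[str, ...] | None = None

    def as_dict(self) -> dict[str, list[float]]:
        return {"RR": [float(s) for s in self.estimates[0]],
                "SS": [float(s) for s in self.estimates[1]]}


def fit_survival(runs: list[StochasticRun], landscape: Landscape,
                 h_dom: float = 0.0) -> SurvivalFit:
    """Least-squares recovery of the homozygote survival entries.

    For every (generation, genotype, habitat) cell the model predicts
    ``survivors = exposed * s_g,k``, with the heterozygote survival tied to
    the homozygote entries through the dominance coefficient
    (``s_RS,k = h_dom * s_RR,k + (1 - h_dom) * s_SS,k``).  Stacking the
    cells gives a bounded linear least-squares problem in the 2K homozygote
    unknowns, solved with box constraints [0, 1].

    Entries whose design-matrix column is identically zero (a genotype
    never exposed in a habitat -- e.g. p fixed at 1 leaves the susceptible
    row with no information) are flagged inestimable, not guessed.
    """
    if not runs:
        raise ValueError("need at least one run")
    if any(r.generations < 1 for r in runs):
        raise ValueError("each run needs at least 1 generation of cohorts")
    K = landscape.n_habitats
    exposed = np.concatenate([r.exposed for r in runs], axis=0)
    survived = np.concatenate([r.survived for r in runs], axis=0)
    # unknowns x = [s_RR,1..K, s_SS,1..K]
    n_cells = exposed.shape[0] * 3 * K
    A = np.zeros((n_cells, 2 * K))
    b = survived.reshape(-1)
    n = exposed.reshape(exposed.shape[0], 3, K)
    row = 0
    for t in range(exposed.shape[0]):
        for g in range(3):
            for k in range(K):
                cell = n[t, g, k]
                if g == 0:
                    A[row, k] = cell
                elif g == 2:
                    A[row, K + k] = cell
                else:
                    A[row, k] = h_dom * cell
                    A[row, K + k] = (1.0 - h_dom) * cell
                row += 1
    informative = np.abs(A).sum(axis=0) > 0.0
    estimates = np.full(2 * K, np.nan)
    if informative.any():
        sol = lsq_linear(A[:, informative], b, bounds=(0.0, 1.0))
        estimates[informative] = sol.x
    names = None
    return SurvivalFit(estimates=estimates.reshape(2, K),
                       inestimable=~informative.reshape(2, K),
                       habitat_names=names)


def replicate_mean_p(runs: list[StochasticRun]) -> np.ndarray:
    """Mean allele-frequency trajectory across replicates (NaN-aware)."""
    return np.nanmean(np.vstack([r.p for r in runs]), axis=0)


def runs_to_frame(runs: list[StochasticRun]) -> pd.DataFrame:
    """Tidy per-generation table of replicate trajectories.

    Columns match the deterministic trajectory writer (generation, p,
    genotype frequencies, mean_fitness, landscape_mortality) plus
    ``replicate`` and ``N``; mean fitness here is the realized survival
    fraction of that generation's cohort.
    """
    records = []
    for rep, run in enumerate(runs):
        for t in range(run.generations):
            if np.isnan(run.p[t]):
                break
            tot_exposed = run.exposed[t].sum()
            tot_survived = run.survived[t].sum()
            wbar = tot_survived / tot_exposed if tot_exposed > 0 else np.nan
            freqs = hardy_weinberg(run.p[t])
            records.append({
                "replicate": rep, "N": run.N, "generation": t,
                "p": run.p[t], "freq_RR": freqs[0], "freq_RS": freqs[1],
                "freq_SS": freqs[2], "mean_fitness": wbar,
                "landscape_mortality": 1.0 - wbar if np.isfinite(wbar) else np.nan,
            })
    return pd.DataFrame.from_records(records)
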