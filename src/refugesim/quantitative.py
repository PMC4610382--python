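"""Quantitative-trait recursion with habitat-specific Gaussian survival.

The continuous analogue of the discrete trade-off topologies: each habitat
has an optimal trait value theta_k, and survival falls off as a Gaussian
of width omega2 around it.  Opposing optima (theta_exposed != theta_refuge)
encode a strong trade-off over a continuum; identical optima encode no
trade-off.  The trait is Gaussian in the population with constant
phenotypic variance; the response to selection follows the breeder's
equation z' = z + h2 * S.  Every stage has a closed form, each checkable
against numerical quadrature over the trait distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Landscape, PopulationExtinct, QuantPopulation, Trajectory
from .discrete import SelectionRegime
from .metrics import YieldModel, yield_index

__all__ = ["GaussianHabitatFitness", "survival_at", "mean_survival",
           "step_quant", "iterate_quant"]


@dataclass(frozen=True)
class GaussianHabitatFitness:
    """Gaussian survival functions over a continuous trait, one per habitat.

    Attributes
    ----------
    theta
        Optimal trait value in each habitat (trait units).
    omega2
        Width (variance) of the survival function, shared across habitats;
        large omega2 means weak stabilizing selection.
    s_max
        Peak survival probability at the optimum, in (0, 1].
    """

    theta: np.ndarray
    omega2: float
    s_max: float = 1.0

    def __post_init__(self) -> None:
        th = np.atleast_1d(np.asarray(self.theta, dtype=float))
        object.__setattr__(self, "theta", th)
        if not self.omega2 > 0.0:
            raise ValueError("omega2 must be positive")
        if not 0.0 < self.s_max <= 1.0:
            raise ValueError("s_max must be in (0, 1]")

    @property
    def n_habitats(self) -> int:
        return int(self.theta.size)


def survival_at(z, fit: GaussianHabitatFitness, habitat: int | None = None):
    """Survival probability of trait value ``z``.

    ``s_max * exp(-(z - theta_k)**2 / (2 * omega2))`` for habitat
    ``habitat``; if ``habitat`` is None, returns the vector over habitats.
    """
    theta = fit.theta if habitat is None else fit.theta[habitat]
    return fit.s_max * np.exp(-((np.asarray(z) - theta) ** 2)
                              / (2.0 * fit.omega2))


def mean_survival(pop: QuantPopulation, fit: GaussianHabitatFitness,
                  landscape: Landscape) -> tuple[np.ndarray, float]:
    """Mean survival per habitat and landscape-wide.

    With a Gaussian trait N(z_bar, sigma2_P) under a Gaussian survival
    function, the integral is closed form:

        E[s in k] = s_max * sqrt(omega2 / (omega2 + sigma2_P))
                    * exp(-(z_bar - theta_k)**2 / (2 (omega2 + sigma2_P)))

    and the landscape value is the area-weighted sum over habitats.
    """
    if fit.n_habitats != landscape.n_habitats:
        raise ValueError("fitness function and landscape habitat counts differ")
    v = fit.omega2 + pop.sigma2_P
    per_habitat = (fit.s_max * np.sqrt(fit.omega2 / v)
                   * np.exp(-((pop.z_bar - fit.theta) ** 2) / (2.0 * v)))
    return per_habitat, float(per_habitat @ landscape.fractions)


def step_quant(pop: QuantPopulation, fit: GaussianHabitatFitness,
               landscape: Landscape,
               regime: SelectionRegime = SelectionRegime.HARD) -> QuantPopulation:
    """Advance the trait mean one generation.

    Within habitat k the post-selection trait mean is the Gaussian
    posterior mean ``(z_bar * omega2 + theta_k * sigma2_P) / (omega2 +
    sigma2_P)``.  Habitat means are pooled with weights ``f_k * E[s in k]``
    (hard selection: survivors pool directly) or ``f_k`` (soft), giving the
    selection differential S; the response is ``z_bar' = z_bar + h2 * S``
    with phenotypic variance held constant.
    """
    per_habitat, total = mean_survival(pop, fit, landscape)
    regime = SelectionRegime(regime)
    if regime is SelectionRegime.HARD:
        weights = landscape.fractions * per_habitat
        if weights.sum() <= 0.0:
            raise PopulationExtinct("zero survival in every habitat")
    else:
        weights = landscape.fractions
    v = fit.omega2 + pop.sigma2_P
    z_star_k = (pop.z_bar * fit.omega2 + fit.theta * pop.sigma2_P) / v
    z_star = float(z_star_k @ weights / weights.sum())
    z_next = pop.z_bar + pop.h2 * (z_star - pop.z_bar)
    return QuantPopulation(z_bar=z_next, sigma2_P=pop.sigma2_P, h2=pop.h2)


def iterate_quant(pop: QuantPopulation, fit: GaussianHabitatFitness,
                  landscape: Landscape,
                  regime: SelectionRegime = SelectionRegime.HARD,
                  generations: int = 0,
                  yield_model: YieldModel | None = None) -> Trajectory:
    """Run the trait recursion, recording one trajectory row per generation."""
    if generations < 0:
        raise ValueError("generations must be >= 0")
    ym = yield_model if yield_model is not None else YieldModel()
    traj = Trajectory()
    state = pop
    for gen in range(generations + 1):
        _, wbar = mean_survival(state, fit, landscape)
        mortality = 1.0 - wbar
        traj.append(generation=gen, z_bar=state.z_bar,
                    mean_fitness=wbar, landscape_mortality=mortality,
                    yield_index=yield_index(mortality, ym))
        if gen == generations:
            break
        try:
            state = step_quant(state, fit, landscape, regime)
        except PopulationExtinct:
            traj.mark_extinct(gen + 1)
            break
    return traj
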