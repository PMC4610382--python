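"""Independent brute-force oracles for the test suite.

The cohort-enumeration oracle replays one generation of the refuge life
cycle with exact rational arithmetic, explicitly enumerating every
genotype-by-habitat cohort as a count rather than reusing the package's
vectorized frequency recursion.  It shares no code path with the
implementation it checks.
"""

from fractions import Fraction

import numpy as np
from scipy import integrate


def exact_cohort_step(p, survival_matrix, fractions, regime="hard"):
    """One generation by explicit cohort enumeration in exact rationals.

    ``survival_matrix`` is the resolved 3-by-K matrix (rows RR, RS, SS)
    and ``fractions`` the habitat areas; floats are converted to exact
    Fractions, so the only approximation is the final float conversion.
    Returns the next allele frequency, or None if everyone dies.
    """
    p = Fraction(p)
    q = 1 - p
    zygotes = {"RR": p * p, "RS": 2 * p * q, "SS": q * q}
    alleles_R = {"RR": 2, "RS": 1, "SS": 0}
    S = [[Fraction(x) for x in row] for row in np.asarray(survival_matrix)]
    f = [Fraction(x) for x in np.asarray(fractions)]
    K = len(f)

    # Enumerate every cohort (genotype g developing in habitat k).
    survivors = {}
    for gi, g in enumerate(("RR", "RS", "SS")):
        for k in range(K):
            survivors[(g, k)] = zygotes[g] * f[k] * S[gi][k]

    if regime == "hard":
        total = sum(survivors.values())
        if total == 0:
            return None
        r_alleles = sum(alleles_R[g] * n for (g, k), n in survivors.items())
        return float(Fraction(r_alleles, 2) / total)

    # Soft (Levene): each habitat contributes offspring proportional to its
    # area; within-habitat allele frequencies among survivors.
    contrib = Fraction(0)
    weight = Fraction(0)
    for k in range(K):
        tot_k = sum(survivors[(g, k)] for g in ("RR", "RS", "SS"))
        if tot_k == 0:
            continue
        r_k = sum(alleles_R[g] * survivors[(g, k)] for g in ("RR", "RS", "SS"))
        contrib += f[k] * Fraction(r_k, 2) / tot_k
        weight += f[k]
    if weight == 0:
        return None
    return float(contrib / weight)


def quadrature_mean_survival(z_bar, sigma2_P, theta_k, omega2, s_max):
    """Numerically integrate Gaussian survival against the trait density."""
    sd = np.sqrt(sigma2_P)

    def integrand(z):
        dens = np.exp(-((z - z_bar) ** 2) / (2 * sigma2_P)) / (sd * np.sqrt(2 * np.pi))
        surv = s_max * np.exp(-((z - theta_k) ** 2) / (2 * omega2))
        return dens * surv

    lo, hi = z_bar - 12 * sd, z_bar + 12 * sd
    val, _ = integrate.quad(integrand, lo, hi, epsabs=1e-12, epsrel=1e-12)
    return val
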