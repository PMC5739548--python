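"""Closed-form and asymptotic results for takeover-time distributions.

For infinitely fit invaders under Bd updating, the takeover time on the
complete graph is a coupon-collector sum of geometrics and converges,
after centering by its mean mu ~ N log N + N*gamma and scaling by N, to a
Gumbel(-gamma, 1) law (gamma the Euler-Mascheroni constant).  The star
graph converges to the same Gumbel with centering N^2 log N + (gamma-1) N^2
and scale N^2 (N = spoke count).  The 1D ring is a Lindeberg-Feller case
and is asymptotically normal with mean (N^2-N)/2 and variance
(2N^3 - 3N^2 + N)/6.  Lattices of dimension d >= 3 are right-skewed with
skewness 2 zeta(3 eta) / zeta(2 eta)^{3/2}, eta = 1 - 1/d, approaching the
Gumbel skewness 12 sqrt(6) zeta(3) / pi^3 as d -> inf.

The deterministic exponential-growth model — pathogen load N0 e^{rt}
triggering symptoms at threshold theta — gives the classical
heterogeneity-based explanation of lognormal incubation periods: T is a
fixed number (log theta - log N0)/r, lognormal across hosts only if theta
or N0 vary across hosts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import special, stats

__all__ = [
    "EULER_GAMMA",
    "LimitLaw",
    "DeterministicGrowthParams",
    "gumbel_density",
    "gumbel_skewness",
    "limit_law",
    "lattice_skew",
    "deterministic_incubation",
    "complete_fixation_mean",
    "complete_fixation_var",
]

EULER_GAMMA = float(np.euler_gamma)


@dataclass(frozen=True)
class LimitLaw:
    """Asymptotic law of a takeover time: T ≈ location + scale * Z.

    ``Z`` is Gumbel(alpha, beta) = Gumbel(-gamma, 1) for coupon-collector
    topologies, or standard normal.  ``standardize`` maps raw times onto
    the law's standardized variable Z.
    """

    family: Literal["gumbel", "normal"]
    location: float
    scale: float
    shape_params: tuple[float, float] = (-EULER_GAMMA, 1.0)

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def standardize(self, times: np.ndarray) -> np.ndarray:
        return (np.asarray(times, dtype=np.float64) - self.location) / self.scale

    @property
    def standard_dist(self):
        """The scipy frozen distribution of the standardized variable."""
        if self.family == "gumbel":
            a, b = self.shape_params
            return stats.gumbel_r(loc=a, scale=b)
        return stats.norm()

    def cdf(self, t: np.ndarray) -> np.ndarray:
        return self.standard_dist.cdf(self.standardize(t))


def gumbel_density(x, alpha: float, beta: float):
    """Gumbel(alpha, beta) density: (1/beta) e^{-z} exp(-e^{-z}), z=(x-a)/b."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    z = (np.asarray(x, dtype=np.float64) - alpha) / beta
    with np.errstate(over="ignore"):  # exp(-z) -> inf gives density 0, as wanted
        return np.exp(-z - np.exp(-z)) / beta


def gumbel_skewness() -> float:
    """Skewness of any Gumbel law: 12 sqrt(6) zeta(3) / pi^3 ≈ 1.1395."""
    return 12.0 * math.sqrt(6.0) * float(special.zeta(3.0)) / math.pi**3


def complete_fixation_mean(n: int) -> float:
    """Exact mean fixation time on the complete graph at r=inf (Bd):
    sum_m 1/p_m = (N-1) H_{N-1} ≈ N log N + N gamma."""
    k = np.arange(1, n, dtype=np.float64)
    return float(((n - 1) / k).sum())


def complete_fixation_var(n: int) -> float:
    """Exact variance of the coupon-collector fixation time:
    sum_m (1-p_m)/p_m^2."""
    m = np.arange(1, n, dtype=np.float64)
    p = (n - m) / (n - 1)
    return float(((1.0 - p) / p**2).sum())


def limit_law(family: str, n: int) -> LimitLaw:
    """Asymptotic takeover-time law for an analytically solvable family.

    ``complete``: Gumbel(-gamma,1) after (T - mu)/N with the exact finite-N
    mean mu = (N-1) H_{N-1} as centering (the asymptotic form
    N log N + N gamma is available via :func:`complete_fixation_mean`
    asymptotics).  ``star``: Gumbel(-gamma,1) after
    (T - N^2 log N - (gamma-1) N^2)/N^2, N the spoke count.  ``ring_1d``:
    standard normal after centering (N^2-N)/2 and scaling
    sqrt((2N^3 - 3N^2 + N)/6).  Higher-dimensional lattices and random
    graphs have no closed-form normalization here; normalize those
    empirically.
    """
    if n < 2:
        raise ValueError("need N >= 2")
    if family == "complete":
        return LimitLaw("gumbel", location=complete_fixation_mean(n), scale=float(n))
    if family == "star":
        loc = n**2 * math.log(n) + (EULER_GAMMA - 1.0) * n**2
        return LimitLaw("gumbel", location=loc, scale=float(n**2))
    if family == "ring_1d":
        loc = (n**2 - n) / 2.0
        scale = math.sqrt((2 * n**3 - 3 * n**2 + n) / 6.0)
        return LimitLaw("normal", location=loc, scale=scale)
    raise ValueError(
        f"no closed-form limit law for family {family!r}; "
        "use empirical normalization"
    )


def lattice_skew(d: int) -> float:
    """Asymptotic takeover-time skewness on a d-dimensional lattice, d >= 3:
    2 zeta(3 eta) / zeta(2 eta)^{3/2} with eta = 1 - 1/d.

    Increases monotonically with d and approaches the Gumbel skewness as
    d -> inf; 1D and 2D lattices are asymptotically normal (skew 0), making
    d = 2 the critical dimension.
    """
    if d < 3:
        raise ValueError("formula applies for d >= 3; 1D/2D lattices have skew 0")
    eta = 1.0 - 1.0 / d
    return float(2.0 * special.zeta(3.0 * eta) / special.zeta(2.0 * eta) ** 1.5)


@dataclass(frozen=True)
class DeterministicGrowthParams:
    """Exponential-growth incubation model: load N0 e^{rt}, symptom
    threshold theta > N0."""

    rate: float
    threshold: float
    inoculum: float

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("growth rate must be positive")
        if not self.threshold > self.inoculum > 0:
            raise ValueError("need threshold > inoculum > 0")


def deterministic_incubation(params: DeterministicGrowthParams) -> float:
    """Incubation time of the deterministic model:
    T = (log theta - log N0) / r."""
    return (math.log(params.threshold) - math.log(params.inoculum)) / params.rate
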