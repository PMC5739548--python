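"""Summary statistics and moment fits for incubation-time samples.

The headline statistic is the *dispersion factor*: the geometric standard
deviation sigma_G = exp(sd of log x), the quantity Sartwell used to
characterise incubation-period variability (typically 1.1-1.5 for
infectious diseases).  It is dimensionless and scale-invariant, and
log(sigma_G) is the natural scale estimate of an unshifted lognormal.

Also here: z-standardization, the moment-matched Gumbel fit
(beta = sd sqrt(6)/pi, alpha = mean - beta*gamma) and the three-parameter
shifted ("noncentral") lognormal fit matching mean, variance and skewness,
plus the Kolmogorov-Smirnov distance used to compare simulated ensembles
with their predicted limit laws.

Conventions: sample sd uses the n-1 denominator; skewness is the plain
moment estimator m3 / m2^{3/2} (no bias correction).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Callable, Literal

import numpy as np
from scipy import stats as sps

from .theory import EULER_GAMMA

__all__ = [
    "SummaryStats",
    "FitResult",
    "dispersion_factor",
    "standardize",
    "skewness",
    "fit_gumbel_moments",
    "fit_shifted_lognormal_moments",
    "ks_distance",
    "bootstrap_dispersion_ci",
    "read_times_csv",
]


@dataclass(frozen=True)
class SummaryStats:
    n: int
    mean: float
    sd: float
    skewness: float
    geo_mean: float
    dispersion: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


@dataclass(frozen=True)
class FitResult:
    family: Literal["gumbel", "normal", "shifted_lognormal"]
    params: dict
    converged: bool = True

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"family": self.family, "params": self.params,
                       "converged": self.converged}, fh, indent=2)


def skewness(x: np.ndarray) -> float:
    """Moment skewness m3 / m2^{3/2} (bias-uncorrected)."""
    return float(sps.skew(np.asarray(x, dtype=np.float64), bias=True))


def dispersion_factor(times) -> SummaryStats:
    """Geometric mean and geometric standard deviation of a positive sample.

    mu_G = exp(mean log x); sigma_G = exp(sqrt(sum log(x/mu_G)^2 / (n-1))).
    sigma_G >= 1 always, with equality iff the sample is constant.
    """
    x = np.asarray(times, dtype=np.float64)
    if len(x) < 2:
        raise ValueError("need at least two observations")
    if np.any(x <= 0):
        raise ValueError("dispersion factor requires strictly positive values")
    logs = np.log(x)
    mu_g = math.exp(logs.mean())
    sigma_g = math.exp(math.sqrt(np.sum((logs - logs.mean()) ** 2) / (len(x) - 1)))
    return SummaryStats(
        n=len(x),
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)),
        skewness=skewness(x),
        geo_mean=mu_g,
        dispersion=sigma_g,
    )


def standardize(times) -> np.ndarray:
    """Affine map to sample mean 0 and sample sd 1 (n-1 denominator)."""
    x = np.asarray(times, dtype=np.float64)
    if len(x) < 2:
        raise ValueError("need at least two observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant sample")
    return (x - x.mean()) / sd


def fit_gumbel_moments(times) -> FitResult:
    """Method-of-moments Gumbel fit: beta = sd sqrt(6)/pi,
    alpha = mean - beta * gamma."""
    x = np.asarray(times, dtype=np.float64)
    if len(x) < 2 or x.std(ddof=1) == 0:
        raise ValueError("degenerate sample")
    beta = x.std(ddof=1) * math.sqrt(6.0) / math.pi
    alpha = x.mean() - beta * EULER_GAMMA
    return FitResult(family="gumbel", params={"alpha": alpha, "beta": beta})


def fit_shifted_lognormal_moments(times) -> FitResult:
    """Three-parameter (noncentral) lognormal matched to mean, variance
    and skewness.

    With w = exp(sigma_log^2), the skewness of a shifted lognormal is
    (w + 2) sqrt(w - 1); substituting u = sqrt(w - 1) gives the depressed
    cubic u^3 + 3u - skew = 0, which has a unique real root for positive
    skew.  Zero or negative sample skewness admits no fit and returns
    ``converged=False``.
    """
    x = np.asarray(times, dtype=np.float64)
    if len(x) < 3:
        raise ValueError("need at least three observations")
    m, v, g = float(x.mean()), float(x.var(ddof=1)), skewness(x)
    if g <= 0 or v == 0:
        return FitResult(
            family="shifted_lognormal",
            params={"shift": math.nan, "log_mean": math.nan, "log_sd": math.nan},
            converged=False,
        )
    # Cardano root of u^3 + 3u - g = 0
    disc = math.sqrt(g * g / 4.0 + 1.0)
    u = math.copysign(abs(g / 2.0 + disc) ** (1 / 3), g / 2.0 + disc) + math.copysign(
        abs(g / 2.0 - disc) ** (1 / 3), g / 2.0 - disc
    )
    w = 1.0 + u * u
    log_sd = math.sqrt(math.log(w))
    log_mean = 0.5 * math.log(v / (w * (w - 1.0)))
    shift = m - math.exp(log_mean) * math.sqrt(w)
    return FitResult(
        family="shifted_lognormal",
        params={"shift": shift, "log_mean": log_mean, "log_sd": log_sd},
    )


def ks_distance(times, reference_cdf: Callable[[np.ndarray], np.ndarray]) -> float:
    """sup |empirical CDF - reference CDF| over the sample points."""
    x = np.sort(np.asarray(times, dtype=np.float64))
    n = len(x)
    if n == 0:
        raise ValueError("empty sample")
    cdf = np.asarray(reference_cdf(x), dtype=np.float64)
    hi = np.arange(1, n + 1) / n - cdf
    lo = cdf - np.arange(0, n) / n
    return float(max(hi.max(), lo.max()))


def bootstrap_dispersion_ci(
    times,
    n_boot: int = 2000,
    level: float = 0.95,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for the dispersion factor."""
    if rng is None:
        rng = np.random.default_rng()
    logs = np.log(np.asarray(times, dtype=np.float64))
    n = len(logs)
    idx = rng.integers(0, n, size=(n_boot, n))
    samples = logs[idx]
    dev = samples - samples.mean(axis=1, keepdims=True)
    sig = np.exp(np.sqrt((dev**2).sum(axis=1) / (n - 1)))
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(sig, [a, 1.0 - a])
    return float(lo), float(hi)


def read_times_csv(path) -> np.ndarray:
    """Read a plain one-column numeric CSV (optional header) of times."""
    try:
        return np.loadtxt(path, dtype=np.float64, ndmin=1)
    except ValueError:
        return np.loadtxt(path, dtype=np.float64, skiprows=1, ndmin=1)
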