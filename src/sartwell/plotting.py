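"""Minimal plotting helper: histogram of an ensemble with a fitted or
predicted density overlaid.  Requires matplotlib (optional extra)."""

from __future__ import annotations

import numpy as np

from .stats import FitResult, standardize
from .theory import EULER_GAMMA, LimitLaw, gumbel_density

__all__ = ["plot_histogram_overlay"]


def _density(kind, x):
    if isinstance(kind, LimitLaw):
        return kind.standard_dist.pdf(x) if kind.family == "gumbel" else (
            np.exp(-(x**2) / 2) / np.sqrt(2 * np.pi)
        )
    if isinstance(kind, FitResult):
        if kind.family == "gumbel":
            return gumbel_density(x, kind.params["alpha"], kind.params["beta"])
        if kind.family == "shifted_lognormal":
            from scipy.stats import lognorm

            p = kind.params
            return lognorm(s=p["log_sd"], loc=p["shift"],
                           scale=np.exp(p["log_mean"])).pdf(x)
        from scipy.stats import norm

        return norm(loc=kind.params["mean"], scale=kind.params["sd"]).pdf(x)
    raise TypeError(f"cannot overlay a {type(kind).__name__}")


def plot_histogram_overlay(times, overlay=None, bins=60, standardized=True, ax=None):
    """Histogram of takeover times with an optional density curve.

    ``overlay`` may be a :class:`LimitLaw` (samples are standardized with
    its constants unless ``standardized=False``) or a :class:`FitResult`
    on the raw time scale.  Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = np.asarray(times, dtype=np.float64)
    if isinstance(overlay, LimitLaw) and standardized:
        x = overlay.standardize(x)
    elif standardized and overlay is None:
        x = standardize(x)
    ax.hist(x, bins=bins, density=True, alpha=0.5, color="steelblue")
    if overlay is not None:
        grid = np.linspace(x.min(), x.max(), 400)
        ax.plot(grid, _density(overlay, grid), color="crimson", lw=1.5)
    ax.set_xlabel("takeover time" + (" (standardized)" if standardized else ""))
    ax.set_ylabel("density")
    return ax
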