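"""Simple matplotlib views: diurnal profile, RoC histogram with fitted
density, and a normal QQ plot for the analyst's distribution check."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_diurnal(profile, ax=None, label=None, color=None):
    """Median glucose with IQR band by clock hour (one arm)."""
    if ax is None:
        _, ax = plt.subplots()
    h = profile["bin_start_hour"]
    ax.plot(h, profile["glucose_median"], label=label, color=color)
    ax.fill_between(h, profile["glucose_q1"], profile["glucose_q3"], alpha=0.2, color=color)
    ax.set_xlabel("clock time (h)")
    ax.set_ylabel("glucose (mmol/L)")
    if label:
        ax.legend()
    return ax


def plot_roc_fit(slopes, fit, ax=None, bins=80):
    """Histogram of RoC values with the fitted t location-scale density and
    the +/-1.5 mmol/L/15 min rapid-change thresholds."""
    if ax is None:
        _, ax = plt.subplots()
    slopes = np.asarray(slopes, float)
    ax.hist(slopes, bins=bins, density=True, alpha=0.5)
    x = np.linspace(np.nanmin(slopes), np.nanmax(slopes), 400)
    ax.plot(x, sps.t.pdf(x, fit.df, loc=fit.location, scale=fit.scale))
    for v in (-1.5, 1.5):
        ax.axvline(v, linestyle=":", color="k")
    ax.set_xlabel("RoC (mmol/L per 15 min)")
    ax.set_ylabel("density")
    return ax


def qq_plot(sample, ax=None):
    """Normal QQ plot (visual normality check before choosing a test)."""
    if ax is None:
        _, ax = plt.subplots()
    sps.probplot(np.asarray(sample, float), dist="norm", plot=ax)
    return ax
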