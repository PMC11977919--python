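"""Glucose rate of change (RoC), rapid-change time, and heavy-tailed fits.

RoC is the ordinary least-squares slope of glucose on time over a 15-min
window of four consecutive 5-min readings (t = 0, 5, 10, 15 min), expressed
in mmol/L per 15 min. Windows advance in steps of 15 min, sharing one
endpoint slot with their neighbour; a window is valid only if all four slots
carry a value (no imputation). TRC+/TRC- are the percent of valid windows
with slope strictly above +1.5 / strictly below -1.5 mmol/L/15 min, and AARC
is the mean absolute slope.

The pooled RoC values of a cohort are heavy-tailed and are summarized by a
maximum-likelihood t location-scale fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize, stats

from .core import GlucoseTrace
from .errors import FitError, UndefinedMetricsError

#: Rapid-change threshold, mmol/L per 15 min.
ROC_THRESHOLD = 1.5

# OLS slope weights for ordinates at x = 0, 1/3, 2/3, 1 (15-min units):
# slope = sum(w * y) with w = (x - xbar) / sum((x - xbar)^2).
_SLOPE_W = np.array([-0.9, -0.3, 0.3, 0.9])


@dataclass
class RocSeries:
    """Per-trace RoC windows: start slots and slopes of the valid windows."""

    window_starts: np.ndarray  # slot index of t=0 for each valid window
    slopes: np.ndarray  # mmol/L per 15 min
    n_candidate_windows: int
    n_valid_windows: int


def roc_series(trace: GlucoseTrace, step: int = 3) -> RocSeries:
    """Compute the RoC series of a trace.

    ``step=3`` gives the default endpoint-sharing tiling (windows every
    15 min); ``step=4`` gives fully disjoint windows. A trace with fewer than
    4 slots yields an empty series.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    v = trace.values
    n = v.size
    if n < 4:
        return RocSeries(np.empty(0, int), np.empty(0), 0, 0)
    starts = np.arange(0, n - 3, step)
    windows = v[starts[:, None] + np.arange(4)]
    valid = ~np.isnan(windows).any(axis=1)
    slopes = windows[valid] @ _SLOPE_W
    return RocSeries(
        window_starts=starts[valid],
        slopes=slopes,
        n_candidate_windows=int(starts.size),
        n_valid_windows=int(valid.sum()),
    )


@dataclass
class TrcMetrics:
    """Time with rapid change of glucose, percent of valid RoC windows."""

    trc_plus: float
    trc_minus: float
    trc: float
    aarc: float  # mmol/L per 15 min


def trc_metrics(series: RocSeries, threshold: float = ROC_THRESHOLD) -> TrcMetrics:
    """TRC+/TRC-/TRC and AARC from an RoC series (strict thresholds)."""
    if series.n_valid_windows < 1:
        raise UndefinedMetricsError("no valid RoC windows")
    s = series.slopes
    plus = 100.0 * (s > threshold).sum() / s.size
    minus = 100.0 * (s < -threshold).sum() / s.size
    return TrcMetrics(
        trc_plus=plus,
        trc_minus=minus,
        trc=plus + minus,
        aarc=float(np.abs(s).mean()),
    )


@dataclass
class TLocScaleFit:
    """Maximum-likelihood t location-scale fit of pooled RoC values.

    ``sd`` is the implied standard deviation ``scale * sqrt(df/(df-2))``
    (NaN when df <= 2, where the variance does not exist).
    """

    location: float
    scale: float
    df: float
    sd: float
    loglik: float
    n: int


def _t_loglik(x: np.ndarray, loc: float, scale: float, df: float) -> float:
    return float(stats.t.logpdf(x, df, loc=loc, scale=scale).sum())


def fit_t_location_scale(
    slopes: np.ndarray,
    df_start: float = 5.0,
    max_iter: int = 5000,
) -> TLocScaleFit:
    """Fit the three-parameter t location-scale family by maximum likelihood.

    The optimizer (Nelder-Mead on location, log-scale, log-df) starts from
    robust moment estimates: the sample median, the normal-consistent scaled
    MAD, and df = 5; convergence is declared when successive log-likelihood
    improvement falls below 1e-8. The fitted log-likelihood never falls below
    the starting value (raising :class:`FitError` otherwise, with the
    optimizer trajectory attached).
    """
    x = np.asarray(slopes, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 50:
        raise ValueError("at least 50 values required for a stable fit")

    loc0 = float(np.median(x))
    mad = float(np.median(np.abs(x - loc0)))
    scale0 = 1.4826 * mad if mad > 0 else max(float(x.std()), 1e-6)
    theta0 = np.array([loc0, np.log(scale0), np.log(df_start)])

    trajectory = []

    def nll(theta):
        loc, log_scale, log_df = theta
        ll = _t_loglik(x, loc, np.exp(log_scale), np.exp(log_df))
        trajectory.append((theta.copy(), ll))
        return -ll

    res = optimize.minimize(
        nll,
        theta0,
        method="Nelder-Mead",
        options={"fatol": 1e-8, "xatol": 1e-8, "maxiter": max_iter, "maxfev": max_iter},
    )
    loc, log_scale, log_df = res.x
    scale, df = float(np.exp(log_scale)), float(np.exp(log_df))
    ll_fit = _t_loglik(x, loc, scale, df)
    ll_start = _t_loglik(x, theta0[0], np.exp(theta0[1]), np.exp(theta0[2]))
    if not res.success or not np.isfinite(ll_fit):
        raise FitError(f"t location-scale fit did not converge: {res.message}", trajectory)
    if ll_fit < ll_start - 1e-9:
        raise FitError("fit log-likelihood below starting value", trajectory)
    sd = scale * np.sqrt(df / (df - 2.0)) if df > 2.0 else float("nan")
    return TLocScaleFit(float(loc), scale, df, float(sd), ll_fit, int(x.size))


@dataclass
class SkewTFit:
    """Optional skewed heavy-tailed fit (Jones-Faddy skew-t)."""

    a: float
    b: float
    location: float
    scale: float
    loglik: float
    n: int


def fit_skew_t(slopes: np.ndarray) -> SkewTFit:
    """Fit a Jones-Faddy skew-t as an asymmetric alternative to the
    symmetric t location-scale summary (not the default reporting path)."""
    x = np.asarray(slopes, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 50:
        raise ValueError("at least 50 values required for a stable fit")
    a, b, loc, scale = stats.jf_skew_t.fit(x)
    ll = float(stats.jf_skew_t.logpdf(x, a, b, loc=loc, scale=scale).sum())
    return SkewTFit(float(a), float(b), float(loc), float(scale), ll, int(x.size))
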