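"""Consensus glycaemic metrics, diurnal profiles and pump-profile means.

Range metrics follow the international consensus cut-offs with the boundary
convention centralized in :func:`range_masks`: ranges stated as "a to b"
(TIR 3.9-10.0, TITR 3.9-7.8 mmol/L) are closed intervals; "above"/"below"
cut-offs (TAR >10.0, TAR2 >13.9, TBR <3.9, TBR2 <3.0) are strict. All
denominators are the number of slots carrying a glucose value, not the raster
length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (
    SLOTS_PER_DAY,
    TAR2_CUT,
    TBR2_CUT,
    TIR_HIGH,
    TIR_LOW,
    TITR_HIGH,
    GlucoseTrace,
)
from .errors import InvalidProfileError, UndefinedMetricsError

#: GMI (glucose management indicator) linear coefficients for mmol/mol
#: from mean sensor glucose in mmol/L.
GMI_SLOPE = 4.70587
GMI_INTERCEPT = 12.71


def gmi(mean_glucose: float) -> float:
    """Glucose management indicator, mmol/mol, from mean glucose in mmol/L.

    ``4.70587 * mean + 12.71``, unrounded (reports round to one decimal).
    """
    if mean_glucose < 0:
        raise ValueError("mean glucose must be non-negative")
    return GMI_SLOPE * mean_glucose + GMI_INTERCEPT


def range_masks(values: np.ndarray) -> Dict[str, np.ndarray]:
    """Boolean range masks for an array of present glucose values."""
    v = np.asarray(values, dtype=float)
    return {
        "tir": (v >= TIR_LOW) & (v <= TIR_HIGH),
        "titr": (v >= TIR_LOW) & (v <= TITR_HIGH),
        "tar": v > TIR_HIGH,
        "tar2": v > TAR2_CUT,
        "tbr": v < TIR_LOW,
        "tbr2": v < TBR2_CUT,
    }


@dataclass
class RangeMetrics:
    """Per-subject consensus range metrics (percent of readings) plus
    mean/SD/CV of sensor glucose and the GMI."""

    tir: float
    titr: float
    tar: float
    tar2: float
    tbr: float
    tbr2: float
    mean_glucose: float
    sd_glucose: float
    cv: float
    gmi: float
    n_values: int


def range_metrics(trace: GlucoseTrace) -> RangeMetrics:
    """Compute the consensus range metrics for one trace.

    Raises :class:`UndefinedMetricsError` on an all-missing trace. SD is the
    sample standard deviation (n-1); CV is 100*SD/mean.
    """
    v = trace.values[trace.present]
    if v.size == 0:
        raise UndefinedMetricsError(f"{trace.subject_id}: no glucose values")
    masks = range_masks(v)
    pct = {k: 100.0 * m.sum() / v.size for k, m in masks.items()}
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    return RangeMetrics(
        tir=pct["tir"],
        titr=pct["titr"],
        tar=pct["tar"],
        tar2=pct["tar2"],
        tbr=pct["tbr"],
        tbr2=pct["tbr2"],
        mean_glucose=mean,
        sd_glucose=sd,
        cv=100.0 * sd / mean,
        gmi=gmi(mean),
        n_values=int(v.size),
    )


def diurnal_profile(
    traces: Iterable[GlucoseTrace],
    bin_minutes: int = 60,
) -> pd.DataFrame:
    """Clock-time profile of TIR and glucose median (IQR), pooled over
    all present values across days and subjects.

    Returns one row per clock-time bin with columns ``bin_start_hour``, ``n``,
    ``tir``, ``glucose_median``, ``glucose_q1``, ``glucose_q3`` and ``empty``.
    Bins without data are flagged empty (metrics NaN) rather than zero.
    """
    if bin_minutes <= 0 or 1440 % bin_minutes:
        raise ValueError("bin_minutes must divide 1440")
    traces = list(traces)
    if not traces:
        raise ValueError("at least one trace required")
    slots_per_bin = bin_minutes // 5
    n_bins = 1440 // bin_minutes
    pooled: List[List[np.ndarray]] = [[] for _ in range(n_bins)]
    for tr in traces:
        day_slot = np.arange(tr.n_slots) % SLOTS_PER_DAY
        bins = day_slot // slots_per_bin
        pres = tr.present
        for b in range(n_bins):
            sel = pres & (bins == b)
            if sel.any():
                pooled[b].append(tr.values[sel])
    rows = []
    for b in range(n_bins):
        vals = np.concatenate(pooled[b]) if pooled[b] else np.empty(0)
        if vals.size:
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            tir = 100.0 * range_masks(vals)["tir"].sum() / vals.size
            rows.append((b * bin_minutes / 60.0, vals.size, tir, med, q1, q3, False))
        else:
            rows.append((b * bin_minutes / 60.0, 0, np.nan, np.nan, np.nan, np.nan, True))
    return pd.DataFrame(
        rows,
        columns=["bin_start_hour", "n", "tir", "glucose_median", "glucose_q1", "glucose_q3", "empty"],
    )


@dataclass
class StepProfile24h:
    """A 24-h pump-settings step profile.

    ``segments`` are ``(start_minute, end_minute, value)`` triples that must
    tile [0, 1440) without gaps or overlap.
    """

    segments: Sequence[Tuple[float, float, float]]

    def validate(self) -> None:
        segs = sorted(self.segments)
        if not segs:
            raise InvalidProfileError("profile has no segments")
        if segs[0][0] != 0 or segs[-1][1] != 1440:
            raise InvalidProfileError("profile must start at 00:00 and end at 24:00")
        for (s0, e0, _), (s1, _, _) in zip(segs, segs[1:]):
            if e0 < s1:
                raise InvalidProfileError(f"gap between minute {e0} and {s1}")
            if e0 > s1:
                raise InvalidProfileError(f"overlap between minute {s1} and {e0}")
        for s, e, _ in segs:
            if e <= s:
                raise InvalidProfileError(f"segment ({s}, {e}) has non-positive duration")


def time_weighted_mean(profile: StepProfile24h) -> float:
    """Time-weighted 24-h mean of a step profile: sum(value * minutes)/1440."""
    profile.validate()
    return sum(v * (e - s) for s, e, v in profile.segments) / 1440.0
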