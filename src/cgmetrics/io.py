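"""Reading raw CGM exports and aligning them to the 5-min analysis raster.

Supported export dialects differ only in header names, timestamp format and
glucose unit; everything is normalized to mmol/L on a fixed raster anchored
at midnight of the first day of the analysis window, so diurnal (clock-time)
binning downstream is exact.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from datetime import datetime, time, timedelta
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_N_DAYS,
    GLUCOSE_MAX,
    GLUCOSE_MIN,
    MGDL_PER_MMOLL,
    SLOT_MINUTES,
    SLOTS_PER_DAY,
    GlucoseTrace,
)
from .errors import DialectError, EmptyInputError


@dataclass(frozen=True)
class Dialect:
    """Column mapping for one CGM export flavour."""

    timestamp_col: str
    glucose_col: str
    timestamp_format: Optional[str] = None  # None -> ISO-8601
    unit: str = "mmol/L"  # or "mg/dL"


DIALECTS = {
    "generic": Dialect("timestamp", "glucose_mmol_l"),
    "vendor_a": Dialect("Time", "Sensor Glucose (mmol/L)", "%d-%m-%Y %H:%M"),
    "vendor_b": Dialect("Timestamp", "Glucose Value (mg/dL)", "%m/%d/%Y %H:%M", unit="mg/dL"),
}


@dataclass
class ParseReport:
    """Row-level accounting for one parsed export.

    ``n_rows`` input rows split into parsed samples, rows dropped as
    unparseable, rows rejected by the plausibility window, and rows collapsed
    into an earlier sample sharing its timestamp; the pieces always reconcile:
    ``n_samples = n_rows - n_unparseable - n_out_of_range - n_duplicates_collapsed``.
    """

    n_rows: int = 0
    n_samples: int = 0
    n_unparseable: int = 0
    n_out_of_range: int = 0
    n_duplicates_collapsed: int = 0


@dataclass
class RawSampleStream:
    """Timestamp-sorted glucose samples for one subject, in mmol/L."""

    subject_id: str
    timestamps: pd.DatetimeIndex
    glucose: np.ndarray
    report: ParseReport = field(default_factory=ParseReport)

    def __post_init__(self) -> None:
        self.glucose = np.asarray(self.glucose, dtype=float)
        if len(self.timestamps) != self.glucose.size:
            raise ValueError("timestamps and glucose lengths differ")
        if len(self.timestamps) > 1 and not self.timestamps.is_monotonic_increasing:
            raise ValueError("timestamps must be sorted increasing")

    def __len__(self) -> int:
        return self.glucose.size


def _sniff_sep(first_line: str) -> str:
    return ";" if first_line.count(";") > first_line.count(",") else ","


def parse_cgm_export(
    path: Union[str, Path, _io.TextIOBase],
    dialect: str = "generic",
    subject_id: Optional[str] = None,
) -> RawSampleStream:
    """Parse a delimited CGM export into a normalized sample stream.

    The delimiter (comma or semicolon) is autodetected from the header row.
    Rows with unparseable timestamps or glucose values are dropped and
    counted; values outside the [1, 30] mmol/L plausibility window are
    rejected; duplicate timestamps are collapsed to their mean. mg/dL inputs
    are converted by dividing by 18.016.

    Raises
    ------
    DialectError
        If a mandatory column is missing.
    EmptyInputError
        If no row parses.
    """
    if dialect not in DIALECTS:
        raise DialectError(f"unknown dialect {dialect!r}; choose from {sorted(DIALECTS)}")
    spec = DIALECTS[dialect]

    if isinstance(path, (str, Path)):
        text = Path(path).read_text(encoding="utf-8")
        if subject_id is None:
            subject_id = Path(path).stem
    else:
        text = path.read()
        if subject_id is None:
            subject_id = "<stream>"
    if not text.strip():
        raise EmptyInputError(f"{subject_id}: empty file")

    sep = _sniff_sep(text.splitlines()[0])
    df = pd.read_csv(_io.StringIO(text), sep=sep, dtype=str, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    missing = {spec.timestamp_col, spec.glucose_col} - set(df.columns)
    if missing:
        raise DialectError(
            f"{subject_id}: columns {sorted(missing)} required by dialect {dialect!r} "
            f"not found in {list(df.columns)}"
        )

    report = ParseReport(n_rows=len(df))
    ts = pd.to_datetime(df[spec.timestamp_col], format=spec.timestamp_format, errors="coerce")
    glu = pd.to_numeric(df[spec.glucose_col], errors="coerce")
    ok = ts.notna() & glu.notna()
    report.n_unparseable = int((~ok).sum())
    ts, glu = ts[ok], glu[ok].astype(float)
    if spec.unit == "mg/dL":
        glu = glu / MGDL_PER_MMOLL

    in_window = (glu >= GLUCOSE_MIN) & (glu <= GLUCOSE_MAX)
    report.n_out_of_range = int((~in_window).sum())
    ts, glu = ts[in_window], glu[in_window]
    if ts.empty:
        raise EmptyInputError(f"{subject_id}: no parseable in-range rows")

    # Duplicate timestamps (vendor double-reports) collapse to their mean,
    # which is order-independent.
    grouped = pd.Series(glu.values, index=ts.values).groupby(level=0).mean().sort_index()
    report.n_duplicates_collapsed = len(ts) - len(grouped)
    report.n_samples = len(grouped)
    return RawSampleStream(
        subject_id=subject_id,
        timestamps=pd.DatetimeIndex(grouped.index),
        glucose=grouped.to_numpy(),
        report=report,
    )


def grid_trace(
    stream: RawSampleStream,
    window_end: Optional[datetime] = None,
    n_days: int = DEFAULT_N_DAYS,
) -> GlucoseTrace:
    """Raster a sample stream onto the 5-min grid of the analysis window.

    The window is the ``n_days`` calendar days ending with the day containing
    ``window_end`` (default: the last sample), so the most recent data are
    retained; the grid is anchored at midnight of the window's first day.
    Each sample goes to the nearest slot (ties toward the earlier slot);
    samples mapping to the same slot are averaged; slots without a sample are
    missing; samples outside the window are discarded.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if window_end is None:
        if len(stream) == 0:
            raise ValueError("window_end required for an empty stream")
        window_end = stream.timestamps[-1].to_pydatetime()
    n_slots = n_days * SLOTS_PER_DAY
    grid_start = datetime.combine(
        window_end.date() - timedelta(days=n_days - 1), time(0, 0)
    )

    values = np.full(n_slots, np.nan)
    if len(stream):
        offset_min = (
            stream.timestamps - pd.Timestamp(grid_start)
        ).total_seconds().to_numpy() / 60.0
        # nearest slot, tie (x.5 slot widths) toward the earlier slot
        slots = np.ceil((offset_min - SLOT_MINUTES / 2) / SLOT_MINUTES).astype(int)
        keep = (slots >= 0) & (slots < n_slots)
        slots, glu = slots[keep], stream.glucose[keep]
        sums = np.zeros(n_slots)
        counts = np.zeros(n_slots)
        np.add.at(sums, slots, glu)
        np.add.at(counts, slots, 1)
        hit = counts > 0
        values[hit] = sums[hit] / counts[hit]
    return GlucoseTrace(stream.subject_id, grid_start, values, n_days)


def active_cgm_time(trace: GlucoseTrace) -> float:
    """Percent of raster slots carrying a glucose value.

    The denominator is the full calendar window (``n_days * 288`` slots, i.e.
    17,280 for 60 days), not the observed span.
    """
    return 100.0 * int(trace.present.sum()) / trace.n_slots


def write_trace(trace: GlucoseTrace, path: Union[str, Path]) -> None:
    """Write a normalized trace: one row per slot, empty field when missing."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("slot_index,timestamp,glucose_mmol_l\n")
        for i, v in enumerate(trace.values):
            stamp = trace.slot_time(i).isoformat(sep=" ")
            fh.write(f"{i},{stamp},{'' if np.isnan(v) else format(v, '.4f')}\n")


def read_trace(path: Union[str, Path], subject_id: Optional[str] = None) -> GlucoseTrace:
    """Read a normalized trace written by :func:`write_trace`."""
    df = pd.read_csv(path)
    ts = pd.to_datetime(df["timestamp"])
    n_slots = len(df)
    if n_slots % SLOTS_PER_DAY:
        raise ValueError("normalized trace length must be a whole number of days")
    return GlucoseTrace(
        subject_id or Path(path).stem,
        ts.iloc[0].to_pydatetime(),
        df["glucose_mmol_l"].to_numpy(dtype=float),
        n_days=n_slots // SLOTS_PER_DAY,
    )


def stream_from_samples(
    subject_id: str,
    samples: Sequence[tuple],
) -> RawSampleStream:
    """Build a stream from in-memory ``(datetime, glucose)`` pairs (sorted)."""
    if not samples:
        return RawSampleStream(subject_id, pd.DatetimeIndex([]), np.empty(0))
    ts, glu = zip(*samples)
    order = np.argsort(pd.DatetimeIndex(ts).values)
    return RawSampleStream(
        subject_id,
        pd.DatetimeIndex(ts)[order],
        np.asarray(glu, dtype=float)[order],
    )
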