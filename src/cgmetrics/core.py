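"""Core containers and constants shared across the package.

Glucose is carried internally in mmol/L throughout. A subject's sensor data
live on a fixed 5-min raster (288 slots/day); missing slots are NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Optional

import numpy as np

#: Raster resolution in minutes.
SLOT_MINUTES = 5
#: Number of 5-min slots in one day.
SLOTS_PER_DAY = 24 * 60 // SLOT_MINUTES  # 288
#: Default analysis window in days.
DEFAULT_N_DAYS = 60
#: mg/dL per mmol/L for glucose (molar mass convention used by CGM exports).
MGDL_PER_MMOLL = 18.016
#: Plausibility window for sensor glucose, mmol/L. Values outside are
#: treated as sensor artefacts and rejected at parse time.
GLUCOSE_MIN, GLUCOSE_MAX = 1.0, 30.0

# Consensus glycaemic range cut-offs, mmol/L.
TIR_LOW, TIR_HIGH = 3.9, 10.0
TITR_HIGH = 7.8
TAR2_CUT = 13.9
TBR2_CUT = 3.0


@dataclass
class GlucoseTrace:
    """One subject's rastered glucose series.

    Parameters
    ----------
    subject_id : str
        Opaque subject identifier.
    grid_start : datetime
        Timestamp of slot 0; must fall on a 5-min boundary.
    values : numpy.ndarray
        Float array of length ``n_days * 288``; NaN marks a missing slot.
    n_days : int
        Calendar days covered by the raster.
    """

    subject_id: str
    grid_start: datetime
    values: np.ndarray
    n_days: int = DEFAULT_N_DAYS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = self.n_days * SLOTS_PER_DAY
        if self.values.shape != (expected,):
            raise ValueError(
                f"trace for {self.subject_id!r} has {self.values.size} slots, "
                f"expected {expected} for {self.n_days} days"
            )
        if self.grid_start.minute % SLOT_MINUTES or self.grid_start.second:
            raise ValueError("grid_start must fall on a 5-min boundary")
        present = self.values[~np.isnan(self.values)]
        if present.size and (present.min() < GLUCOSE_MIN or present.max() > GLUCOSE_MAX):
            raise ValueError(
                f"glucose outside plausibility window [{GLUCOSE_MIN}, {GLUCOSE_MAX}] mmol/L"
            )

    @property
    def n_slots(self) -> int:
        return self.n_days * SLOTS_PER_DAY

    @property
    def present(self) -> np.ndarray:
        """Boolean mask of slots that carry a glucose value."""
        return ~np.isnan(self.values)

    def slot_time(self, slot: int) -> datetime:
        """Calendar timestamp of a raster slot."""
        return self.grid_start + timedelta(minutes=SLOT_MINUTES * int(slot))


@dataclass
class SubjectRecord:
    """Clinical covariates for one subject, coded as in the cohort tables.

    ``aid_system``: CIQ = 0, MM780G = 1. ``gender``: female = 0, male = 1.
    ``setting``: regional = 0, university = 1. ``time_with_aid`` is in days;
    the regression layer converts it to months (days / 30.44).
    """

    subject_id: str
    aid_system: int
    hba1c_baseline: float  # mmol/mol
    age: float  # years
    time_with_aid: float  # days
    setting: int
    diabetes_duration: float  # years
    gender: int
    bmi: float  # kg/m^2
    metrics: Optional[object] = field(default=None, repr=False)
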