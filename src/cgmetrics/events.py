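"""Hypoglycaemia event detection with debouncing, rebound flags and rates.

An event requires at least three consecutive present 5-min readings strictly
below the threshold (3.9 mmol/L; 3.0 mmol/L for severe events), and closes
only after at least three consecutive present readings at or above the
threshold. Shorter recoveries (1-2 slots) are absorbed into the event;
missing slots break consecutiveness for both the below-run and the
recovery-run. A below-run still open at the end of the trace is censored
(not counted), mirroring the requirement that an event be *followed by* a
qualifying recovery.

Rebound hyperglycaemia: at least one reading strictly above 10 mmol/L within
120 min (24 slots) after the event, the window starting at the first
recovery slot.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .core import TIR_HIGH, TIR_LOW, TBR2_CUT, GlucoseTrace

#: Slots required below threshold to open, and at/above to close, an event.
MIN_RUN = 3
#: Rebound look-ahead window in slots (120 min).
REBOUND_WINDOW_SLOTS = 24
#: Rebound glucose cut-off, mmol/L (strict).
REBOUND_CUT = TIR_HIGH


@dataclass
class GlycemicEvent:
    """One detected below-threshold episode.

    ``start_slot``/``end_slot`` delimit the first and last below-threshold
    reading of the episode (inclusive); ``severity`` is ``"hypo"`` for the
    3.9 mmol/L threshold and ``"severe"`` for 3.0 mmol/L.
    """

    severity: str
    start_slot: int
    end_slot: int
    rebound: Optional[bool] = None

    @property
    def duration_min(self) -> int:
        return 5 * (self.end_slot - self.start_slot + 1)


def detect_events(
    trace: GlucoseTrace,
    threshold: float = TIR_LOW,
    severity: Optional[str] = None,
    with_rebound: bool = True,
) -> List[GlycemicEvent]:
    """Scan a trace left to right for debounced below-threshold events.

    Severe events are detected by an independent scan at ``threshold=3.0``,
    not as a sub-classification of 3.9-events.
    """
    if severity is None:
        severity = "severe" if threshold == TBR2_CUT else "hypo"
    v = trace.values
    present = ~np.isnan(v)
    below = present & (v < threshold)
    above = present & (v >= threshold)

    events: List[GlycemicEvent] = []
    in_event = False
    below_run = 0
    recovery_run = 0
    start = end = -1
    for i in range(v.size):
        if not in_event:
            below_run = below_run + 1 if below[i] else 0
            if below_run == MIN_RUN:
                in_event = True
                start, end = i - MIN_RUN + 1, i
                recovery_run = 0
        else:
            if below[i]:
                end = i
                recovery_run = 0
            elif above[i]:
                recovery_run += 1
                if recovery_run == MIN_RUN:
                    events.append(GlycemicEvent(severity, start, end))
                    in_event = False
                    below_run = 0
            else:  # missing breaks the recovery run but keeps the event open
                recovery_run = 0
    # an event still open at trace end is censored: no qualifying recovery

    if with_rebound:
        for ev in events:
            ev.rebound = flag_rebound(ev, trace)
    return events


def flag_rebound(event: GlycemicEvent, trace: GlucoseTrace) -> bool:
    """True iff any present reading > 10 mmol/L occurs within 24 slots after
    the event's last below-threshold slot (window truncated at trace end)."""
    lo = event.end_slot + 1
    hi = min(lo + REBOUND_WINDOW_SLOTS, trace.n_slots)
    window = trace.values[lo:hi]
    window = window[~np.isnan(window)]
    return bool((window > REBOUND_CUT).any())


@dataclass
class EventRates:
    """Event frequencies normalized per 14 days.

    ``rebound_fraction`` is the percent of hypoglycaemic events followed by
    rebound hyperglycaemia; it is None (undefined) when no event occurred.
    """

    hypo_per_14d: float
    severe_per_14d: float
    rebound_per_14d: float
    rebound_fraction: Optional[float]


def event_rates(
    hypo_events: List[GlycemicEvent],
    trace: GlucoseTrace,
    severe_events: Optional[List[GlycemicEvent]] = None,
) -> EventRates:
    """Per-14-day event rates: count * 14 / n_days."""
    if severe_events is None:
        severe_events = detect_events(trace, TBR2_CUT, with_rebound=False)
    scale = 14.0 / trace.n_days
    n_hypo = len(hypo_events)
    n_reb = sum(1 for e in hypo_events if e.rebound)
    return EventRates(
        hypo_per_14d=n_hypo * scale,
        severe_per_14d=len(severe_events) * scale,
        rebound_per_14d=n_reb * scale,
        rebound_fraction=100.0 * n_reb / n_hypo if n_hypo else None,
    )
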