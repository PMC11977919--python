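from datetime import datetime

import numpy as np
import pytest

from cgmetrics.core import SLOTS_PER_DAY, GlucoseTrace

GRID0 = datetime(2023, 3, 1, 0, 0)


def make_trace(values, subject_id="s1", n_days=None, grid_start=GRID0):
    """Pad a short value sequence with NaN up to a whole number of days."""
    values = np.asarray(values, dtype=float)
    if n_days is None:
        n_days = max(1, int(np.ceil(values.size / SLOTS_PER_DAY)))
    full = np.full(n_days * SLOTS_PER_DAY, np.nan)
    full[: values.size] = values
    return GlucoseTrace(subject_id, grid_start, full, n_days)


@pytest.fixture
def rng():
    return np.random.default_rng(20230301)


@pytest.fixture
def constant_trace():
    return make_trace(np.full(SLOTS_PER_DAY, 5.0), n_days=1)


def random_trace(rng, n_days=1, missing=0.1, lo=2.0, hi=16.0, subject_id="r"):
    n = n_days * SLOTS_PER_DAY
    v = rng.uniform(lo, hi, n)
    v[rng.random(n) < missing] = np.nan
    return GlucoseTrace(subject_id, GRID0, v, n_days)
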