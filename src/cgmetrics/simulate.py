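"""Synthetic two-arm CGM cohort generator.

The signal model is deliberately statistical rather than physiological: each
subject's 5-min glucose series is an additive combination of a baseline, a
diurnal sinusoid, meal excursion pulses (log-normal-shaped rise, exponential
decay), AR(1) noise, a soft lower floor emulating the insulin-suspension
behaviour of AID systems, and explicitly planted hypoglycaemic dips, with
sensor dropout applied last. This reproduces the marginal and short-range
temporal structure the analysis pipeline measures (ranges, 15-min slopes,
below-threshold runs) without modelling insulin kinetics.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from datetime import datetime
from typing import List, Optional, Tuple

import numpy as np
import yaml
from scipy import signal as _signal

from .core import (
    DEFAULT_N_DAYS,
    GLUCOSE_MAX,
    GLUCOSE_MIN,
    SLOTS_PER_DAY,
    TIR_LOW,
    GlucoseTrace,
    SubjectRecord,
)

#: Default raster origin for simulated cohorts (an arbitrary midnight).
SIM_GRID_START = datetime(2023, 1, 1, 0, 0)


@dataclass
class ArmConfig:
    """Generative parameters for one study arm.

    Rates and targets are expressed in the units the analysis reports:
    glucose in mmol/L, hypoglycaemia as events per 14 days, dropout as the
    complement of fractional active sensor time.
    """

    n_subjects: int = 60
    mean_glucose: float = 8.7  # mmol/L, per-subject target mean
    within_day_sd: float = 2.1  # stationary SD of the AR(1) noise, mmol/L
    ar1_phi: float = 0.985  # 5-min lag autocorrelation, in (0, 1)
    diurnal_amplitude: float = 0.8  # mmol/L, sinusoid semi-amplitude
    diurnal_acrophase_hour: float = 21.0  # clock time of the diurnal peak
    meals_per_day: float = 4.5  # Poisson mean, waking hours
    meal_peak_mean: float = 3.5  # mmol/L, log-normal excursion peak
    meal_peak_sd: float = 1.3
    meal_rise_minutes: float = 60.0
    meal_decay_minutes: float = 120.0
    hypo_events_per_14d: float = 5.0  # planted dip rate
    hypo_depth: float = 0.7  # mmol/L below the 3.9 threshold at the nadir
    missing_fraction: float = 0.02  # target 1 - active_time/100
    gap_pattern: str = "random"  # or "periodic_warmup"
    warmup_interval_days: int = 10  # sensor-change cadence for periodic gaps

    def __post_init__(self) -> None:
        if not 0 < self.ar1_phi < 1:
            raise ValueError("ar1_phi must lie in (0, 1)")
        if not 0 <= self.missing_fraction <= 0.15:
            raise ValueError("missing_fraction must lie in [0, 0.15]")
        if self.gap_pattern not in ("random", "periodic_warmup"):
            raise ValueError("gap_pattern must be 'random' or 'periodic_warmup'")
        for name in ("meals_per_day", "hypo_events_per_14d", "hypo_depth",
                     "within_day_sd", "diurnal_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class CovariateModel:
    """Marginal covariate distributions for simulated subjects (truncated
    normals / Bernoullis matching a typical adult type 1 diabetes cohort)."""

    hba1c_mean: float = 60.0  # mmol/mol
    hba1c_sd: float = 12.0
    age_mean: float = 46.0  # years, truncated to [18, 90]
    age_sd: float = 15.0
    bmi_mean: float = 26.5  # kg/m^2, truncated to [15, 50]
    bmi_sd: float = 5.0
    duration_mean: float = 27.0  # years
    duration_sd: float = 13.0
    p_male: float = 0.42
    p_university: float = 0.54
    time_with_aid_log_mean: float = 6.4  # log-days; exp(6.4) ~ 600 d
    time_with_aid_log_sd: float = 0.4


@dataclass
class SimCohortConfig:
    """Two-arm cohort configuration.

    ``hba1c_slope`` plants a linear dependence of each subject's mean
    glucose on baseline HbA1c (mmol/L per mmol/mol, centred at the HbA1c
    mean) so the covariate regression has recoverable structure;
    ``between_subject_sd`` adds residual subject-level spread.
    """

    arm_a: ArmConfig = field(default_factory=lambda: ArmConfig(
        n_subjects=79, mean_glucose=8.9, hypo_events_per_14d=5.6,
        meals_per_day=4.4, missing_fraction=0.015))
    arm_b: ArmConfig = field(default_factory=lambda: ArmConfig(
        n_subjects=60, mean_glucose=8.5, hypo_events_per_14d=4.7,
        meals_per_day=4.9, missing_fraction=0.035))
    n_days: int = DEFAULT_N_DAYS
    seed: int = 0
    hba1c_slope: float = 0.04
    between_subject_sd: float = 0.9
    covariates: CovariateModel = field(default_factory=CovariateModel)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimCohortConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        raw["arm_a"] = ArmConfig(**raw.get("arm_a", {}))
        raw["arm_b"] = ArmConfig(**raw.get("arm_b", {}))
        raw["covariates"] = CovariateModel(**raw.get("covariates", {}))
        return cls(**raw)


def _meal_pulse_shape(rise_min: float, decay_min: float) -> np.ndarray:
    """Unit-peak pulse sampled every 5 min: log-normal-shaped rise peaking at
    ``rise_min``, exponential decay with constant ``decay_min``; truncated
    where the tail falls below 1% of the peak."""
    t_max = rise_min + decay_min * math.log(100.0)
    t = np.arange(5.0, t_max + 5.0, 5.0)
    shape = np.where(
        t <= rise_min,
        np.exp(-0.5 * (np.log(t / rise_min) / 0.5) ** 2),
        np.exp(-(t - rise_min) / decay_min),
    )
    return shape


_WAKING_START_SLOT = 6 * 12  # 06:00
_WAKING_END_SLOT = 22 * 12  # 22:00
_DIP_EDGE = 7.5  # mmol/L at the dip shoulders
_DIP_RAMP_SLOTS = 4
_MIN_DIP_SEPARATION_SLOTS = 36  # 3 h between planted dip starts


def _lognormal_params(mean: float, sd: float) -> Tuple[float, float]:
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def simulate_trace(
    config: ArmConfig,
    n_days: int = DEFAULT_N_DAYS,
    seed: int = 0,
    subject_id: str = "sim",
    mean_glucose: Optional[float] = None,
) -> GlucoseTrace:
    """Simulate one subject's rastered trace.

    ``mean_glucose`` overrides the arm-level target (used by the cohort
    generator to plant subject-level structure).
    """
    rng = np.random.default_rng(seed)
    n = n_days * SLOTS_PER_DAY
    target_mean = config.mean_glucose if mean_glucose is None else mean_glucose

    # diurnal sinusoid peaking at the acrophase clock time
    hours = (np.arange(n) % SLOTS_PER_DAY) / 12.0
    g = config.diurnal_amplitude * np.cos(
        2 * np.pi * (hours - config.diurnal_acrophase_hour) / 24.0
    )

    # meal pulses: Poisson count per day, uniform start in waking hours
    shape = _meal_pulse_shape(config.meal_rise_minutes, config.meal_decay_minutes)
    mean_meal_lift = 0.0
    if config.meals_per_day > 0 and config.meal_peak_mean > 0:
        mu, sigma = _lognormal_params(config.meal_peak_mean, max(config.meal_peak_sd, 1e-9))
        for day in range(n_days):
            for _ in range(rng.poisson(config.meals_per_day)):
                start = day * SLOTS_PER_DAY + rng.integers(_WAKING_START_SLOT, _WAKING_END_SLOT)
                peak = rng.lognormal(mu, sigma)
                stop = min(start + shape.size, n)
                g[start:stop] += peak * shape[: stop - start]
        mean_meal_lift = config.meals_per_day * config.meal_peak_mean * shape.sum() / SLOTS_PER_DAY

    # AR(1) noise with stationary SD within_day_sd
    if config.within_day_sd > 0:
        s, phi = config.within_day_sd, config.ar1_phi
        eps = rng.standard_normal(n) * s * math.sqrt(1 - phi * phi)
        eps[0] = rng.normal(0.0, s)
        g += _signal.lfilter([1.0], [1.0, -phi], eps)

    # baseline chosen so the realized mean tracks the target despite the
    # strictly positive meal contribution
    g += target_mean - mean_meal_lift

    # soft lower floor: AID systems suspend insulin, so spontaneous drifts
    # below ~4 mmol/L are rare; planted dips are applied after this
    floor, width = 4.1, 0.6
    g = floor + width * np.logaddexp(0.0, (g - floor) / width)

    # planted hypoglycaemic dips
    n_dips = rng.poisson(config.hypo_events_per_14d * n_days / 14.0)
    if n_dips:
        starts = np.sort(rng.integers(0, max(n - 40, 1), size=n_dips))
        kept = []
        for st in starts:
            if not kept or st - kept[-1] >= _MIN_DIP_SEPARATION_SLOTS:
                kept.append(int(st))
        for st in kept:
            # per-dip nadir spread around the configured mean depth, so a
            # realistic minority of episodes cross the severe 3.0 threshold
            depth = config.hypo_depth * rng.lognormal(-0.125, 0.5)
            nadir = max(TIR_LOW - depth, GLUCOSE_MIN)
            core = int(round(rng.uniform(30.0, 90.0) / 5.0))
            k = np.arange(core)
            core_traj = 3.85 - (3.85 - nadir) * np.sin(np.pi * (k + 0.5) / core)
            ramp_in = np.linspace(_DIP_EDGE, TIR_LOW, _DIP_RAMP_SLOTS, endpoint=False)
            ramp_out = np.linspace(TIR_LOW, _DIP_EDGE, _DIP_RAMP_SLOTS + 1)[1:]
            traj = np.concatenate([ramp_in, core_traj, ramp_out])
            stop = min(st + traj.size, n)
            g[st:stop] = np.minimum(g[st:stop], traj[: stop - st])

    g = np.clip(g, GLUCOSE_MIN, GLUCOSE_MAX)

    # sensor dropout, applied last
    missing = np.zeros(n, dtype=bool)
    target_missing = config.missing_fraction
    if config.gap_pattern == "periodic_warmup":
        for day in range(0, n_days, config.warmup_interval_days):
            gap_start = day * SLOTS_PER_DAY + int(rng.integers(0, SLOTS_PER_DAY - 24))
            missing[gap_start : gap_start + 24] = True
        target_missing = max(0.0, target_missing - missing.mean())
    if target_missing > 0:
        missing |= rng.random(n) < target_missing
    g[missing] = np.nan

    return GlucoseTrace(subject_id, SIM_GRID_START, g, n_days)


def _draw_covariates(rng: np.random.Generator, cm: CovariateModel) -> dict:
    def trunc_normal(mean, sd, lo, hi):
        for _ in range(1000):
            x = rng.normal(mean, sd)
            if lo <= x <= hi:
                return float(x)
        return float(min(max(mean, lo), hi))

    age = trunc_normal(cm.age_mean, cm.age_sd, 18.0, 90.0)
    return {
        "hba1c_baseline": trunc_normal(cm.hba1c_mean, cm.hba1c_sd, 30.0, 120.0),
        "age": age,
        "bmi": trunc_normal(cm.bmi_mean, cm.bmi_sd, 15.0, 50.0),
        "diabetes_duration": trunc_normal(cm.duration_mean, cm.duration_sd, 1.0, age - 1.0),
        "gender": int(rng.random() < cm.p_male),
        "setting": int(rng.random() < cm.p_university),
        "time_with_aid": float(rng.lognormal(cm.time_with_aid_log_mean, cm.time_with_aid_log_sd)),
    }


def simulate_cohort(
    config: SimCohortConfig,
) -> Tuple[List[GlucoseTrace], List[SubjectRecord]]:
    """Simulate both arms: traces plus clinical covariates.

    Each subject's target mean glucose is
    ``arm.mean_glucose + hba1c_slope * (hba1c - hba1c_mean) + N(0, between_subject_sd)``,
    so mean glucose (and hence TIR) carries a recoverable linear HbA1c signal
    on top of the planted arm effect.
    """
    rng = np.random.default_rng(config.seed)
    traces: List[GlucoseTrace] = []
    records: List[SubjectRecord] = []
    for arm_code, arm, prefix in ((0, config.arm_a, "A"), (1, config.arm_b, "B")):
        for i in range(arm.n_subjects):
            sid = f"{prefix}{i + 1:03d}"
            cov = _draw_covariates(rng, config.covariates)
            subject_mean = (
                arm.mean_glucose
                + config.hba1c_slope * (cov["hba1c_baseline"] - config.covariates.hba1c_mean)
                + rng.normal(0.0, config.between_subject_sd)
            )
            subject_mean = float(np.clip(subject_mean, 5.0, 14.0))
            trace_seed = int(rng.integers(0, 2**31 - 1))
            traces.append(
                simulate_trace(arm, config.n_days, trace_seed, sid, mean_glucose=subject_mean)
            )
            records.append(SubjectRecord(subject_id=sid, aid_system=arm_code, **cov))
    return traces, records
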