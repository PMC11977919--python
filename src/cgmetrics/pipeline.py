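"""End-to-end cohort analysis: eligibility filtering, per-subject metrics,
two-arm comparison tables, covariate regressions, diurnal profiles and RoC
distribution fits.

Report tables round the way the study tables print (percent metrics and
rates to one decimal, AARC to two); raw unrounded values are always retained
in the machine-readable output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import events as ev
from . import io as cio
from . import metrics as met
from . import roc as rc
from . import stats as st
from .core import DEFAULT_N_DAYS, TBR2_CUT, TIR_LOW, GlucoseTrace, SubjectRecord
from .errors import UndefinedMetricsError

log = logging.getLogger("cgmetrics.pipeline")

#: Administrative exclusion reasons, applied in cohort-flow order before the
#: trace-based active-time filter.
ADMIN_EXCLUSIONS = ("emigrated", "no_pump", "denied", "no_response", "no_upload")


@dataclass
class AnalysisConfig:
    """Thresholds and window parameters, echoed into every report."""

    active_time_threshold: float = 85.0  # percent
    n_days: int = DEFAULT_N_DAYS
    hypo_threshold: float = TIR_LOW
    severe_threshold: float = TBR2_CUT
    roc_threshold: float = rc.ROC_THRESHOLD
    rebound_window_min: int = 120
    roc_step: int = 3

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class EligibilityReport:
    """Sequential cohort-flow ledger; always balances:
    ``final = invited - sum(exclusions.values())``."""

    invited: int
    exclusions: "OrderedDict[str, int]"
    final: int
    retained_ids: Tuple[str, ...] = ()

    def balanced(self) -> bool:
        return self.final == self.invited - sum(self.exclusions.values())


def apply_eligibility(
    traces: Dict[str, Optional[GlucoseTrace]],
    admin_flags: Dict[str, Optional[str]],
    config: Optional[AnalysisConfig] = None,
) -> Tuple[List[GlucoseTrace], EligibilityReport]:
    """Apply administrative exclusions, then the active-sensor-time filter.

    ``admin_flags`` maps every invited subject to an exclusion reason from
    :data:`ADMIN_EXCLUSIONS` or None; subjects surviving the administrative
    stage must have a trace in ``traces``, which is then filtered on
    ``active_cgm_time >= active_time_threshold``.
    """
    config = config or AnalysisConfig()
    counts: "OrderedDict[str, int]" = OrderedDict((r, 0) for r in ADMIN_EXCLUSIONS)
    counts["low_active_time"] = 0
    survivors = []
    for sid, flag in admin_flags.items():
        if flag is None:
            survivors.append(sid)
        elif flag in counts:
            counts[flag] += 1
            log.info("excluded %s: %s", sid, flag)
        else:
            raise ValueError(f"unknown exclusion flag {flag!r} for subject {sid!r}")
    retained = []
    for sid in survivors:
        tr = traces.get(sid)
        if tr is None:
            raise ValueError(f"subject {sid!r} passed administrative filters but has no trace")
        active = cio.active_cgm_time(tr)
        if active >= config.active_time_threshold:
            retained.append(tr)
        else:
            counts["low_active_time"] += 1
            log.info("excluded %s: active time %.1f%% < %.0f%%", sid, active,
                     config.active_time_threshold)
    report = EligibilityReport(
        invited=len(admin_flags),
        exclusions=counts,
        final=len(retained),
        retained_ids=tuple(t.subject_id for t in retained),
    )
    assert report.balanced()
    return retained, report


@dataclass
class SubjectMetrics:
    """Full per-subject glycaemic summary (the study's per-subject row)."""

    subject_id: str
    active_cgm_time: float
    mean_glucose: float
    sd_glucose: float
    cv: float
    gmi: float
    tir: float
    titr: float
    tar: float
    tar2: float
    tbr: float
    tbr2: float
    trc_plus: float
    trc_minus: float
    trc: float
    aarc: float
    hypo_per_14d: float
    severe_per_14d: float
    rebound_per_14d: float
    rebound_fraction: Optional[float]

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def compute_subject_metrics(
    trace: GlucoseTrace, config: Optional[AnalysisConfig] = None
) -> SubjectMetrics:
    """Range, variability, rate-of-change and event metrics for one trace."""
    config = config or AnalysisConfig()
    rm = met.range_metrics(trace)
    series = rc.roc_series(trace, step=config.roc_step)
    try:
        trc = rc.trc_metrics(series, threshold=config.roc_threshold)
    except UndefinedMetricsError:
        trc = rc.TrcMetrics(np.nan, np.nan, np.nan, np.nan)
    hypo = ev.detect_events(trace, config.hypo_threshold)
    severe = ev.detect_events(trace, config.severe_threshold, with_rebound=False)
    rates = ev.event_rates(hypo, trace, severe_events=severe)
    return SubjectMetrics(
        subject_id=trace.subject_id,
        active_cgm_time=cio.active_cgm_time(trace),
        mean_glucose=rm.mean_glucose,
        sd_glucose=rm.sd_glucose,
        cv=rm.cv,
        gmi=rm.gmi,
        tir=rm.tir,
        titr=rm.titr,
        tar=rm.tar,
        tar2=rm.tar2,
        tbr=rm.tbr,
        tbr2=rm.tbr2,
        trc_plus=trc.trc_plus,
        trc_minus=trc.trc_minus,
        trc=trc.trc,
        aarc=trc.aarc,
        hypo_per_14d=rates.hypo_per_14d,
        severe_per_14d=rates.severe_per_14d,
        rebound_per_14d=rates.rebound_per_14d,
        rebound_fraction=rates.rebound_fraction,
    )


def metrics_table(
    traces: Iterable[GlucoseTrace], config: Optional[AnalysisConfig] = None
) -> pd.DataFrame:
    """One row of :class:`SubjectMetrics` per trace."""
    rows = [compute_subject_metrics(t, config).as_dict() for t in traces]
    return pd.DataFrame(rows).set_index("subject_id")


# Which two-sample test each reported metric uses: mean-like metrics use the
# pooled t-test, skewed metrics the Mann-Whitney / Hodges-Lehmann route.
METRIC_METHODS = OrderedDict(
    [
        ("mean_glucose", "t"),
        ("sd_glucose", "t"),
        ("cv", "t"),
        ("gmi", "t"),
        ("tar2", "mwu"),
        ("tar", "t"),
        ("tir", "t"),
        ("titr", "t"),
        ("tbr", "mwu"),
        ("tbr2", "mwu"),
        ("active_cgm_time", "mwu"),
        ("hypo_per_14d", "mwu"),
        ("severe_per_14d", "mwu"),
        ("rebound_per_14d", "mwu"),
        ("rebound_fraction", "t"),
        ("trc", "mwu"),
        ("trc_plus", "mwu"),
        ("trc_minus", "mwu"),
        ("aarc", "t"),
    ]
)

_ROUND_2DP = {"aarc"}


def compare_arms(
    table: pd.DataFrame, arm: pd.Series, metrics: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Arm-B-minus-arm-A comparison of every metric column.

    ``arm`` is a subject-indexed series coded 0 (arm A) / 1 (arm B).
    Returns the comparison table with raw and print-rounded columns.
    """
    metrics = list(metrics or [m for m in METRIC_METHODS if m in table.columns])
    rows = []
    for m in metrics:
        vals = table[m].astype(float)
        a = vals[arm.reindex(vals.index) == 0].dropna().to_numpy()
        b = vals[arm.reindex(vals.index) == 1].dropna().to_numpy()
        if a.size < 2 or b.size < 2:
            warnings.warn(f"metric {m!r}: too few subjects per arm, skipped")
            continue
        if METRIC_METHODS.get(m) == "t":
            cmp_ = st.compare_means(a, b, name=m)
        else:
            cmp_ = st.compare_medians(a, b, name=m)
        nd = 2 if m in _ROUND_2DP else 1
        rows.append(
            {
                "metric": m,
                "method": cmp_.method,
                "group_a": round(cmp_.group_a_summary[0], nd),
                "group_b": round(cmp_.group_b_summary[0], nd),
                "difference": round(cmp_.difference, nd),
                "ci_low": round(cmp_.ci95[0], nd),
                "ci_high": round(cmp_.ci95[1], nd),
                "p": cmp_.p_value,
                "difference_raw": cmp_.difference,
                "ci_low_raw": cmp_.ci95[0],
                "ci_high_raw": cmp_.ci95[1],
            }
        )
    return pd.DataFrame(rows).set_index("metric")


@dataclass
class AnalysisResult:
    """Bundle produced by :func:`run_analysis`."""

    config: AnalysisConfig
    metrics: pd.DataFrame
    comparison: Optional[pd.DataFrame]
    regressions: Dict[str, st.RegressionFit]
    diurnal: Dict[str, pd.DataFrame]
    roc_fits: Dict[str, rc.TLocScaleFit]
    eligibility: Optional[EligibilityReport] = None

    def write(self, outdir) -> None:
        """Write the bundle as delimited tables plus a JSON report."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.metrics.round(4).to_csv(out / "subject_metrics.csv")
        if self.comparison is not None:
            self.comparison.to_csv(out / "comparison.csv")
        for name, prof in self.diurnal.items():
            prof.to_csv(out / f"diurnal_{name}.csv", index=False)
        payload = {
            "config": self.config.to_dict(),
            "roc_fits": {
                k: {"location": f.location, "scale": f.scale, "df": f.df,
                    "sd": f.sd, "loglik": f.loglik, "n": f.n}
                for k, f in self.roc_fits.items()
            },
            "regressions": {
                k: {
                    "r_squared": v.r_squared,
                    "n": v.n,
                    "coefficients": {
                        str(i): {"beta": r.beta, "ci_low": r.ci_low,
                                 "ci_high": r.ci_high, "p": r.p}
                        for i, r in v.coefficients.iterrows()
                    },
                    "p_values_unadjusted": True,
                }
                for k, v in self.regressions.items()
            },
        }
        if self.eligibility is not None:
            payload["eligibility"] = {
                "invited": self.eligibility.invited,
                "exclusions": dict(self.eligibility.exclusions),
                "final": self.eligibility.final,
            }
        with open(out / "report.json", "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)


def run_analysis(
    traces: Sequence[GlucoseTrace],
    records: Sequence[SubjectRecord],
    config: Optional[AnalysisConfig] = None,
    eligibility: Optional[EligibilityReport] = None,
) -> AnalysisResult:
    """Compute the full report bundle for an ingested cohort.

    With fewer than two subjects in either arm the comparison and regression
    stages are skipped with a warning; per-subject metrics are always
    emitted.
    """
    config = config or AnalysisConfig()
    table = metrics_table(traces, config)
    by_id = {r.subject_id: r for r in records}
    for tr in traces:
        if tr.subject_id in by_id:
            by_id[tr.subject_id].metrics = compute_subject_metrics(tr, config)
    arm = pd.Series({r.subject_id: r.aid_system for r in records})
    arm = arm.reindex(table.index)

    arm_traces = {
        "arm_a": [t for t in traces if arm.get(t.subject_id) == 0],
        "arm_b": [t for t in traces if arm.get(t.subject_id) == 1],
    }
    diurnal = {k: met.diurnal_profile(v) for k, v in arm_traces.items() if v}

    roc_fits = {}
    for name, tlist in arm_traces.items():
        pooled = np.concatenate(
            [rc.roc_series(t, step=config.roc_step).slopes for t in tlist]
        ) if tlist else np.empty(0)
        if pooled.size >= 50:
            roc_fits[name] = rc.fit_t_location_scale(pooled)

    comparison = None
    regressions: Dict[str, st.RegressionFit] = {}
    n_a, n_b = (arm == 0).sum(), (arm == 1).sum()
    if n_a >= 2 and n_b >= 2:
        comparison = compare_arms(table, arm)
        analysed = [by_id[s] for s in table.index if s in by_id and by_id[s].metrics]
        for resp in ("tir", "titr"):
            try:
                regressions[resp] = st.fit_regression(analysed, resp)
            except (ValueError, st.CollinearityError) as exc:  # pragma: no cover
                warnings.warn(f"regression on {resp} skipped: {exc}")
    else:
        warnings.warn("fewer than 2 subjects in an arm: comparisons skipped")

    return AnalysisResult(config, table, comparison, regressions, diurnal,
                          roc_fits, eligibility)


def load_cohort_dir(cohort_dir, covariates_path=None, n_days: int = DEFAULT_N_DAYS):
    """Load a directory of generic-dialect trace exports (and an optional
    covariate table) into traces + records."""
    cohort_dir = Path(cohort_dir)
    traces = []
    for f in sorted(cohort_dir.glob("*.csv")):
        if covariates_path and Path(covariates_path).resolve() == f.resolve():
            continue
        if f.name == "covariates.csv":
            continue
        stream = cio.parse_cgm_export(f, dialect="generic")
        traces.append(cio.grid_trace(stream, n_days=n_days))
    records = []
    if covariates_path is None and (cohort_dir / "covariates.csv").exists():
        covariates_path = cohort_dir / "covariates.csv"
    if covariates_path is not None:
        df = pd.read_csv(covariates_path, dtype={"subject_id": str})
        for _, row in df.iterrows():
            records.append(
                SubjectRecord(
                    subject_id=str(row["subject_id"]),
                    aid_system=int(row["aid_system"]),
                    hba1c_baseline=float(row["hba1c_baseline"]),
                    age=float(row["age"]),
                    time_with_aid=float(row["time_with_aid"]),
                    setting=int(row["setting"]),
                    diabetes_duration=float(row["diabetes_duration"]),
                    gender=int(row["gender"]),
                    bmi=float(row["bmi"]),
                )
            )
    return traces, records


def write_cohort_dir(traces, records, outdir) -> None:
    """Write traces in the generic export dialect plus a covariate table."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for tr in traces:
        with open(out / f"{tr.subject_id}.csv", "w", encoding="utf-8") as fh:
            fh.write("timestamp,glucose_mmol_l\n")
            for i, v in enumerate(tr.values):
                if not np.isnan(v):
                    fh.write(f"{tr.slot_time(i).isoformat(sep=' ')},{v:.4f}\n")
    if records:
        st.records_frame(records).assign(
            time_with_aid=[r.time_with_aid for r in records]
        ).drop(columns=["time_with_aid_months"]).to_csv(out / "covariates.csv")
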