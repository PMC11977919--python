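# Methods

This note documents the analytical conventions, the synthetic-data model,
and the numerically delicate choices in cgmetrics. It states no empirical
claim that the test suite does not itself compute.

## Rastering and the analysis window

All analysis happens on a fixed 5-min raster. The window is the `n_days`
(default 60) calendar days ending with the day of the last sample (or an
explicit `window_end`), and the grid is anchored at midnight of the
window's first day. Midnight anchoring makes diurnal binning exact in clock
time; the alternative — anchoring at the first sample — would smear
clock-hour bins across subjects. Raw samples are assigned to the nearest
slot, with ties broken toward the earlier slot, making assignment
deterministic and symmetric under ±2 min of sensor timestamp jitter.
Duplicate timestamps and multiple samples landing in one slot are averaged
(order-independent). Timestamps are treated as naive local clock time;
daylight-saving duplications collapse under the duplicate rule. Glucose
outside 1.0–30.0 mmol/L (beyond commercial sensor reporting ranges) is
rejected at parse time and counted in the parse report, whose fields always
reconcile row-for-row with the input.

Active CGM time divides by the *full* window (17,280 slots for 60 days);
every other metric divides by the number of present values only.

## Metric conventions

Ranges written "a to b" are closed intervals; "above"/"below" cut-offs are
strict. So a reading of exactly 10.0 mmol/L is in range, not above it; the
comparator lives in one function (`metrics.range_masks`) so the convention
cannot drift between metrics. SD is the sample standard deviation (n−1).
GMI is the linear map 4.70587·mean + 12.71 (mmol/mol), kept unrounded
internally; report tables round to one decimal (two for AARC).

Diurnal profiles pool all present values by clock hour across days and
subjects (hourly bins are the conventional ambulatory-glucose-profile
display; the bin width is a parameter). Pooling across subjects is the
default; empty bins are flagged, not zeroed. Pump-settings step profiles
must tile 24 h exactly; their time-weighted mean is Σ(value·minutes)/1440.

## Rate of change

RoC windows span four consecutive slots (t = 0, 5, 10, 15 min) and advance
in steps of three slots, so adjacent windows share one endpoint — the
reading at t = 15 of one window is t = 0 of the next. This follows from the
window being defined by four points spanning exactly 15 min; a fully
disjoint tiling (step 4) is available as an option. The slope is the exact
closed-form OLS solution with abscissae 0, 1/3, 2/3, 1 (15-min units),
reducing to a fixed inner product with weights (−0.9, −0.3, 0.3, 0.9).
Windows containing any missing slot are skipped, with no imputation, and
excluded from the TRC denominator: in cohorts restricted to ≥85% active
sensor time this discards little and is unbiased under
missingness-at-random. TRC thresholds are strict (a slope of exactly
±1.5 mmol/L/15 min is not rapid change).

The pooled RoC distribution is summarized by a three-parameter
t location-scale MLE. The optimizer is Nelder–Mead on (location,
log scale, log df) — the log transform keeps the positivity constraints
implicit — started from the sample median, the normal-consistent scaled MAD
(1.4826·MAD), and df = 5, with convergence at a log-likelihood improvement
below 1e-8. The fit is rejected (with the optimizer trajectory attached to
the error) if it fails to converge or ends below the starting
log-likelihood. The implied SD, scale·√(df/(df−2)), is NaN when df ≤ 2.
Tests cross-check the fit against an independent reference MLE
(scipy's built-in t fit). A Jones–Faddy skew-t alternative is available
behind a separate function but is not the default summary, since the
symmetric fit is the reporting convention.

## Event detection

The detector is a left-to-right finite-state scan. An episode opens at the
first of ≥3 consecutive present readings strictly below threshold and
closes only after ≥3 consecutive present readings at/above threshold;
shorter recoveries (1–2 slots) are absorbed into the episode. Missing slots
break consecutiveness for both the below-run and the recovery-run — gaps
are never bridged, because no imputation rule is defensible inside a
candidate event. A below-run still open at the end of the trace is censored
(not counted): the definition requires the recovery to be observed.
Severe episodes are detected by an independent scan at 3.0 mmol/L, not by
sub-classifying 3.9-events; a property test verifies that every severe
below-run nevertheless nests inside a hypoglycaemic episode's span.

The rebound window (24 slots = 120 min, strict >10.0 mmol/L) is anchored at
the first slot after the episode's last below-threshold reading — i.e., at
the start of recovery — matching the intent of post-recovery
hyperglycaemia; the window truncates at trace end. Rates are count·14/n_days;
the rebound fraction is undefined (None), not zero, when no event occurred.

The detector is verified exhaustively against a regular-expression oracle
(`L{3,}(H{1,2}L+)*(?=H{3})`) on every below/above pattern up to length 14.

## Cohort statistics

Comparisons are oriented arm B − arm A throughout. Mean-like metrics use
the pooled-variance (Student) t-test with a t-distribution CI; skewed
metrics (event rates, TBR, TRC, level-2 ranges, active time) use the
Mann–Whitney U test with the Hodges–Lehmann estimate — the median of all
n_a·n_b pairwise differences — and a CI whose endpoints are the k-th
extreme pairwise differences. k comes from the exact Mann–Whitney U null
distribution (a dynamic-programme over the standard recurrence) when
n_a·n_b ≤ 400, otherwise from the normal approximation; the p-value uses
exact enumeration at the same cut-off when there are no ties, else the
tie-corrected normal approximation. Proportions use Pearson χ² without
continuity correction (the correction is exposed as a flag) and a Wald
(unpooled) CI on the difference in percentage points.

The regression is OLS of TIR or TITR on seven covariates plus intercept,
with categorical codings fixed (arm: 0/1; gender: female 0, male 1;
setting: regional 0, university 1) and AID exposure entered in months
(days/30.44). Listwise deletion is applied and counted; a rank-deficient
design raises an error naming the offending columns. p-values are reported
unadjusted: the report mirrors a single pre-specified comparison table, and
no multiplicity correction is applied across its rows.

## Synthetic cohort generator

The generator produces the statistical structure the pipeline measures,
not glucose physiology. Per subject:

    g(t) = clamp( softfloor( baseline + diurnal + meals + AR(1) noise )
                  ∧ planted dips, 1.0, 30.0 )

- **Diurnal**: cosine with semi-amplitude 0.8 mmol/L peaking at 21:00.
- **Meals**: Poisson count per day (default 4.4–4.9 by arm) at uniform
  waking times (06:00–22:00); each pulse has a log-normal peak (mean
  3.5 mmol/L, SD 1.3), a log-normal-shaped rise peaking at 60 min and an
  exponential decay (120 min). The baseline is lowered by the expected meal
  lift so the realized mean tracks the configured mean.
- **Noise**: AR(1) at 5-min lag with φ = 0.985 and stationary SD
  2.1 mmol/L.
- **Soft floor** at ~4.1 mmol/L (softplus, width 0.6): AID systems suspend
  insulin approaching hypoglycaemia, so spontaneous drifts below 4 are
  rare; hypoglycaemia instead enters through explicitly planted dips, which
  keeps the planted event rate recoverable by the detector.
- **Dips**: Poisson events (default 5.6 / 4.7 per 14 days by arm), ≥3 h
  apart, each with a 30–90 min below-threshold core reaching a nadir
  3.9 − depth, where depth varies log-normally around the configured mean
  (0.7 mmol/L) so a realistic minority of episodes cross the severe
  3.0 mmol/L line; shoulders ramp from ~7.5 mmol/L.
- **Dropout**, applied last: i.i.d. slot dropout to the target missing
  fraction, or 2-h sensor-warm-up gaps every k days plus residual random
  dropout.

The free parameters (φ, noise SD, meal peak) were fixed once, by a pilot
run of the generator itself, so that default 60-day traces land at an
overall SD ≈ 3.0 mmol/L, CV ≈ 34%, TRC ≈ 7–9% and AARC ≈ 0.6–0.7
mmol/L/15 min — the magnitudes typical of adult AID cohorts — and were not
revisited. Covariates are drawn from truncated normals/Bernoullis typical
of an adult type 1 diabetes clinic population (HbA1c 60 ± 12 mmol/mol, age
46 ± 15 y, BMI 26.5 ± 5, duration 27 ± 13 y, 42% male, 54% university
setting, log-normal AID exposure around 600 days). Each subject's mean
glucose adds a planted linear HbA1c term (0.04 mmol/L per mmol/mol) and a
between-subject residual (SD 0.9 mmol/L), giving the regression recoverable
structure.

What the generator does *not* emulate: sensor error structure specific to
any vendor, insulin dosing dynamics, carbohydrate announcements, or
correlation between meals and hypoglycaemia. Passing round-trip tests
therefore demonstrates that the pipeline measures what the generator
plants — not that real sensors behave like the generator.

## Problem sizes in the test suite

The validation battery chooses sizes that make each check sharp but quick:
exhaustive event patterns to length 14; the Hodges–Lehmann grid to 30×30;
1,000 one-day random traces for the conservation laws; 50,000 draws for the
t MLE recovery; 500 replicates at n = 139 for the regression recovery;
50 sixty-day traces for the generator–detector round trip; and 8 cohort
replicates at the study's 79/60 arm sizes over a 20-day window for the
planted-difference power check, whose acceptance band was set by a pilot
run at that scale.

## Known limitations

- The 60-day window is calendar-contiguous and ends at the last upload;
  subjects with sparse recent data are handled by the active-time filter,
  not by searching for a denser historical window.
- Short sensor gaps inside candidate events are never bridged; detected
  event rates are therefore conservative at low active times.
- The Wald proportion CI and the normal-approximation Hodges–Lehmann CI are
  asymptotic; for very small arms the exact paths apply only up to
  n_a·n_b = 400.
- The t location-scale fit assumes symmetry of the RoC distribution; use
  the skew-t alternative to probe asymmetry.
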