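# cgmetrics

Analysis of raw continuous glucose monitoring (CGM) data for comparing
automated insulin delivery (AID) cohorts. The package takes per-subject CGM
exports (timestamp + glucose in mmol/L), aligns them to a fixed 5-min raster
over a 60-day window, and computes the consensus glycaemic metrics, glucose
rate-of-change statistics, debounced hypoglycaemia events with rebound
flags, and the two-arm statistical comparison — plus a synthetic two-arm
cohort generator so the whole pipeline can be exercised and validated
without patient data.

Intended users: diabetes-technology researchers and biostatisticians who
want consensus CGM metrics computed from raw sensor data with a consistent,
auditable method rather than vendor-platform summaries.

## What it computes

With sensor glucose $g_t$ (mmol/L) on a 5-min raster of $N = 288\,n_{days}$
slots (17,280 for 60 days):

- **Active CGM time** $= 100 \cdot \#\{\text{slots with a value}\} / N$;
  all other metrics divide by the number of *present* values.
- **Ranges**: TIR ($3.9 \le g \le 10.0$), TITR ($3.9 \le g \le 7.8$),
  TAR ($g > 10.0$), TAR level 2 ($g > 13.9$), TBR ($g < 3.9$), TBR level 2
  ($g < 3.0$); mean, sample SD, CV $= 100\,\mathrm{SD}/\bar g$, and
  **GMI** $= 4.70587\,\bar g + 12.71$ mmol/mol.
- **Rate of change (RoC)**: the OLS slope of glucose on time over each
  15-min window of four readings ($t = 0, 5, 10, 15$ min), in
  mmol/L per 15 min, windows advancing every 15 min. **TRC+/TRC−** are the
  percent of valid windows with slope $> +1.5$ / $< -1.5$; TRC is their
  sum; **AARC** is the mean $|$slope$|$. Pooled RoC values are summarized by
  a maximum-likelihood t location-scale fit
  $(\mu, \sigma, \nu)$ with implied SD $\sigma\sqrt{\nu/(\nu-2)}$.
- **Hypoglycaemia events**: $\ge 3$ consecutive readings $< 3.9$ mmol/L
  ($< 3.0$ for severe), closed only by $\ge 3$ consecutive readings at/above
  threshold; **rebound hyperglycaemia** is any reading $> 10$ mmol/L within
  120 min after the event. Rates are reported per 14 days.
- **Cohort statistics**, oriented arm B − arm A: pooled-variance t-test,
  Mann–Whitney U with Hodges–Lehmann median-difference CI, uncorrected
  χ² with a Wald CI for proportions, and OLS of TIR/TITR on seven clinical
  covariates (AID system, baseline HbA1c, age, months with AID, clinical
  setting, diabetes duration, gender, BMI).

## Worked example

Simulate a study-sized synthetic cohort (79 vs 60 subjects, 60 days) and run
the full analysis:

```python
from cgmetrics import AnalysisConfig, run_analysis
from cgmetrics.simulate import SimCohortConfig, simulate_cohort

traces, records = simulate_cohort(SimCohortConfig(seed=42))
res = run_analysis(traces, records, AnalysisConfig())
print(res.comparison.loc[["tir", "titr", "gmi"],
                         ["group_a", "group_b", "difference",
                          "ci_low", "ci_high", "p"]])
```

```
        group_a  group_b  difference  ci_low  ci_high         p
metric
tir        66.8     70.1         3.3    -0.5      7.2  0.090400
titr       40.1     44.7         4.6    -0.2      9.3  0.059100
gmi        54.0     52.7        -1.3    -2.8      0.3  0.103000
```

Arm B was generated with mean glucose 0.4 mmol/L below arm A, which
surfaces here as a ~3–5 point TIR/TITR advantage and a ~1.3 mmol/mol lower
GMI — the same ordering of effects the metrics are designed to resolve.
The RoC pool of each arm is heavy-tailed; the fitted t location-scale
summary for arm A is location −0.05, scale 0.60, df 3.6 (implied SD
0.89 mmol/L/15 min, n = 428,272 windows), and the TIR regression recovers
the planted negative HbA1c dependence (β = −0.40 per mmol/mol,
p < 10⁻⁶).

The same pipeline runs from the shell on a directory of CGM exports:

```bash
cgmetrics simulate -o cohort --seed 42     # or bring your own exports
cgmetrics report cohort -o results
```

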