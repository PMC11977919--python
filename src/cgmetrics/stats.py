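"""Two-arm cohort statistics: group comparisons and the covariate regression.

All comparisons are oriented as arm B minus arm A (in the study layout,
MM780G minus CIQ). Continuous outcomes judged normal are compared with the
pooled-variance (Student) unpaired t-test; skewed outcomes with the
Mann-Whitney U test, the point estimate and CI of the median difference
coming from the Hodges-Lehmann construction (median of all pairwise
differences, CI from Mann-Whitney critical values on the ordered pairwise
differences). Proportions are compared with an (uncorrected) Pearson chi^2
test and a Wald CI on the difference. The multiple regression is ordinary
least squares of TIR or TITR on the seven clinical covariates plus
intercept; p-values are reported unadjusted for multiplicity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .core import SubjectRecord
from .errors import CollinearityError, DegenerateSampleError

#: Days per month used to convert AID exposure from days to months.
DAYS_PER_MONTH = 30.44


@dataclass
class GroupComparison:
    """One between-arm contrast, oriented B - A."""

    statistic_name: str
    group_a_summary: Tuple[float, float]  # (mean, sd) or (median, iqr-width)
    group_b_summary: Tuple[float, float]
    difference: float
    ci95: Tuple[float, float]
    p_value: float
    method: str  # t_test | mann_whitney_hl | chi2_prop


def compare_means(a: Sequence[float], b: Sequence[float], name: str = "") -> GroupComparison:
    """Pooled-variance two-sample t-test; difference b - a with 95% t CI."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        raise DegenerateSampleError("zero pooled variance")
    diff = float(b.mean() - a.mean())
    se = float(np.sqrt(sp2 * (1 / na + 1 / nb)))
    dof = na + nb - 2
    tstat = diff / se
    p = 2 * sps.t.sf(abs(tstat), dof)
    half = sps.t.ppf(0.975, dof) * se
    return GroupComparison(
        name,
        (float(a.mean()), float(a.std(ddof=1))),
        (float(b.mean()), float(b.std(ddof=1))),
        diff,
        (diff - half, diff + half),
        float(p),
        "t_test",
    )


def _mwu_exact_cdf(m: int, n: int) -> np.ndarray:
    """Exact null CDF of the Mann-Whitney U statistic for sizes (m, n).

    Dynamic programme over the recurrence
    ``f(u; m, n) = f(u - n; m - 1, n) + f(u; m, n - 1)``.
    """
    max_u = m * n
    # table[i][j] = count vector over u for sizes (i, j)
    counts = np.zeros((m + 1, n + 1, max_u + 1))
    counts[0, :, 0] = 1.0
    counts[:, 0, 0] = 1.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            c = counts[i, j - 1].copy()
            shifted = np.zeros(max_u + 1)
            shifted[j:] = counts[i - 1, j, : max_u + 1 - j]
            counts[i, j] = c + shifted
    pmf = counts[m, n]
    pmf /= pmf.sum()
    return np.cumsum(pmf)


def _hl_critical_rank(m: int, n: int, exact_limit: int = 400) -> int:
    """Number of extreme pairwise differences to trim on each side for a
    (conservative) 95% Hodges-Lehmann CI."""
    K = m * n
    if K <= exact_limit:
        cdf = _mwu_exact_cdf(m, n)
        # largest k with P(U <= k - 1) <= 0.025  ->  trim k-1 .. use k index
        k = int(np.searchsorted(cdf, 0.025, side="right"))
    else:
        mu = K / 2.0
        sigma = np.sqrt(m * n * (m + n + 1) / 12.0)
        k = int(np.floor(mu - sps.norm.ppf(0.975) * sigma))
    return max(k, 0)


def compare_medians(a: Sequence[float], b: Sequence[float], name: str = "") -> GroupComparison:
    """Mann-Whitney U p-value with Hodges-Lehmann estimate and CI (b - a).

    The point estimate is the median of all n_a*n_b pairwise differences;
    the CI endpoints are the k-th smallest/largest pairwise differences with
    k from the exact U distribution when n_a*n_b <= 400, otherwise from the
    normal approximation. The p-value uses exact enumeration at the same
    size cut-off (ties force the tie-corrected normal approximation).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each sample needs n >= 3")
    diffs = np.sort(np.subtract.outer(b, a).ravel())
    est = float(np.median(diffs))
    K = diffs.size

    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (K <= 400 and not has_ties) else "asymptotic"
    p = float(sps.mannwhitneyu(b, a, alternative="two-sided", method=method).pvalue)

    k = _hl_critical_rank(b.size, a.size)
    lo = float(diffs[k]) if k < K else float(diffs[0])
    hi = float(diffs[K - 1 - k]) if k < K else float(diffs[-1])

    def _summ(x):
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        return (float(med), float(q3 - q1))

    return GroupComparison(name, _summ(a), _summ(b), est, (lo, hi), p, "mann_whitney_hl")


def compare_proportions(
    k_a: int, n_a: int, k_b: int, n_b: int, name: str = "", yates: bool = False
) -> GroupComparison:
    """Pearson chi^2 test (no continuity correction by default) with a Wald
    95% CI on the difference in percentage points, oriented b - a."""
    for k, n in ((k_a, n_a), (k_b, n_b)):
        if n < 1 or not 0 <= k <= n:
            raise ValueError("counts must satisfy 0 <= k <= n, n >= 1")
    table = np.array([[k_a, n_a - k_a], [k_b, n_b - k_b]])
    if table.sum(axis=0).min() == 0:  # degenerate margin: no chi2 defined
        p = 1.0
    else:
        p = float(sps.chi2_contingency(table, correction=yates)[1])
    pa, pb = k_a / n_a, k_b / n_b
    diff = 100.0 * (pb - pa)
    se = 100.0 * np.sqrt(pa * (1 - pa) / n_a + pb * (1 - pb) / n_b)
    z = sps.norm.ppf(0.975)
    return GroupComparison(
        name,
        (100.0 * pa, float(n_a)),
        (100.0 * pb, float(n_b)),
        diff,
        (diff - z * se, diff + z * se),
        p,
        "chi2_prop",
    )


#: Regression design columns, in report order.
REGRESSION_COVARIATES = [
    "aid_system",
    "hba1c_baseline",
    "age",
    "time_with_aid_months",
    "setting",
    "diabetes_duration",
    "gender",
    "bmi",
]


@dataclass
class RegressionFit:
    """OLS fit of a glycaemic outcome on the clinical covariates."""

    response: str
    coefficients: pd.DataFrame  # index: const + covariates; beta, ci_low, ci_high, p
    r_squared: float
    n: int
    n_dropped: int
    results: object = field(repr=False, default=None)  # statsmodels results

    def summary(self) -> str:
        lines = [f"OLS: {self.response} ~ covariates  (n={self.n}, "
                 f"dropped={self.n_dropped}, R^2={self.r_squared:.2f})"]
        for name, row in self.coefficients.iterrows():
            lines.append(
                f"  {name:<22s} {row.beta:8.2f}  ({row.ci_low:.2f} to {row.ci_high:.2f})"
                f"  p={row.p:.3g}"
            )
        return "\n".join(lines)


def records_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Tidy covariate frame (AID exposure converted to months)."""
    rows = []
    for r in records:
        rows.append(
            {
                "subject_id": r.subject_id,
                "aid_system": r.aid_system,
                "hba1c_baseline": r.hba1c_baseline,
                "age": r.age,
                "time_with_aid_months": (
                    r.time_with_aid / DAYS_PER_MONTH if r.time_with_aid is not None else np.nan
                ),
                "setting": r.setting,
                "diabetes_duration": r.diabetes_duration,
                "gender": r.gender,
                "bmi": r.bmi,
            }
        )
    return pd.DataFrame(rows).set_index("subject_id")


def fit_regression(
    records: Sequence[SubjectRecord],
    response: str = "tir",
    response_values: Optional[Dict[str, float]] = None,
) -> RegressionFit:
    """OLS of a per-subject metric on the seven covariates plus intercept.

    The response is taken from each record's attached ``metrics`` (attribute
    ``response``, e.g. ``tir`` or ``titr``) unless ``response_values`` maps
    subject ids to values directly. Rows with any missing covariate or
    response are dropped (listwise) and counted. Raises
    :class:`CollinearityError`, naming the offending columns, when the design
    is singular.
    """
    X = records_frame(records)
    if response_values is not None:
        y = pd.Series({str(k): v for k, v in response_values.items()}, name=response)
    else:
        y = pd.Series(
            {r.subject_id: getattr(r.metrics, response, np.nan) for r in records},
            name=response,
        )
    y = y.reindex(X.index).astype(float)
    data = X.assign(**{response: y})
    complete = data.dropna()
    n_dropped = len(data) - len(complete)
    n = len(complete)
    if n <= len(REGRESSION_COVARIATES) + 1:
        raise ValueError(f"need n > {len(REGRESSION_COVARIATES) + 1} complete rows, got {n}")

    design = sm.add_constant(complete[REGRESSION_COVARIATES], has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        bad = _singular_columns(design)
        raise CollinearityError(f"singular design; offending columns: {bad}", bad)
    res = sm.OLS(complete[response], design).fit()
    ci = res.conf_int(alpha=0.05)
    coef = pd.DataFrame(
        {"beta": res.params, "ci_low": ci[0], "ci_high": ci[1], "p": res.pvalues}
    )
    return RegressionFit(response, coef, float(res.rsquared), n, n_dropped, res)


def _singular_columns(design: pd.DataFrame) -> Tuple[str, ...]:
    bad = [c for c in design.columns if c != "const" and design[c].nunique() <= 1]
    cols = [c for c in design.columns if c != "const"]
    corr = design[cols].corr().abs()
    for i, c1 in enumerate(cols):
        for c2 in cols[i + 1 :]:
            if corr.loc[c1, c2] > 1 - 1e-10:
                bad.extend([c1, c2])
    return tuple(dict.fromkeys(bad)) or tuple(cols)
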