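"""Between-group comparison machinery for trial outcomes.

Pearson chi-square (no continuity correction) for categorical outcomes,
one-way ANOVA with Tukey pairwise comparisons for symmetrically distributed
variables, Kruskal-Wallis with pairwise Wilcoxon rank-sum and Holm-corrected
p-values for asymmetric variables, and OLS slopes for the association and
sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class TestResult:
    statistic: float
    df: float | None
    p_value: float
    method: str

    def __post_init__(self):
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value must lie in [0, 1]")


@dataclass
class ContingencyTable:
    """Groups x outcome-level counts."""

    counts: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        if np.any(self.counts < 0) or not np.all(self.counts == np.round(self.counts)):
            raise ValueError("counts must be non-negative integers")
        r, c = self.counts.shape
        if len(self.row_labels) != r or len(self.col_labels) != c:
            raise ValueError("label lengths must match the count matrix")

    @classmethod
    def from_events(cls, events, totals, groups=("CON", "EXE", "MOT")):
        """Binary outcome: a groups x 2 table of (event, non-event) counts."""
        events = np.asarray(events, dtype=int)
        totals = np.asarray(totals, dtype=int)
        if np.any(events > totals):
            raise ValueError("event counts cannot exceed group totals")
        return cls(
            np.stack([events, totals - events], axis=1),
            tuple(groups),
            ("event", "no_event"),
        )

    @classmethod
    def from_series(cls, values: pd.Series, labels: pd.Series):
        tab = pd.crosstab(labels, values)
        return cls(tab.to_numpy(), tuple(map(str, tab.index)), tuple(map(str, tab.columns)))


def pearson_chi2(table: ContingencyTable) -> TestResult:
    """Pearson chi-square test of independence, no continuity correction."""
    counts = table.counts
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("every row and column must have a positive marginal total")
    chi2, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return TestResult(float(chi2), float(df), float(p), "pearson_chi2")


def _split_groups(values, labels):
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if len(values) != len(labels):
        raise ValueError("values and labels must have equal length")
    keys = pd.unique(labels)
    return keys, [values[labels == k] for k in keys]


def one_way_anova(values, labels) -> TestResult:
    """One-way ANOVA F-test across the label groups."""
    keys, groups = _split_groups(values, labels)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least two observations")
    ssw = sum(np.sum((g - g.mean()) ** 2) for g in groups)
    if ssw == 0:
        raise ValueError("zero within-group variance; F is undefined")
    f, p = stats.f_oneway(*groups)
    df1 = len(groups) - 1
    df2 = sum(len(g) for g in groups) - len(groups)
    return TestResult(float(f), float(df1), float(p), f"anova F({df1},{df2})")


def tukey_pairwise(values, labels) -> pd.DataFrame:
    """Tukey HSD: simultaneous pairwise mean differences with adjusted p and 95% CIs."""
    keys, groups = _split_groups(values, labels)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least two observations")
    res = stats.tukey_hsd(*groups)
    ci = res.confidence_interval(0.95)
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            rows.append(
                {
                    "group_a": str(keys[i]),
                    "group_b": str(keys[j]),
                    "difference": float(res.statistic[i, j]),
                    "ci_low": float(ci.low[i, j]),
                    "ci_high": float(ci.high[i, j]),
                    "p_adj": float(res.pvalue[i, j]),
                }
            )
    return pd.DataFrame(rows)


def kruskal_wallis(values, labels) -> TestResult:
    """Kruskal-Wallis H (midranks, tie-corrected), chi-square approximation."""
    keys, groups = _split_groups(values, labels)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if sum(len(g) for g in groups) < 3:
        raise ValueError("need at least three observations in total")
    allv = np.concatenate(groups)
    if np.all(allv == allv[0]):
        raise ValueError("all values identical; tie correction is degenerate")
    h, p = stats.kruskal(*groups)
    return TestResult(float(h), float(len(groups) - 1), float(p), "kruskal_wallis")


def holm_adjust(p_values) -> np.ndarray:
    """Step-down Holm adjustment, returned in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_max = 0.0
    for rank, idx in enumerate(order):
        running_max = max(running_max, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running_max)
    return adjusted


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when both samples have n <= 8 and there are no ties;
    otherwise the Normal approximation with continuity and tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    no_ties = len(np.unique(combined)) == len(combined)
    if np.all(combined == combined[0]):
        return TestResult(float(len(x) * len(y) / 2.0), None, 1.0, "wilcoxon_rank_sum")
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and no_ties) else "asymptotic"
    u, p = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(float(u), None, float(min(p, 1.0)), f"wilcoxon_rank_sum[{method}]")


def wilcoxon_holm_pairwise(values, labels) -> pd.DataFrame:
    """All pairwise rank-sum tests with Holm-corrected p-values."""
    keys, groups = _split_groups(values, labels)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group must be non-empty")
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            res = wilcoxon_rank_sum(groups[i], groups[j])
            rows.append(
                {
                    "group_a": str(keys[i]),
                    "group_b": str(keys[j]),
                    "statistic": res.statistic,
                    "p_raw": res.p_value,
                    "method": res.method,
                }
            )
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_adjust(out["p_raw"].to_numpy())
    return out


@dataclass
class SlopeResult:
    slope: float
    ci_low: float
    ci_high: float
    p_value: float
    stderr: float


def linear_regression_slope(x, y) -> SlopeResult:
    """OLS slope of y on x with t-based 95% CI and two-sided p-value.

    Degenerate perfect fits are handled explicitly: zero residual variance
    collapses the CI to a point, with p = 1 for a zero slope (no evidence of
    association is distinguishable from a flat, noiseless response) and p = 0
    for a non-zero slope.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least three observations")
    if np.var(x) == 0:
        raise ValueError("x is constant; the slope is undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    slope = float(model.params[1])
    if model.mse_resid < 1e-24 or not np.isfinite(model.bse[1]):
        p = 1.0 if abs(slope) < 1e-12 else 0.0
        return SlopeResult(slope, slope, slope, p, 0.0)
    lo, hi = model.conf_int(alpha=0.05)[1]
    return SlopeResult(slope, float(lo), float(hi), float(model.pvalues[1]), float(model.bse[1]))


def covid_sensitivity(gwg, covid_flag, labels) -> pd.DataFrame:
    """Per-arm OLS of total GWG on the COVID-period indicator.

    The slope is the estimated difference in total GWG for participants
    enrolled during versus before the pandemic period, within each arm.
    """
    gwg = np.asarray(gwg, dtype=float)
    covid = np.asarray(covid_flag, dtype=float)
    labels = np.asarray(labels)
    rows = []
    for g in pd.unique(labels):
        m = labels == g
        if len(np.unique(covid[m])) < 2 or m.sum() < 3:
            rows.append({"group": str(g), "difference": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "p_value": np.nan})
            continue
        res = linear_regression_slope(covid[m], gwg[m])
        rows.append({"group": str(g), "difference": res.slope, "ci_low": res.ci_low,
                     "ci_high": res.ci_high, "p_value": res.p_value})
    return pd.DataFrame(rows)


def pa_gwg_association(pa_values, gwg) -> SlopeResult:
    """Association between a physical-activity summary and total GWG (all arms pooled)."""
    pa = np.asarray(pa_values, dtype=float)
    gwg = np.asarray(gwg, dtype=float)
    ok = np.isfinite(pa) & np.isfinite(gwg)
    return linear_regression_slope(pa[ok], gwg[ok])
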