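"""Group-comparison and correlation statistics for the clinical tables.

Covers the statistical battery that accompanies the classification
analysis: two-sample t-tests (from raw data or published mean/SD/n
summaries), Pearson chi-square tests of count tables, component-by-clinical
Pearson correlation tables with Bonferroni control, one-way ANOVA, and the
Games-Howell pairwise post-hoc test for unequal variances and group sizes.

The default t-test pools variances (Student), which reproduces summary
tables computed that way; Welch's correction is available via
``equal_var=False``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SummaryGroup",
    "TestResult",
    "ttest_from_summary",
    "ttest_raw",
    "chi_square",
    "correlation_table",
    "anova_oneway",
    "games_howell",
    "CLINICAL_VARS",
]

#: Default clinical rows of the component correlation table (binary
#: variables enter as 0/1, i.e. point-biserial correlation).
CLINICAL_VARS = [
    "sex", "age", "education",
    "MMSE", "CDR_global", "CDR_sum", "FAQ", "LM_I", "LM_II", "ADAS_cog_J",
    "WF_category", "WF_initial", "TMT_A", "TMT_B", "JART",
    "ab_positivity",
]


@dataclass
class SummaryGroup:
    """Published group summary: mean, SD, and sample size."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    @classmethod
    def of(cls, x) -> "SummaryGroup":
        x = np.asarray(x, dtype=float)
        return cls(mean=float(x.mean()), sd=float(x.std(ddof=1)),
                   n=int(x.size))


@dataclass
class TestResult:
    """A test statistic with its degrees of freedom and p-value."""

    statistic: float
    df: float | tuple[float, float]
    p: float
    method: str
    adjusted_p: float | None = None
    detail: dict | None = None

    def __post_init__(self) -> None:
        if np.isfinite(self.p) and not 0.0 <= self.p <= 1.0 + 1e-12:
            raise ValueError(f"p-value {self.p} outside [0, 1]")


def ttest_from_summary(
    g1: SummaryGroup, g2: SummaryGroup, equal_var: bool = True
) -> TestResult:
    """Two-sample t-test from mean/SD/n summaries (two-tailed).

    ``equal_var=True`` pools variances (df = n1+n2-2); ``False`` applies
    the Welch-Satterthwaite correction.
    """
    if g1.n < 2 or g2.n < 2:
        raise ValueError("both groups need n >= 2 for a t-test")
    if g1.sd == 0 and g2.sd == 0 and g1.mean == g2.mean:
        df = g1.n + g2.n - 2
        return TestResult(0.0, df, 1.0, "t (pooled)" if equal_var else "t (Welch)")
    res = sps.ttest_ind_from_stats(
        g1.mean, g1.sd, g1.n, g2.mean, g2.sd, g2.n, equal_var=equal_var
    )
    if equal_var:
        df = float(g1.n + g2.n - 2)
        method = "t (pooled)"
    else:
        v1, v2 = g1.sd**2 / g1.n, g2.sd**2 / g2.n
        df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
        method = "t (Welch)"
    return TestResult(float(res.statistic), df, float(res.pvalue), method)


def ttest_raw(x1, x2, equal_var: bool = True) -> TestResult:
    """Two-sample t-test on raw values; identical to the summary version
    applied to the samples' mean/SD/n."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise ValueError("both samples need n >= 2")
    return ttest_from_summary(
        SummaryGroup.of(x1), SummaryGroup.of(x2), equal_var=equal_var
    )


def chi_square(table, correction: bool = False) -> TestResult:
    """Pearson chi-square test of independence on a count table.

    No Yates continuity correction by default.  Rows or columns with a zero
    margin are dropped with a warning; df = (r-1)(c-1) on the reduced table.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need a table with >= 2 rows and >= 2 columns")
    if np.any(obs < 0) or np.any(obs != np.round(obs)):
        raise ValueError("counts must be non-negative integers")
    if obs.sum() == 0:
        raise ValueError("all-zero count table")

    row_ok = obs.sum(axis=1) > 0
    col_ok = obs.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        warnings.warn(
            "dropping zero-margin rows/columns from the chi-square table",
            stacklevel=2,
        )
        obs = obs[row_ok][:, col_ok]
        if obs.shape[0] < 2 or obs.shape[1] < 2:
            raise ValueError(
                "table degenerate after dropping zero margins"
            )
    res = sps.chi2_contingency(obs, correction=correction)
    return TestResult(float(res.statistic), float(res.dof),
                      float(res.pvalue), "chi-square")


def correlation_table(
    loadings: np.ndarray,
    clinical: pd.DataFrame,
    variables: list[str] | None = None,
    alpha_levels: tuple[float, ...] = (0.01, 0.05),
    bonferroni_family: int | None = None,
) -> pd.DataFrame:
    """Pearson r of every clinical variable against every component loading.

    Binary variables (sex as M=1/F=0, Ab status as positive=1) enter as
    0/1, making their cells point-biserial correlations.  Two-tailed p with
    Bonferroni correction across the variables within each component column
    (family size = number of variables unless overridden).  Zero-variance
    variables yield NaN cells.  Returns a tidy frame indexed by variable
    with MultiIndex columns (component, {r, p, p_bonferroni, sig_0.05, ...}).
    """
    loadings = np.asarray(loadings, dtype=float)
    if loadings.ndim != 2 or loadings.shape[0] != len(clinical):
        raise ValueError("loadings must be subjects x K, aligned to the table")
    if variables is None:
        variables = [v for v in CLINICAL_VARS
                     if v in clinical.columns
                     or v in ("sex", "ab_positivity")]

    enc = pd.DataFrame(index=clinical.index)
    for var in variables:
        if var == "sex":
            enc[var] = (clinical["sex"] == "M").astype(float)
        elif var == "ab_positivity":
            enc[var] = (clinical["ab_label"] == "positive").astype(float)
        else:
            enc[var] = clinical[var].astype(float)

    family = bonferroni_family if bonferroni_family is not None else len(variables)
    K = loadings.shape[1]
    cols: dict = {}
    for k in range(K):
        comp = f"IC_{k + 1}"
        r_col, p_col, padj_col = [], [], []
        flags = {a: [] for a in alpha_levels}
        for var in variables:
            x = enc[var].to_numpy()
            ok = np.isfinite(x)
            if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(loadings[ok, k]) == 0:
                r, p = float("nan"), float("nan")
            else:
                r, p = sps.pearsonr(x[ok], loadings[ok, k])
            padj = min(1.0, p * family) if np.isfinite(p) else float("nan")
            r_col.append(r)
            p_col.append(p)
            padj_col.append(padj)
            for a in alpha_levels:
                flags[a].append(bool(np.isfinite(padj) and padj < a))
        cols[(comp, "r")] = r_col
        cols[(comp, "p")] = p_col
        cols[(comp, "p_bonferroni")] = padj_col
        for a in alpha_levels:
            cols[(comp, f"sig_{a}")] = flags[a]
    out = pd.DataFrame(cols, index=variables)
    out.columns = pd.MultiIndex.from_tuples(out.columns,
                                            names=["component", "stat"])
    return out


def anova_oneway(groups: list) -> TestResult:
    """One-way ANOVA: F with df = (k-1, N-k) and its p-value."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs n >= 2")
    k = len(arrays)
    N = sum(a.size for a in arrays)
    res = sps.f_oneway(*arrays)
    stat = float(res.statistic)
    p = float(res.pvalue)
    if not np.isfinite(stat):  # identical constant groups
        stat, p = 0.0, 1.0
    return TestResult(stat, (float(k - 1), float(N - k)), p, "one-way ANOVA")


def games_howell(groups: list, labels: list[str] | None = None) -> list[TestResult]:
    """Games-Howell pairwise post-hoc test for unequal variances/sizes.

    For each pair (i, j): Welch standard error SE = sqrt(s_i^2/n_i +
    s_j^2/n_j), Welch-Satterthwaite df, statistic q = |mean_i - mean_j| /
    SE * sqrt(2), and p from the studentized-range distribution with the
    total number of groups k and that df.  At k = 2 this reduces to the
    two-tailed Welch t-test.  A pair with zero variance in both groups is
    reported with NaN statistic and p.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs n >= 2")
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrays))]
    k = len(arrays)
    means = [a.mean() for a in arrays]
    variances = [a.var(ddof=1) for a in arrays]
    ns = [a.size for a in arrays]

    results = []
    for i in range(k):
        for j in range(i + 1, k):
            vi, vj = variances[i] / ns[i], variances[j] / ns[j]
            pair = {"groups": (labels[i], labels[j]),
                    "mean_diff": means[i] - means[j]}
            if vi + vj == 0:
                results.append(TestResult(
                    float("nan"), float("nan"), float("nan"),
                    "Games-Howell", detail=pair,
                ))
                continue
            se = np.sqrt(vi + vj)
            df_num = (vi + vj) ** 2
            df_den = 0.0
            if ns[i] > 1 and vi > 0:
                df_den += vi**2 / (ns[i] - 1)
            if ns[j] > 1 and vj > 0:
                df_den += vj**2 / (ns[j] - 1)
            # with one degenerate group the Welch df reduces to the other's
            df = df_num / df_den if df_den > 0 else float(ns[i] + ns[j] - 2)
            q = abs(means[i] - means[j]) / se * np.sqrt(2.0)
            p = float(np.clip(sps.studentized_range.sf(q, k, df), 0.0, 1.0))
            results.append(TestResult(float(q), float(df), p,
                                      "Games-Howell", detail=pair))
    return results
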