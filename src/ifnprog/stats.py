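"""Group-comparison and association statistics for the cohort analyses.

Thin, consistently-typed wrappers around scipy for the standard tests
(ANOVA + Tukey, Fisher's exact, Kendall tau-b, Pearson), plus the
Stuart–Maxwell test of marginal homogeneity for paired categorical data,
which has no scipy equivalent and is implemented from its quadratic form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    df: float | None = None
    estimate: float | None = None

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass
class PairedCategoryTable:
    """Square table of paired category counts.

    ``counts[i, j]`` = number of subjects in category ``i`` at baseline and
    category ``j`` at follow-up.
    """

    categories: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        k = len(self.categories)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square and match the category labels")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.round(self.counts)) or np.any(self.counts < 0):
                raise ValueError("counts must be non-negative integers")
            self.counts = self.counts.astype(int)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def stuart_maxwell(table: PairedCategoryTable) -> TestResult:
    """Stuart–Maxwell χ² test of marginal homogeneity for paired categories.

    With marginal differences ``d_i = row_i − col_i`` and covariance
    ``S_ii = row_i + col_i − 2·n_ii``, ``S_ij = −(n_ij + n_ji)``, the statistic
    is ``d' S⁻¹ d`` after dropping one category (the one with the smallest
    marginal sum, so structural zeros do not break inversion); a generalised
    inverse is used if the reduced S is still singular.  For two categories
    this reduces exactly to McNemar's (b−c)²/(b+c) without continuity
    correction.
    """
    n = table.counts.astype(float)
    k = n.shape[0]
    if k < 2:
        raise ValueError("need at least two categories")
    row = n.sum(axis=1)
    col = n.sum(axis=0)
    if float(n.sum() - np.trace(n)) == 0.0:
        warnings.warn("all observations on the diagonal; statistic is 0", stacklevel=2)
        return TestResult(0.0, 1.0, "stuart-maxwell", df=k - 1)
    d = row - col
    s = -(n + n.T)
    np.fill_diagonal(s, row + col - 2 * np.diag(n))
    drop = int(np.argmin(row + col))
    keep = [i for i in range(k) if i != drop]
    d_r = d[keep]
    s_r = s[np.ix_(keep, keep)]
    try:
        chi2 = float(d_r @ np.linalg.solve(s_r, d_r))
        df = k - 1
    except np.linalg.LinAlgError:
        pinv = np.linalg.pinv(s_r)
        chi2 = float(d_r @ pinv @ d_r)
        df = int(np.linalg.matrix_rank(s_r))
    p = float(stats.chi2.sf(chi2, df))
    return TestResult(chi2, p, "stuart-maxwell", df=df)


def anova_tukey(groups: list[np.ndarray]) -> tuple[TestResult, list[dict]]:
    """One-way ANOVA with Tukey HSD pairwise contrasts on the same samples.

    NaN values are dropped per group.  Returns the overall F test and a list
    of pairwise records (group indices, mean difference, Tukey CI and p).
    """
    clean = []
    for g in groups:
        g = np.asarray(g, dtype=float)
        g = g[~np.isnan(g)]
        if g.size < 2:
            raise ValueError("each group needs at least two observed values")
        clean.append(g)
    if len(clean) < 2:
        raise ValueError("need at least two groups")
    if all(np.var(g) == 0 for g in clean) and len({g[0] for g in clean}) == 1:
        raise ValueError("zero variance everywhere; ANOVA undefined")
    f, p = stats.f_oneway(*clean)
    n_total = sum(g.size for g in clean)
    overall = TestResult(float(f), float(p), "anova", df=len(clean) - 1)
    overall_df2 = n_total - len(clean)
    hsd = stats.tukey_hsd(*clean)
    ci = hsd.confidence_interval()
    pairs = []
    for i in range(len(clean)):
        for j in range(i + 1, len(clean)):
            pairs.append(
                {
                    "groups": (i, j),
                    "diff": float(clean[i].mean() - clean[j].mean()),
                    "ci_low": float(ci.low[i, j]),
                    "ci_high": float(ci.high[i, j]),
                    "p": float(hsd.pvalue[i, j]),
                }
            )
    overall.df = (len(clean) - 1, overall_df2)
    return overall, pairs


def kendall_tau_b(x, y) -> TestResult:
    """Kendall's tau-b with tie correction; p from the normal approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("tau-b undefined for a constant vector")
    res = stats.kendalltau(x, y, variant="b", method="asymptotic")
    return TestResult(float(res.statistic), float(res.pvalue), "kendall-tau-b",
                      estimate=float(res.statistic))


def fisher_exact(table) -> TestResult:
    """Two-sided Fisher's exact test on a 2×2 count table."""
    t = np.asarray(table)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.round(t)):
        raise ValueError("need a 2x2 table of non-negative integer counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        warnings.warn("empty margin; Fisher p fixed at 1", stacklevel=2)
        return TestResult(float("nan"), 1.0, "fisher-exact")
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return TestResult(float(odds), float(p), "fisher-exact", estimate=float(odds))


def pearson_r(x, y) -> TestResult:
    """Pearson product-moment correlation with the t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = stats.pearsonr(x, y)
    return TestResult(float(res.statistic), float(res.pvalue), "pearson",
                      estimate=float(res.statistic))
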