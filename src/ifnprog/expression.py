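"""qPCR expression arithmetic: ΔCt normalisation, relative expression and fold differences.

Ct values are PCR cycle thresholds; one extra cycle is one halving of template,
so expression is quantified on a log2 scale.  The sign convention throughout is

    ΔCt = Ct(target) − Ct(reference)

so a *higher* ΔCt means *lower* expression.  Wherever "higher = more expression"
is needed (regressions, plots), the reflected value −ΔCt is used instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats


class InsufficientDataError(ValueError):
    """A group contrast was requested with fewer than two observed values."""


@dataclass
class ExpressionMatrix:
    """Ct values by gene and sample, with a designated reference (housekeeping) gene.

    Parameters
    ----------
    genes : list of str
        Gene symbols, one per row of ``ct``.
    samples : list of str
        Sample identifiers, one per column of ``ct``.
    ct : ndarray, shape (n_genes, n_samples)
        Raw cycle-threshold values; ``NaN`` marks a missing measurement.
    reference_gene : str
        The housekeeping gene used for ΔCt normalisation (e.g. *PPIA*).
    """

    genes: list[str]
    samples: list[str]
    ct: np.ndarray
    reference_gene: str

    def __post_init__(self) -> None:
        self.ct = np.asarray(self.ct, dtype=float)
        if self.ct.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"ct shape {self.ct.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if self.reference_gene not in self.genes:
            raise KeyError(f"reference gene {self.reference_gene!r} not in gene list")
        present = self.ct[~np.isnan(self.ct)]
        if present.size and not np.all(np.isfinite(present)):
            raise ValueError("non-finite Ct values present (use NaN for missing)")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ct, index=self.genes, columns=self.samples)


@dataclass
class DeltaCtMatrix:
    """ΔCt values (reference gene subtracted and removed).

    ``reflected`` indicates the −ΔCt orientation, in which larger values mean
    greater expression.
    """

    genes: list[str]
    samples: list[str]
    dct: np.ndarray
    reflected: bool = False

    def __post_init__(self) -> None:
        self.dct = np.asarray(self.dct, dtype=float)
        if self.dct.shape != (len(self.genes), len(self.samples)):
            raise ValueError("dct shape does not match gene/sample labels")

    def reflect(self) -> "DeltaCtMatrix":
        """Return the −ΔCt view; applying twice restores the original exactly."""
        return replace(self, dct=-self.dct, reflected=not self.reflected)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dct, index=self.genes, columns=self.samples)


@dataclass
class FoldDifference:
    """A between-group expression contrast on the fold scale (2^−ΔΔCt)."""

    estimate: float
    ci_low: float
    ci_high: float
    delta_delta_ct: float
    group_a: str = "a"
    group_b: str = "b"
    n_a: int = 0
    n_b: int = 0
    p_value: float = float("nan")
    method: str = "welch"

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("fold-difference CI does not bracket the estimate")

    def reciprocal(self) -> "FoldDifference":
        """The same contrast with the groups swapped: FD(a,b)·FD(b,a) = 1."""
        return FoldDifference(
            estimate=1.0 / self.estimate,
            ci_low=1.0 / self.ci_high,
            ci_high=1.0 / self.ci_low,
            delta_delta_ct=-self.delta_delta_ct,
            group_a=self.group_b,
            group_b=self.group_a,
            n_a=self.n_b,
            n_b=self.n_a,
            p_value=self.p_value,
            method=self.method,
        )


def compute_delta_ct(expr: ExpressionMatrix) -> DeltaCtMatrix:
    """Normalise a Ct matrix against its reference gene.

    ``ΔCt[g, s] = Ct[g, s] − Ct[reference, s]``; the reference row is removed.
    A sample whose reference Ct is missing yields all-NaN ΔCt (with a warning)
    but is retained so sample alignment is preserved.
    """
    ref_idx = expr.genes.index(expr.reference_gene)
    ref_row = expr.ct[ref_idx]
    keep = [i for i in range(len(expr.genes)) if i != ref_idx]
    dct = expr.ct[keep] - ref_row[np.newaxis, :]
    n_bad = int(np.isnan(ref_row).sum())
    if n_bad:
        warnings.warn(
            f"{n_bad} sample(s) missing reference-gene Ct; their ΔCt are all NaN",
            stacklevel=2,
        )
    return DeltaCtMatrix(
        genes=[expr.genes[i] for i in keep],
        samples=list(expr.samples),
        dct=dct,
    )


def relative_expression(dct):
    """Convert ΔCt to relative expression 2^−ΔCt (NaN propagates)."""
    return np.power(2.0, -np.asarray(dct, dtype=float))


def _welch_interval(a: np.ndarray, b: np.ndarray, conf: float):
    res = stats.ttest_ind(a, b, equal_var=False)
    ci = res.confidence_interval(confidence_level=conf)
    return ci.low, ci.high, float(res.pvalue)


def _tukey_interval(a, b, context, conf: float):
    """Tukey-HSD interval for the a-vs-b mean difference within a ≥3 group ANOVA."""
    groups = [np.asarray(a, float), np.asarray(b, float)]
    groups += [np.asarray(g, float)[~np.isnan(np.asarray(g, float))] for g in context]
    res = stats.tukey_hsd(*groups)
    ci = res.confidence_interval(confidence_level=conf)
    # statistic[i, j] = mean(i) - mean(j); a is group 0, b is group 1
    return ci.low[0, 1], ci.high[0, 1], float(res.pvalue[0, 1])


def fold_difference(
    group_a,
    group_b,
    method: str = "welch",
    context_groups=(),
    conf: float = 0.95,
    labels: tuple[str, str] = ("a", "b"),
) -> FoldDifference:
    """Fold difference 2^−ΔΔCt between two groups of ΔCt values, with CI.

    ΔΔCt = mean(ΔCt_a) − mean(ΔCt_b); because ΔCt is inverted relative to
    expression, a group with *lower* ΔCt has *higher* expression and FD > 1.
    The CI is computed on the ΔΔCt scale (Welch t by default, or the Tukey
    studentised range when ``method="tukey_context"`` and the remaining ANOVA
    groups are supplied) and then exponentiated; endpoints are re-ordered after
    the sign flip of the transform.

    NaN values are dropped per group. Raises :class:`InsufficientDataError`
    when either group has fewer than two observed values.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError(
            f"need >=2 observed ΔCt per group, got {a.size} and {b.size}"
        )
    ddct = float(a.mean() - b.mean())
    if method == "welch":
        lo, hi, p = _welch_interval(a, b, conf)
    elif method == "pooled":
        res = stats.ttest_ind(a, b, equal_var=True)
        ci = res.confidence_interval(confidence_level=conf)
        lo, hi, p = ci.low, ci.high, float(res.pvalue)
    elif method == "tukey_context":
        if not context_groups:
            raise ValueError("tukey_context requires the remaining ANOVA groups")
        lo, hi, p = _tukey_interval(a, b, context_groups, conf)
    else:
        raise ValueError(f"unknown method {method!r}")
    # 2^-x is decreasing, so the interval flips
    bounds = sorted((2.0 ** -lo, 2.0 ** -hi))
    return FoldDifference(
        estimate=2.0 ** -ddct,
        ci_low=bounds[0],
        ci_high=bounds[1],
        delta_delta_ct=ddct,
        group_a=labels[0],
        group_b=labels[1],
        n_a=int(a.size),
        n_b=int(b.size),
        p_value=p,
        method=method,
    )
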