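"""Biomarker evaluation: ROC curves, paired AUC comparison, cutoff selection,
and confusion-matrix diagnostics with Wilson score intervals.

AUC is computed as the Mann–Whitney probability of correct ranking (ties
count one half) and its confidence interval uses the DeLong structural-
components variance; the paired two-score comparison is DeLong's test with
the statistic reported as χ² (1 df) = z².  ΔCt scores are evaluated with
``higher_is_positive=False`` — lower ΔCt means more interferon activity —
which is equivalent to reflecting the score first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .stats import TestResult


@dataclass
class DiagnosticTable:
    """Confusion-matrix counts for a binary rule against a binary outcome."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
            setattr(self, name, int(v))


@dataclass
class DiagnosticMetrics:
    """Sensitivity, specificity, PPV, NPV with 95% Wilson score intervals."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    ppv_ci: tuple[float, float]
    npv_ci: tuple[float, float]
    table: DiagnosticTable

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0

    def as_percent(self) -> dict:
        """Rounded-percentage view (integers, matching reporting convention)."""
        out = {}
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            v = getattr(self, name)
            lo, hi = getattr(self, f"{name}_ci")
            out[name] = None if np.isnan(v) else round(100 * v)
            out[f"{name}_ci"] = (round(100 * lo), round(100 * hi))
        return out


@dataclass
class ROCCurve:
    """A full threshold sweep for one score.

    ``thresholds`` are in the score's own units; at row ``i`` a sample is
    called positive when its score is ≥ threshold (higher_is_positive) or
    ≤ threshold (otherwise). ``tp``/``fp`` give the calls at each threshold.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    n_pos: int
    n_neg: int
    auc: float
    auc_ci: tuple[float, float]
    higher_is_positive: bool
    scores: np.ndarray  # retained for paired DeLong comparison
    outcome: np.ndarray


def wilson_interval(count: int, nobs: int, conf: float = 0.95) -> tuple[float, float]:
    """Two-sided Wilson score interval for a binomial proportion."""
    lo, hi = proportion_confint(count, nobs, alpha=1 - conf, method="wilson")
    # closed-form endpoints are exactly 0/1 at the boundaries; undo FP jitter
    phat = count / nobs
    return float(min(lo, phat)), float(max(hi, phat))


def diagnostics(table: DiagnosticTable) -> DiagnosticMetrics:
    """Sens/spec/PPV/NPV from a confusion table, each with a Wilson 95% CI.

    PPV (resp. NPV) is NaN with a warning when no sample was called positive
    (resp. negative).
    """
    tp, fp, fn, tn = table.tp, table.fp, table.fn, table.tn
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("need at least one event and one non-event")

    def prop(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (empty denominator)", stacklevel=3)
            return float("nan"), (float("nan"), float("nan"))
        return num / den, wilson_interval(num, den)

    sens, sens_ci = prop(tp, tp + fn, "sensitivity")
    spec, spec_ci = prop(tn, tn + fp, "specificity")
    ppv, ppv_ci = prop(tp, tp + fp, "ppv")
    npv, npv_ci = prop(tn, tn + fn, "npv")
    return DiagnosticMetrics(sens, spec, ppv, npv, sens_ci, spec_ci, ppv_ci, npv_ci, table)


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(pos: np.ndarray, neg: np.ndarray):
    """DeLong structural components V10 (per positive) and V01 (per negative)."""
    m, n = pos.size, neg.size
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return auc, v10, v01


def roc_curve(scores, outcome, higher_is_positive: bool = True) -> ROCCurve:
    """ROC sweep over the unique score values, AUC and DeLong 95% CI.

    NaN scores are excluded (with their outcomes). Requires both outcome
    classes to be present after exclusion.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcome).astype(int)
    keep = ~np.isnan(s)
    s, y = s[keep], y[keep]
    if not (set(np.unique(y)) <= {0, 1}) or len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes (0 and 1)")
    oriented = s if higher_is_positive else -s
    pos = oriented[y == 1]
    neg = oriented[y == 0]
    auc, v10, v01 = _delong_components(pos, neg)
    def _var(v):  # singleton class contributes no sampling variance term
        return v.var(ddof=1) if v.size > 1 else 0.0

    var = _var(v10) / pos.size + _var(v01) / neg.size
    z = stats.norm.ppf(0.975)
    half = z * np.sqrt(var)
    ci = (max(0.0, auc - half), min(1.0, auc + half))

    thr_oriented = np.unique(oriented)[::-1]  # most stringent first
    tp = np.array([(pos >= t).sum() for t in thr_oriented])
    fp = np.array([(neg >= t).sum() for t in thr_oriented])
    sens = tp / pos.size
    spec = 1.0 - fp / neg.size
    thresholds = thr_oriented if higher_is_positive else -thr_oriented
    return ROCCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        tp=tp,
        fp=fp,
        n_pos=int(pos.size),
        n_neg=int(neg.size),
        auc=float(auc),
        auc_ci=(float(ci[0]), float(ci[1])),
        higher_is_positive=higher_is_positive,
        scores=s,
        outcome=y,
    )


def compare_auc_paired(curve1: ROCCurve, curve2: ROCCurve) -> TestResult:
    """DeLong's paired test for the difference of two AUCs on the same samples.

    The statistic is reported as χ² with 1 df (the square of the z statistic),
    matching the convention of `roc.test`-style outputs.
    """
    if curve1.scores.size != curve2.scores.size or not np.array_equal(
        curve1.outcome, curve2.outcome
    ):
        raise ValueError("paired comparison requires identical samples and outcomes")
    y = curve1.outcome
    out = []
    for c in (curve1, curve2):
        oriented = c.scores if c.higher_is_positive else -c.scores
        out.append(_delong_components(oriented[y == 1], oriented[y == 0]))
    (auc1, v10_1, v01_1), (auc2, v10_2, v01_2) = out
    m, n = v10_1.size, v01_1.size
    s10 = np.cov(np.vstack([v10_1, v10_2]))
    s01 = np.cov(np.vstack([v01_1, v01_2]))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0:
        return TestResult(0.0, 1.0, "delong-paired", df=1, estimate=float(auc1 - auc2))
    z = (auc1 - auc2) / np.sqrt(var_diff)
    chi2 = float(z**2)
    p = float(stats.chi2.sf(chi2, 1))
    return TestResult(chi2, p, "delong-paired", df=1, estimate=float(auc1 - auc2))


def _metrics_at(curve: ROCCurve, idx: int) -> tuple[float, DiagnosticMetrics]:
    tp = int(curve.tp[idx])
    fp = int(curve.fp[idx])
    table = DiagnosticTable(tp=tp, fp=fp, fn=curve.n_pos - tp, tn=curve.n_neg - fp)
    return float(curve.thresholds[idx]), diagnostics(table)


def youden_cutoff(curve: ROCCurve) -> tuple[float, DiagnosticMetrics]:
    """The threshold maximising Youden's J = sensitivity + specificity − 1.

    Ties are broken toward higher sensitivity.
    """
    j = curve.sensitivity + curve.specificity - 1.0
    best = np.flatnonzero(j == j.max())
    idx = best[np.argmax(curve.sensitivity[best])]
    return _metrics_at(curve, int(idx))


def rule_in_cutoff(
    curve: ROCCurve, min_specificity: float
) -> tuple[float, DiagnosticMetrics]:
    """The most sensitive threshold whose specificity is ≥ ``min_specificity``.

    Intended for rule-in use: a high specificity floor excludes the
    lowest-risk individuals at the cost of sensitivity.
    """
    if not 0.0 <= min_specificity < 1.0:
        raise ValueError("min_specificity must be in [0, 1)")
    ok = np.flatnonzero(curve.specificity >= min_specificity)
    if ok.size == 0:
        raise ValueError(
            f"specificity {min_specificity} unattainable; maximum is "
            f"{curve.specificity.max():.3f}"
        )
    idx = ok[np.argmax(curve.sensitivity[ok])]
    return _metrics_at(curve, int(idx))
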