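"""End-to-end orchestration: ΔCt → scores → group contrasts → ROC/cutoffs →
univariable screen → multiple imputation → penalised model → pooled report.

`run_pipeline` is the library entry point the command-line wrapper calls; it
writes a machine-readable JSON report plus tidy CSVs into the output
directory and returns the in-memory :class:`AnalysisReport`.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diagnostics import roc_curve, compare_auc_paired, youden_cutoff, rule_in_cutoff
from .expression import ExpressionMatrix, compute_delta_ct, fold_difference
from .io import write_cohort, write_ct_matrix, write_partition, write_scores
from .prediction import (
    CohortTable,
    mice_impute,
    multivariable_pooled,
    penalised_pooled,
    univariable_screen,
)
from .scoring import GenePartition, compute_scores
from .stats import anova_tukey

log = logging.getLogger("ifnprog")


@dataclass
class RunConfig:
    """Settings for one pipeline run."""

    reference_gene: str = "PPIA"
    cutoff_policy: str = "youden"  # "youden" | "spec:<float>" | "fixed:<ΔCt>"
    m_imputations: int = 20
    mice_cycles: int = 10
    seed: int = 0
    alpha_screen: float = 0.10
    n_lambda: int = 100
    out_dir: Path | None = None



@dataclass
class AnalysisReport:
    """All pipeline outputs plus provenance, serialisable to JSON."""

    score_summary: dict
    fold_differences: list[dict]
    roc: dict
    operating_point: dict
    univariable: dict
    multivariable: dict
    penalised: dict
    provenance: dict
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "score_summary": self.score_summary,
            "fold_differences": self.fold_differences,
            "roc": self.roc,
            "operating_point": self.operating_point,
            "univariable": self.univariable,
            "multivariable": self.multivariable,
            "penalised": self.penalised,
            "provenance": self.provenance,
            **({"extras": self.extras} if self.extras else {}),
        }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) else f
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    return obj


def _config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(
        {k: str(v) for k, v in vars(cfg).items() if k != "out_dir"}, sort_keys=True
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def group_contrasts(
    scores_frame: pd.DataFrame, groups: pd.Series, which: str
) -> tuple[dict, list[dict]]:
    """ANOVA across HC / at-risk / SLE plus pairwise Tukey fold differences."""
    col = f"score_{which.lower()}"
    order = [g for g in ("HC", "AtRisk", "SLE") if g in set(groups)]
    vals = {g: scores_frame.loc[groups[groups == g].index, col].dropna().to_numpy()
            for g in order}
    overall, _ = anova_tukey([vals[g] for g in order])
    fds = []
    for i, gi in enumerate(order):
        for gj in order[i + 1:]:
            others = [vals[g] for g in order if g not in (gi, gj)]
            fd = fold_difference(
                vals[gi], vals[gj],
                method="tukey_context" if others else "welch",
                context_groups=others, labels=(gi, gj),
            )
            # ΔCt is inverse to expression: FD(gi, gj) > 1 means gi expresses more
            fds.append(
                {
                    "score": which,
                    "groups": f"{gi} vs {gj}",
                    "fold_difference": fd.estimate,
                    "ci_low": fd.ci_low,
                    "ci_high": fd.ci_high,
                    "p": fd.p_value,
                }
            )
    anova_rec = {
        "score": which,
        "F": overall.statistic,
        "df": list(np.atleast_1d(overall.df)),
        "p": overall.p_value,
    }
    return anova_rec, fds


def _metrics_for_policy(curve, policy: str):
    """Resolve a cutoff-policy string against a ROC curve.

    Policies: ``youden`` (maximise J), ``spec:<p>`` (rule-in: most sensitive
    threshold with specificity ≥ p), ``fixed:<ΔCt>`` (the sweep threshold at
    or just below the requested ΔCt, keeping the ≤-cutoff rule inclusive).
    """
    if policy == "youden":
        return youden_cutoff(curve)
    kind, _, value = policy.partition(":")
    if not value or kind not in ("spec", "fixed"):
        raise ValueError(f"unknown cutoff policy {policy!r}")
    if kind == "spec":
        return rule_in_cutoff(curve, float(value))
    from .diagnostics import _metrics_at

    candidates = np.flatnonzero(curve.thresholds <= float(value))
    if candidates.size == 0:
        candidates = np.array([int(np.argmin(curve.thresholds))])
    idx = int(candidates[np.argmax(curve.thresholds[candidates])])
    return _metrics_at(curve, idx)


def run_pipeline(
    expr: ExpressionMatrix,
    cohort: CohortTable,
    partition: GenePartition,
    groups: pd.Series,
    config: RunConfig | None = None,
) -> AnalysisReport:
    """Execute the full analysis on in-memory inputs.

    ``cohort`` rows must be the at-risk samples (a subset of ``expr`` /
    ``groups``); comparator groups enter only the score contrasts.
    """
    cfg = config or RunConfig()
    log.info("computing ΔCt and median scores")
    dct = compute_delta_ct(expr)
    scores = compute_scores(dct, partition)
    sframe = scores.to_frame()

    summary = {}
    for which in ("A", "B"):
        col = f"score_{which.lower()}"
        per_group = {
            g: {
                "n": int(sframe.loc[groups[groups == g].index, col].notna().sum()),
                "mean_dct": float(np.nanmean(sframe.loc[groups[groups == g].index, col])),
            }
            for g in sorted(set(groups))
        }
        summary[which] = per_group

    log.info("group contrasts")
    anovas, fds = [], []
    for which in ("A", "B"):
        a_rec, f_rec = group_contrasts(sframe, groups, which)
        anovas.append(a_rec)
        fds.extend(f_rec)

    # progression contrasts within at-risk
    ar = cohort.data.index
    outcome = cohort.data["outcome"]
    for which in ("A", "B"):
        col = f"score_{which.lower()}"
        prog = sframe.loc[ar[outcome == 1], col].dropna().to_numpy()
        non = sframe.loc[ar[outcome == 0], col].dropna().to_numpy()
        fd = fold_difference(prog, non, labels=("progressor", "non-progressor"))
        fds.append(
            {
                "score": which,
                "groups": "progressor vs non-progressor",
                "fold_difference": fd.estimate,
                "ci_low": fd.ci_low,
                "ci_high": fd.ci_high,
                "p": fd.p_value,
            }
        )

    log.info("ROC analysis (lower ΔCt = IFN positive)")
    curves = {}
    for which in ("A", "B"):
        col = f"score_{which.lower()}"
        vals = sframe.loc[ar, col].to_numpy()
        curves[which] = roc_curve(vals, outcome.to_numpy(), higher_is_positive=False)
    cmp = compare_auc_paired(curves["B"], curves["A"])
    roc_rec = {
        which: {"auc": c.auc, "auc_ci": list(c.auc_ci), "n_pos": c.n_pos, "n_neg": c.n_neg}
        for which, c in curves.items()
    }
    roc_rec["paired_comparison"] = {
        "chi2": cmp.statistic, "p": cmp.p_value, "auc_difference": cmp.estimate,
    }

    cutoff, metrics = _metrics_for_policy(curves["B"], cfg.cutoff_policy)
    op = {"score": "B", "policy": cfg.cutoff_policy, "cutoff_dct": cutoff}
    op.update(metrics.as_percent())
    op["counts"] = vars(metrics.table)

    log.info("univariable screen + multiple imputation (m=%d)", cfg.m_imputations)
    imputations = mice_impute(
        cohort, m=cfg.m_imputations, cycles=cfg.mice_cycles, seed=cfg.seed
    )
    predictors = cohort.predictors
    kept, uni_table = univariable_screen(imputations, predictors, alpha=cfg.alpha_screen)
    log.info("multivariable + penalised model on %d predictors", len(kept))
    multi = multivariable_pooled(imputations, kept)
    pen = penalised_pooled(imputations, kept, n_lambda=cfg.n_lambda)

    report = AnalysisReport(
        score_summary=summary,
        fold_differences=fds,
        roc=roc_rec,
        operating_point=op,
        univariable={
            "table": uni_table.reset_index(names="predictor").to_dict("records"),
            "kept": kept,
            "alpha": cfg.alpha_screen,
        },
        multivariable=multi.to_frame().reset_index(names="predictor").to_dict("records"),
        penalised=pen.reset_index(names="predictor").to_dict("records"),
        provenance={
            "seed": cfg.seed,
            "m_imputations": cfg.m_imputations,
            "config_hash": _config_hash(cfg),
            "version": __version__,
        },
        extras={"anova": anovas},
    )

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        try:
            with open(out / "report.json", "w") as fh:
                json.dump(_jsonable(report.to_dict()), fh, indent=2)
                fh.write("\n")
            write_scores(scores, out / "scores.csv")
            pd.DataFrame(fds).to_csv(out / "fold_differences.csv", index=False)
            uni_table.to_csv(out / "univariable.csv", index_label="predictor")
            multi.to_frame().to_csv(out / "multivariable.csv", index_label="predictor")
            pen.to_csv(out / "penalised.csv", index_label="predictor")
        except Exception:
            for f in out.glob("*"):
                f.unlink()  # no partial outputs
            raise
    return report


def write_cohort_inputs(cohort, out_dir) -> dict:
    """Write a synthetic cohort in the CSV/JSON dialects the pipeline reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_ct_matrix(cohort.expression, out / "ct_matrix.csv")
    write_partition(cohort.partition, out / "partition.json")
    write_cohort(cohort.cohort, out / "metadata.csv")
    cohort.groups.to_csv(out / "groups.csv")
    return {
        "ct": str(out / "ct_matrix.csv"),
        "partition": str(out / "partition.json"),
        "metadata": str(out / "metadata.csv"),
        "groups": str(out / "groups.csv"),
    }
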