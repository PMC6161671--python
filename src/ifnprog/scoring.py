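"""Two-score interferon-stimulated-gene (ISG) system.

A panel of ISGs is reduced to two factors by principal-axis factoring with
varimax rotation; each gene is assigned to the factor on which it loads most
strongly, and a sample's score for a factor is the *median ΔCt* of that
factor's genes.  Because ΔCt is inverse to expression, a lower score means
higher interferon activity, and samples are called IFN-high when the score
falls at or below a ΔCt cutoff.

In routine use the gene partition is fixed up front (supplied as
a :class:`GenePartition` or JSON file) and factor fitting is skipped.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import DeltaCtMatrix


@dataclass
class FactorModel:
    """A rotated factor solution over genes."""

    genes: list[str]
    loadings: np.ndarray  # (n_genes, n_factors)
    n_factors: int
    variance_explained: np.ndarray  # proportion of total variance per factor
    communalities: np.ndarray

    @property
    def cumulative_variance(self) -> float:
        return float(np.sum(self.variance_explained))


@dataclass
class GenePartition:
    """Assignment of genes to the Score-A / Score-B sets."""

    score_a_genes: set[str]
    score_b_genes: set[str]
    unassigned: set[str] = field(default_factory=set)
    loading_threshold: float = 0.4

    def __post_init__(self) -> None:
        self.score_a_genes = set(self.score_a_genes)
        self.score_b_genes = set(self.score_b_genes)
        self.unassigned = set(self.unassigned)
        if self.score_a_genes & self.score_b_genes:
            raise ValueError("a gene cannot belong to both score sets")

    @property
    def all_genes(self) -> set[str]:
        return self.score_a_genes | self.score_b_genes | self.unassigned

    def to_dict(self) -> dict:
        return {
            "score_a": sorted(self.score_a_genes),
            "score_b": sorted(self.score_b_genes),
            "unassigned": sorted(self.unassigned),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GenePartition":
        return cls(
            score_a_genes=set(d["score_a"]),
            score_b_genes=set(d["score_b"]),
            unassigned=set(d.get("unassigned", [])),
        )


@dataclass
class IFNScores:
    """Per-sample IFN-Score-A and IFN-Score-B in ΔCt units."""

    samples: list[str]
    score_a: np.ndarray
    score_b: np.ndarray
    n_genes_a: np.ndarray
    n_genes_b: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "score_a": self.score_a,
                "score_b": self.score_b,
                "n_a": self.n_genes_a,
                "n_b": self.n_genes_b,
            },
            index=pd.Index(self.samples, name="sample"),
        )


def _varimax(loadings: np.ndarray, max_iter: int = 100, tol: float = 1e-8) -> np.ndarray:
    """Kaiser varimax rotation (orthogonal)."""
    p, k = loadings.shape
    rotation = np.eye(k)
    var = 0.0
    for _ in range(max_iter):
        rotated = loadings @ rotation
        u, s, vt = np.linalg.svd(
            loadings.T
            @ (rotated**3 - rotated @ np.diag(np.sum(rotated**2, axis=0)) / p)
        )
        rotation = u @ vt
        new_var = float(np.sum(s))
        if new_var < var * (1 + tol):
            break
        var = new_var
    return loadings @ rotation


def fit_factor_model(
    dct: DeltaCtMatrix,
    n_factors: int = 2,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> FactorModel:
    """Principal-axis factoring with varimax rotation on the gene correlation matrix.

    Genes are variables and samples observations; only samples with complete
    ΔCt enter the correlation matrix.  Communalities are initialised at the
    squared multiple correlations and iterated to convergence.  Constant genes
    are excluded with a warning.
    """
    x = dct.dct
    if dct.reflected is False:
        x = -x  # factor the reflected (expression-oriented) values
    complete = ~np.isnan(x).any(axis=0)
    x = x[:, complete]
    if x.shape[1] < n_factors + 2:
        raise ValueError(
            f"need at least {n_factors + 2} complete samples, have {x.shape[1]}"
        )
    sd = x.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [g for g, k in zip(dct.genes, keep) if not k]
        warnings.warn(f"excluding constant gene(s): {dropped}", stacklevel=2)
    genes = [g for g, k in zip(dct.genes, keep) if k]
    x = x[keep]
    if len(genes) < 3 * n_factors:
        raise ValueError(f"need >= {3 * n_factors} usable genes, have {len(genes)}")
    corr = np.corrcoef(x)

    # initial communalities: squared multiple correlations (with ridge fallback)
    try:
        inv = np.linalg.inv(corr)
        h2 = 1.0 - 1.0 / np.diag(inv)
    except np.linalg.LinAlgError:
        h2 = np.full(len(genes), 0.5)
    h2 = np.clip(h2, 0.0, 0.999)
    for _ in range(max_iter):
        reduced = corr.copy()
        np.fill_diagonal(reduced, h2)
        vals, vecs = np.linalg.eigh(reduced)
        order = np.argsort(vals)[::-1][:n_factors]
        lam = np.clip(vals[order], 0.0, None)
        loadings = vecs[:, order] * np.sqrt(lam)
        new_h2 = np.clip(np.sum(loadings**2, axis=1), 0.0, 0.999)
        if np.max(np.abs(new_h2 - h2)) < tol:
            h2 = new_h2
            break
        h2 = new_h2
    # variance shares are conventionally quoted for the unrotated extraction
    # (varimax redistributes sums of squares but preserves their total)
    unrotated_share = np.sort(lam)[::-1] / len(genes)
    loadings = _varimax(loadings) if n_factors > 1 else loadings
    # fix sign so each factor loads positively on balance
    signs = np.sign(np.sum(loadings, axis=0))
    signs[signs == 0] = 1.0
    loadings = loadings * signs
    # order rotated factors by their sum of squared loadings
    ss = np.sum(loadings**2, axis=0)
    order = np.argsort(ss)[::-1]
    loadings = loadings[:, order]
    return FactorModel(
        genes=genes,
        loadings=loadings,
        n_factors=n_factors,
        variance_explained=unrotated_share,
        communalities=np.sum(loadings**2, axis=1),
    )


def assign_genes(model: FactorModel, loading_threshold: float = 0.4) -> GenePartition:
    """Assign each gene to the factor with the larger |loading|, if above threshold.

    Factor 0 feeds Score-A, factor 1 Score-B; ties go to Score-A. Genes whose
    best loading falls below the threshold are left unassigned.
    """
    if model.n_factors != 2:
        raise ValueError("gene assignment is defined for a two-factor model")
    a, b, un = set(), set(), set()
    for gene, (la, lb) in zip(model.genes, np.abs(model.loadings)):
        if max(la, lb) < loading_threshold:
            un.add(gene)
        elif la >= lb:
            a.add(gene)
        else:
            b.add(gene)
    return GenePartition(a, b, un, loading_threshold=loading_threshold)


def compute_scores(
    dct: DeltaCtMatrix,
    partition: GenePartition,
    min_genes: int | None = None,
) -> IFNScores:
    """Median-ΔCt factor scores per sample.

    For each score set the sample's score is the median of its observed ΔCt
    values (even cardinality: mean of the central pair).  A score is NaN when
    fewer than ``min_genes`` of the set are observed (default: half the set,
    rounded up).
    """
    if dct.reflected:
        raise ValueError("scores are defined on raw ΔCt; un-reflect first")
    frame = dct.to_frame()

    def one_set(gene_set: set[str], label: str):
        genes = [g for g in dct.genes if g in gene_set]
        if not genes:
            raise ValueError(f"score {label} has no genes present in the matrix")
        floor = min_genes if min_genes is not None else math.ceil(len(genes) / 2)
        block = frame.loc[genes]
        n_obs = block.notna().sum(axis=0).to_numpy()
        med = np.nanmedian(
            np.where(np.isnan(block.to_numpy()), np.nan, block.to_numpy()), axis=0
        )
        med = np.where(n_obs >= max(floor, 1), med, np.nan)
        if (n_obs < floor).any() and (n_obs > 0).any():
            short = int(((n_obs < floor) & (n_obs > 0)).sum())
            if short:
                warnings.warn(
                    f"{short} sample(s) below the {floor}-gene floor for score {label}; "
                    "score set to NaN",
                    stacklevel=3,
                )
        return med, n_obs

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN medians
        score_a, n_a = one_set(partition.score_a_genes, "A")
        score_b, n_b = one_set(partition.score_b_genes, "B")
    return IFNScores(
        samples=list(dct.samples),
        score_a=score_a,
        score_b=score_b,
        n_genes_a=n_a,
        n_genes_b=n_b,
    )


def classify(scores: IFNScores, cutoff: float, which: str = "B") -> pd.Series:
    """Label samples IFN-positive when the chosen score is ≤ cutoff (ΔCt).

    The cutoff is inclusive — a score exactly at the cutoff is positive,
    matching the "≤ cutoff ΔCt" convention.  NaN scores are 'unclassified'.
    """
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    vals = {"A": scores.score_a, "B": scores.score_b}[which.upper()]
    labels = np.where(
        np.isnan(vals), "unclassified", np.where(vals <= cutoff, "positive", "negative")
    )
    return pd.Series(labels, index=pd.Index(scores.samples, name="sample"), name=f"ifn_{which.lower()}")
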