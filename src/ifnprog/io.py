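"""Readers and writers for the pipeline's plain-text interchange formats.

Ct matrices travel as CSV with a leading ``gene`` column and one column per
sample (empty cell = missing); gene partitions as JSON; scores, metadata and
test results as tidy CSV.  Parse errors carry row/column context.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .prediction import CohortTable
from .scoring import GenePartition, IFNScores
from .stats import PairedCategoryTable


class FormatError(ValueError):
    """A malformed input file, with location context in the message."""


def read_ct_matrix(path, reference_gene: str) -> ExpressionMatrix:
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    if df.columns[0] != "gene":
        raise FormatError(f"{path}: first column must be 'gene', got {df.columns[0]!r}")
    if df["gene"].duplicated().any():
        dup = df["gene"][df["gene"].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicated gene {dup!r}")
    genes = df["gene"].tolist()
    samples = df.columns[1:].tolist()
    ct = np.empty((len(genes), len(samples)))
    for j, col in enumerate(samples):
        for i, cell in enumerate(df[col]):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() == "":
                ct[i, j] = np.nan
                continue
            try:
                ct[i, j] = float(cell)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric Ct at gene {genes[i]!r}, sample {col!r} "
                    f"(row {i + 2}): {cell!r}"
                ) from None
    return ExpressionMatrix(genes=genes, samples=samples, ct=ct, reference_gene=reference_gene)


def write_ct_matrix(expr: ExpressionMatrix, path) -> None:
    frame = expr.to_frame()
    frame.insert(0, "gene", frame.index)
    frame.to_csv(path, index=False)


def read_partition(path) -> GenePartition:
    with open(path) as fh:
        try:
            d = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid JSON ({exc})") from None
    for key in ("score_a", "score_b"):
        if key not in d:
            raise FormatError(f"{path}: missing key {key!r}")
    return GenePartition.from_dict(d)


def write_partition(partition: GenePartition, path) -> None:
    with open(path, "w") as fh:
        json.dump(partition.to_dict(), fh, indent=2)
        fh.write("\n")


def write_scores(scores: IFNScores, path) -> None:
    scores.to_frame().to_csv(path)


def read_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="sample")
    for col in ("score_a", "score_b"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return df


def read_metadata(path, require_outcome: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    if require_outcome and "outcome" not in df.columns:
        raise FormatError(f"{path}: missing required column 'outcome'")
    return df


def write_cohort(table: CohortTable, path) -> None:
    table.data.to_csv(path, index_label="sample")


def read_cohort(path) -> CohortTable:
    return CohortTable(read_metadata(path))


def read_transition_table(path) -> PairedCategoryTable:
    """Square CSV: header row/index are the category labels, cells are counts."""
    df = pd.read_csv(path, index_col=0)
    if list(df.index.astype(str)) != [str(c) for c in df.columns]:
        raise FormatError(f"{path}: row and column categories must match")
    return PairedCategoryTable(
        categories=[str(c) for c in df.columns], counts=df.to_numpy()
    )


def write_transition_table(table: PairedCategoryTable, path) -> None:
    pd.DataFrame(table.counts, index=table.categories, columns=table.categories).to_csv(path)
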