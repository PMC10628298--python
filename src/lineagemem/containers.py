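"""Shared in-memory containers.

The toolkit moves three kinds of data between modules:

* :class:`CountMatrix` -- genes x cells non-negative integer counts with
  gene and cell labels (the single-cell expression matrix).
* :class:`NormalizedMatrix` -- the dense log-normalized counterpart.
* *cell tables* -- plain :class:`pandas.DataFrame` objects with the columns
  in :data:`CELL_TABLE_COLUMNS`, one row per cell, linking cell id, sample,
  lineage id, state label and (optionally) the primed signature score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

#: Canonical column order for per-cell tables.
CELL_TABLE_COLUMNS = ("cell_id", "sample_id", "lineage_id", "state", "primed_score")

#: State labels: drug-susceptible, primed, intermediate.
STATES = ("S", "P", "I")


def _check_labels(labels: Sequence[str], what: str) -> list:
    labels = list(labels)
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate {what} labels")
    return labels


@dataclass
class CountMatrix:
    """Genes x cells count matrix with labels.

    ``values`` is stored as CSR; any array-like with non-negative entries is
    accepted. Dimensions must match the label lists (genes are rows).
    """

    values: sp.spmatrix
    genes: list
    cells: list

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.genes = _check_labels(self.genes, "gene")
        self.cells = _check_labels(self.cells, "cell")
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())

    def gene_indices(self, names: Iterable[str]) -> np.ndarray:
        """Row indices of ``names``; raises ``KeyError`` listing missing genes."""
        lookup = {g: i for i, g in enumerate(self.genes)}
        missing = [g for g in names if g not in lookup]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        return np.array([lookup[g] for g in names], dtype=int)


@dataclass
class NormalizedMatrix:
    """Dense log-normalized expression, genes x cells."""

    values: np.ndarray
    genes: list
    cells: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.genes = _check_labels(self.genes, "gene")
        self.cells = _check_labels(self.cells, "cell")
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise ValueError("normalized matrix shape does not match labels")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def gene_indices(self, names: Iterable[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.genes)}
        missing = [g for g in names if g not in lookup]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        return np.array([lookup[g] for g in names], dtype=int)

    def cell_indices(self, names: Iterable[str]) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.cells)}
        missing = [c for c in names if c not in lookup]
        if missing:
            raise KeyError(f"cells not in matrix: {missing}")
        return np.array([lookup[c] for c in names], dtype=int)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.cells)


def make_cell_table(
    cell_id,
    sample_id,
    lineage_id,
    state,
    primed_score=None,
) -> pd.DataFrame:
    """Assemble a validated cell table (see :data:`CELL_TABLE_COLUMNS`)."""
    df = pd.DataFrame(
        {
            "cell_id": pd.Series(cell_id, dtype="string"),
            "sample_id": pd.Series(sample_id, dtype="string"),
            "lineage_id": pd.Series(lineage_id, dtype="string"),
            "state": pd.Series(state, dtype="string"),
        }
    )
    df["primed_score"] = np.nan if primed_score is None else np.asarray(primed_score, float)
    return validate_cell_table(df)


def validate_cell_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CELL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cell table missing columns: {missing}")
    if df["cell_id"].duplicated().any():
        dups = df.loc[df["cell_id"].duplicated(), "cell_id"].tolist()[:5]
        raise ValueError(f"duplicate cell ids in cell table, e.g. {dups}")
    bad = set(df["state"].dropna()) - set(STATES)
    if bad:
        raise ValueError(f"unknown state labels: {sorted(bad)}")
    return df
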