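"""File formats: FASTQ, Matrix Market count matrices, tables, manifests.

FASTQ parsing is delegated to Biopython's fast tuple iterator; count
matrices go through :mod:`scipy.io` Matrix Market readers/writers with two
one-column label tables (``genes.tsv`` / ``cells.tsv``) alongside
``matrix.mtx``, the usual single-cell layout.
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .containers import CountMatrix


def read_fastq(path):
    """Yield ``(name, sequence, quality)`` tuples from a 4-line FASTQ file.

    A truncated or malformed record raises ``ValueError`` naming the
    approximate line.
    """
    with open(path) as fh:
        it = FastqGeneralIterator(fh)
        i = 0
        while True:
            try:
                rec = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(
                    f"malformed FASTQ record near line {4 * i + 1} of {path}: {exc}"
                ) from exc
            i += 1
            yield rec


def write_fastq(path, reads: Iterable) -> int:
    """Write ``(name, sequence, quality)`` tuples as 4-line FASTQ; returns count."""
    n = 0
    with open(path, "w") as fh:
        for name, seq, qual in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def write_matrix(matrix: CountMatrix, directory) -> None:
    """Write a count matrix as ``matrix.mtx`` + ``genes.tsv`` + ``cells.tsv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(directory / "matrix.mtx"), sp.coo_matrix(matrix.values))
    (directory / "genes.tsv").write_text("".join(f"{g}\n" for g in matrix.genes))
    (directory / "cells.tsv").write_text("".join(f"{c}\n" for c in matrix.cells))


def read_matrix(directory) -> CountMatrix:
    """Read a count matrix written by :func:`write_matrix`.

    Label/dimension mismatches raise ``ValueError`` naming both counts.
    """
    directory = Path(directory)
    values = sp.csr_matrix(scipy.io.mmread(str(directory / "matrix.mtx")))
    genes = (directory / "genes.tsv").read_text().splitlines()
    cells = (directory / "cells.tsv").read_text().splitlines()
    if values.shape[0] != len(genes) or values.shape[1] != len(cells):
        raise ValueError(
            f"matrix is {values.shape[0]} x {values.shape[1]} but labels give "
            f"{len(genes)} genes and {len(cells)} cells"
        )
    if values.nnz and not np.allclose(values.data, np.round(values.data)):
        raise ValueError("count matrix contains non-integer values")
    values = values.astype(np.int64)
    return CountMatrix(values, genes=genes, cells=cells)


def write_manifest(directory, payload: Mapping) -> Path:
    """Write a JSON run manifest echoing every effective parameter and seed."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / "manifest.json"
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_jsonify))
    return path


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dict__"):
        return vars(obj)
    return str(obj)


def read_cell_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"cell_id": str, "sample_id": str, "lineage_id": str})
    return df


def write_cell_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
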