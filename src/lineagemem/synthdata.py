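"""Synthetic data generation.

Everything needed to exercise the toolkit without any external download:

* WSN-patterned lineage barcode libraries (W = A/T, S = G/C, N = any base,
  repeating in that order), mirroring the semi-random 100-nt transcribed
  barcodes delivered by lentivirus in lineage-tracing experiments;
* noisy barcode reads in FASTQ form (anchor + barcode, i.i.d. substitution
  errors, read names carrying cell id and UMI);
* two-state negative-binomial count matrices in which primed (P) cells
  up-regulate primed marker genes (NT5E, EGFR, AXL, FN1, SERPINE2) and
  drug-susceptible (S) cells up-regulate melanocytic markers (SOX10, MITF);
* lognormal flow-cytometry-like intensity tables with a shifted primed
  component.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import CountMatrix

#: Marker genes up-regulated in the primed (drug-resistance-prone) state.
PRIMED_MARKERS = ("NT5E", "EGFR", "AXL", "FN1", "SERPINE2")
#: Marker genes up-regulated in the drug-susceptible (melanocytic) state.
SUSCEPTIBLE_MARKERS = ("SOX10", "MITF")

#: Default "known sequence" preceding the lineage barcode in every read.
#: The anchor is a configuration value, not a biological constant.
DEFAULT_ANCHOR = "ATCGACTGGTACCTCATCAGGC"

_WSN_POOLS = ("AT", "GC", "ACGT")
_UMI_LENGTH = 12
_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")


@dataclass
class SynthConfig:
    """Parameters of the synthetic study.

    Defaults reflect the emulated experiment: ~2% of drug-naive cells are
    primed, markers show a strong (8x) fold change, ~20% of cells carry a
    lineage barcode, and sequencing introduces rare substitution errors.
    """

    n_cells: int = 2000
    n_genes: int = 200
    primed_fraction: float = 0.02
    marker_up_primed: tuple = PRIMED_MARKERS
    marker_up_susceptible: tuple = SUSCEPTIBLE_MARKERS
    nb_mean_base: float = 3.0
    nb_dispersion: float = 3.0
    marker_fold_change: float = 8.0
    read_error_rate: float = 0.005
    infected_fraction: float = 0.2
    seed: int = 0
    barcode_length: int = 100
    anchor: str = DEFAULT_ANCHOR
    indel_rate: float = 0.0  # optional stress-test knob; substitutions only by default

    def __post_init__(self) -> None:
        for name in ("primed_fraction", "read_error_rate", "infected_fraction", "indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.nb_mean_base <= 0:
            raise ValueError("nb_mean_base must be > 0")
        if self.marker_fold_change <= 0:
            raise ValueError("marker_fold_change must be > 0")
        if set(self.marker_up_primed) & set(self.marker_up_susceptible):
            raise ValueError("marker sets must be disjoint")
        if self.n_cells < 1 or self.n_genes < 1:
            raise ValueError("n_cells and n_genes must be >= 1")


@dataclass
class BarcodeLibrary:
    """An ordered collection of unique WSN-patterned barcode sequences."""

    sequences: list
    length: int = 100

    def __post_init__(self) -> None:
        self.sequences = list(self.sequences)
        if len(set(self.sequences)) != len(self.sequences):
            raise ValueError("barcode library sequences must be unique")
        pat = wsn_regex(self.length)
        for s in self.sequences:
            if not pat.fullmatch(s):
                raise ValueError(f"sequence does not match the WSN pattern: {s}")

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)


def wsn_regex(length: int) -> re.Pattern:
    """Compiled regular expression for a WSN-repeat barcode of ``length``."""
    unit = ("[AT]", "[GC]", "[ACGT]")
    return re.compile("".join(unit[i % 3] for i in range(length)))


def gen_barcode_library(n: int, length: int = 100, seed: int = 0) -> BarcodeLibrary:
    """Draw ``n`` unique WSN-repeat barcodes of ``length`` nucleotides.

    Position ``i`` (0-based) holds W if ``i % 3 == 0``, S if ``i % 3 == 1``
    and N if ``i % 3 == 2``. The length need not be a multiple of three:
    the canonical 100-nt barcode ends on a partial repeat.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if length < 1:
        raise ValueError(f"barcode length must be >= 1, got {length}")
    pool_sizes = [len(_WSN_POOLS[i % 3]) for i in range(length)]
    capacity = math.prod(pool_sizes)
    if n > capacity:
        raise ValueError(
            f"cannot draw {n} unique barcodes: the length-{length} WSN space "
            f"holds only {capacity} sequences"
        )
    rng = np.random.default_rng(seed)
    seen: dict = {}
    out: list = []
    while len(out) < n:
        k = n - len(out)
        cols = np.empty((k, length), dtype="U1")
        for j in range(length):
            pool = np.array(list(_WSN_POOLS[j % 3]))
            cols[:, j] = rng.choice(pool, size=k)
        for row in cols:
            s = "".join(row)
            if s not in seen:
                seen[s] = True
                out.append(s)
    return BarcodeLibrary(out, length=length)


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    """Apply i.i.d. substitution errors at per-base ``rate``."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    if hits.size == 0:
        return seq
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def gen_reads(
    library: BarcodeLibrary,
    cell_assignments: Mapping[str, str],
    reads_per_cell: int,
    config: SynthConfig,
    seed: int | None = None,
) -> list:
    """Generate noisy barcode reads for each assigned cell.

    Each read is ``anchor + lineage barcode`` with substitution errors at
    ``config.read_error_rate`` applied across the whole sequence; the read
    name encodes the cell id and a random UMI as ``cell:umi``. Returns a
    list of ``(name, sequence, quality)`` tuples (valid FASTQ records when
    written with :func:`lineagemem.io.write_fastq`).
    """
    if reads_per_cell == 0:
        warnings.warn("reads_per_cell is 0; no reads generated")
        return []
    if reads_per_cell < 0:
        raise ValueError("reads_per_cell must be >= 0")
    valid = set(library.sequences)
    for cell, bc in cell_assignments.items():
        if bc not in valid:
            raise ValueError(f"cell {cell} assigned a barcode absent from the library")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    reads = []
    for cell in cell_assignments:
        bc = cell_assignments[cell]
        for _ in range(reads_per_cell):
            umi = "".join(_BASES[rng.integers(4, size=_UMI_LENGTH)])
            seq = _mutate(config.anchor + bc, rng, config.read_error_rate)
            qual = "I" * len(seq)
            reads.append((f"{cell}:{umi}", seq, qual))
    return reads


def gen_counts(
    states: Mapping[str, str],
    config: SynthConfig,
    seed: int | None = None,
) -> CountMatrix:
    """Negative-binomial two-state count matrix.

    ``states`` maps cell id to "S" or "P". Counts are drawn NB with mean
    ``nb_mean_base`` and dispersion ``nb_dispersion`` (variance
    ``mu + mu^2 / dispersion``); marker genes of a cell's own state have
    their mean multiplied by ``marker_fold_change``.
    """
    bad = set(states.values()) - {"S", "P"}
    if bad:
        raise ValueError(f"states must be 'S' or 'P', got {sorted(bad)}")
    cells = list(states)
    markers_p = list(config.marker_up_primed)
    markers_s = list(config.marker_up_susceptible)
    if not markers_p and not markers_s:
        warnings.warn("empty marker sets: generating a plain NB matrix")
    markers = markers_p + markers_s
    n_filler = max(config.n_genes - len(markers), 0)
    genes = markers + [f"gene_{i:04d}" for i in range(n_filler)]

    rng = np.random.default_rng(config.seed if seed is None else seed)
    mu = np.full((len(genes), len(cells)), config.nb_mean_base)
    is_primed = np.array([states[c] == "P" for c in cells])
    for g in markers_p:
        mu[genes.index(g), is_primed] *= config.marker_fold_change
    for g in markers_s:
        mu[genes.index(g), ~is_primed] *= config.marker_fold_change

    r = config.nb_dispersion
    lam = rng.gamma(shape=r, scale=mu / r)
    counts = rng.poisson(lam)
    return CountMatrix(counts, genes=genes, cells=cells)


def gen_flow(
    n_events: int,
    primed_fraction: float,
    shift: float,
    seed: int = 0,
    log_mean: float = 4.0,
    log_sd: float = 0.5,
) -> pd.DataFrame:
    """Lognormal intensity mixture with a shifted primed component.

    The primed component's location is shifted by ``shift`` on the natural
    log scale. Returns one row per event with columns ``event_id``,
    ``intensity`` and the latent ``label`` ("P"/"S").
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if not 0.0 <= primed_fraction <= 1.0:
        raise ValueError(f"primed_fraction must be in [0, 1], got {primed_fraction}")
    rng = np.random.default_rng(seed)
    primed = rng.random(n_events) < primed_fraction
    log_i = rng.normal(log_mean + shift * primed, log_sd)
    return pd.DataFrame(
        {
            "event_id": [f"e{i:06d}" for i in range(n_events)],
            "intensity": np.exp(log_i),
            "label": np.where(primed, "P", "S"),
        }
    )


def assign_barcodes(
    cells: Sequence[str],
    library: BarcodeLibrary,
    infected_fraction: float = 1.0,
    seed: int = 0,
) -> dict:
    """Assign one library barcode per infected cell (uniform with replacement).

    Cells that escape infection (probability ``1 - infected_fraction``)
    receive no barcode and are absent from the returned map.
    """
    rng = np.random.default_rng(seed)
    out = {}
    seqs = library.sequences
    for cell in cells:
        if rng.random() < infected_fraction:
            out[cell] = seqs[rng.integers(len(seqs))]
    return out
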