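"""Lineage barcode recovery, error-correction clustering and cell assignment.

The processing chain mirrors how transcribed lineage barcodes are recovered
in barcoded scRNA-seq experiments:

1. :func:`extract_barcodes` -- scan each read for a known anchor sequence
   (allowing a few substitutions) and take the following L nucleotides as
   the barcode, collapsing duplicate reads per (cell, barcode) by UMI.
2. :func:`cluster_barcodes` -- merge sequencing-error variants into the most
   frequently observed sequence (greedy sphere clustering by Levenshtein
   distance, the behaviour popularised by starcode-style tools).
3. :func:`assign_lineages` -- one lineage per retained cell, applying the
   filtering rules used for real data: lineages seen in more than one
   independently-barcoded sample are impossible and removed; cells with
   several barcodes are kept only when the same barcode combination recurs
   in at least two cells; small lineages (< ``min_cells``) are dropped.
4. :func:`filter_oversized` -- remove lineages larger than plausible given
   the number of doublings cells were allowed.

Filters only ever remove cells or lineages; no assignment is rewritten.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

SHARING_DESIGNS = ("independent_samples", "shared_split")

#: Drop reason codes recorded on dropped cells.
DROP_AMBIGUOUS = "ambiguous_multibarcode"
DROP_CROSS_SAMPLE = "cross_sample"
DROP_TOO_FEW = "too_few_cells"
DROP_OVERSIZED = "oversized"


@dataclass(frozen=True)
class BarcodeCount:
    """UMI-collapsed support for one barcode sequence in one cell."""

    sequence: str
    cell_id: str
    read_count: int
    umi_count: int

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty barcode sequence")
        if self.read_count < 1 or self.umi_count < 1:
            raise ValueError("counts must be >= 1")


@dataclass(frozen=True)
class LineageAssignment:
    """Lineage call for one cell; ``drop_reason`` is None for retained cells."""

    cell_id: str
    sample_id: str
    lineage_id: str
    n_supporting_umis: int
    drop_reason: str | None = None

    @property
    def retained(self) -> bool:
        return self.drop_reason is None


@dataclass
class ExtractResult:
    counts: list
    n_reads: int = 0
    n_no_anchor: int = 0
    n_too_short: int = 0


def _find_anchor(seq: str, anchor_arr: np.ndarray, max_mismatch: int) -> int:
    """Leftmost window with the fewest mismatches, or -1 if above the cap."""
    sa = np.frombuffer(seq.encode(), dtype=np.uint8)
    if sa.size < anchor_arr.size:
        return -1
    win = np.lib.stride_tricks.sliding_window_view(sa, anchor_arr.size)
    mm = (win != anchor_arr).sum(axis=1)
    j = int(mm.argmin())
    return j if mm[j] <= max_mismatch else -1


def extract_barcodes(
    reads: Iterable,
    anchor: str,
    max_anchor_mismatch: int = 2,
    barcode_length: int = 100,
) -> ExtractResult:
    """Pull lineage barcodes out of reads by anchored scanning.

    ``reads`` yields ``(name, sequence, quality)`` with names formatted
    ``cell:umi``. For each read the anchor is located allowing up to
    ``max_anchor_mismatch`` substitutions (leftmost best window); the
    ``barcode_length`` nucleotides that follow are the barcode. Reads with
    no acceptable anchor window, or too short to hold a full barcode after
    the hit, are skipped and tallied.
    """
    if len(anchor) < 10:
        raise ValueError("anchor must be at least 10 nt")
    anchor_arr = np.frombuffer(anchor.encode(), dtype=np.uint8)
    res = ExtractResult(counts=[])
    read_counts: dict = defaultdict(int)
    umis: dict = defaultdict(set)
    for name, seq, _qual in reads:
        res.n_reads += 1
        cell, _, umi = name.split()[0].partition(":")
        pos = _find_anchor(seq, anchor_arr, max_anchor_mismatch)
        if pos < 0:
            res.n_no_anchor += 1
            continue
        start = pos + len(anchor)
        if len(seq) < start + barcode_length:
            res.n_too_short += 1
            continue
        bc = seq[start : start + barcode_length]
        read_counts[(cell, bc)] += 1
        umis[(cell, bc)].add(umi)
    res.counts = [
        BarcodeCount(sequence=bc, cell_id=cell, read_count=n, umi_count=len(umis[(cell, bc)]))
        for (cell, bc), n in sorted(read_counts.items())
    ]
    return res


def _levenshtein_at_most(a: str, b: str, k: int):
    """Levenshtein distance if <= k else None (edlib banded alignment)."""
    d = edlib.align(a, b, task="distance", k=k)["editDistance"]
    return d if d >= 0 else None


def cluster_barcodes(
    counts: Iterable[BarcodeCount],
    max_dist: int = 5,
    merge_ratio: float = 5.0,
) -> dict:
    """Greedy error-correction clustering; returns sequence -> canonical map.

    Sequences are visited in descending total read count (ties broken
    lexicographically). A sequence merges into the highest-count existing
    canonical whose Levenshtein distance is <= ``max_dist`` and whose count
    is >= ``merge_ratio`` times its own; otherwise it founds a new
    canonical. The map is idempotent (canonicals map to themselves).

    Defaults (``max_dist=5``, ``merge_ratio=5``) follow the documented
    defaults of starcode-style sphere clustering for ~100-nt sequences.
    """
    totals: dict = defaultdict(int)
    for c in counts:
        totals[c.sequence] += c.read_count
    order = sorted(totals, key=lambda s: (-totals[s], s))
    canonical: list = []  # (sequence, total) in descending-count order
    mapping: dict = {}
    for s in order:
        cnt = totals[s]
        target = None
        for cs, cc in canonical:
            if cc < merge_ratio * cnt:
                # canonicals are sorted by count; later ones are no bigger
                break
            if _levenshtein_at_most(s, cs, max_dist) is not None:
                target = cs
                break
        if target is None:
            canonical.append((s, cnt))
            mapping[s] = s
        else:
            mapping[s] = target
    return mapping


def canonicalize(counts: Iterable[BarcodeCount], mapping: Mapping[str, str]) -> list:
    """Re-key counts by canonical sequence, summing support per (cell, canonical)."""
    agg: dict = {}
    for c in counts:
        key = (c.cell_id, mapping.get(c.sequence, c.sequence))
        if key in agg:
            prev = agg[key]
            agg[key] = replace(
                prev,
                read_count=prev.read_count + c.read_count,
                umi_count=prev.umi_count + c.umi_count,
            )
        else:
            agg[key] = replace(c, sequence=key[1])
    return [agg[k] for k in sorted(agg)]


def resolve_multibarcode(
    cells_with_multiple_barcodes: Mapping[str, Iterable[str]],
    umi_counts: Mapping | None = None,
    samples: Mapping[str, str] | None = None,
) -> list:
    """Group multi-barcode cells by their full barcode combination.

    A sorted barcode combination observed in >= 2 cells becomes a
    combination lineage keyed by the joined sorted set (``b1+b2``);
    combinations seen in exactly one cell are ambiguous and dropped.
    """
    keys: dict = {}
    for cell, bcs in cells_with_multiple_barcodes.items():
        bcs = sorted(set(bcs))
        if len(bcs) < 2:
            raise ValueError(f"cell {cell} does not have multiple barcodes")
        keys[cell] = "+".join(bcs)
    by_key: dict = defaultdict(list)
    for cell, key in keys.items():
        by_key[key].append(cell)
    out = []
    for cell in cells_with_multiple_barcodes:
        key = keys[cell]
        n_umi = 0
        if umi_counts is not None:
            n_umi = sum(
                umi_counts.get((cell, bc), 0) for bc in key.split("+")
            )
        out.append(
            LineageAssignment(
                cell_id=cell,
                sample_id=samples.get(cell, "") if samples else "",
                lineage_id=key,
                n_supporting_umis=max(n_umi, 0),
                drop_reason=None if len(by_key[key]) >= 2 else DROP_AMBIGUOUS,
            )
        )
    return out


def assign_lineages(
    counts: Iterable[BarcodeCount],
    samples: Mapping[str, str],
    sharing_design: str = "independent_samples",
    min_cells: int = 3,
) -> list:
    """Assign each cell to one lineage, applying the standard filters.

    ``counts`` must already be canonicalized (see :func:`cluster_barcodes`
    and :func:`canonicalize`). Cells with one barcode take it as their
    lineage; cells with several take the top barcode when its UMI support
    strictly dominates, and otherwise fall back to the combination rule of
    :func:`resolve_multibarcode`. Under ``independent_samples`` any lineage
    observed in more than one sample is removed entirely; under
    ``shared_split`` (split-plate designs where every barcode is expected
    in all conditions) cross-sample sharing is kept. Lineages with fewer
    than ``min_cells`` total cells are dropped.
    """
    if sharing_design not in SHARING_DESIGNS:
        raise ValueError(
            f"unknown sharing_design {sharing_design!r}; expected one of {SHARING_DESIGNS}"
        )
    per_cell: dict = defaultdict(dict)
    for c in counts:
        per_cell[c.cell_id][c.sequence] = per_cell[c.cell_id].get(c.sequence, 0) + c.umi_count
    unknown = [cell for cell in per_cell if cell not in samples]
    if unknown:
        raise ValueError(f"cells with no sample id: {sorted(unknown)[:5]}")

    assignments: list = []
    multi: dict = {}
    multi_umis: dict = {}
    for cell in sorted(per_cell):
        bcs = per_cell[cell]
        if len(bcs) == 1:
            (seq, numi), = bcs.items()
            assignments.append(
                LineageAssignment(cell, samples[cell], seq, numi)
            )
            continue
        ranked = sorted(bcs.items(), key=lambda kv: (-kv[1], kv[0]))
        if ranked[0][1] > ranked[1][1]:
            assignments.append(
                LineageAssignment(cell, samples[cell], ranked[0][0], ranked[0][1])
            )
        else:
            multi[cell] = list(bcs)
            for seq, numi in bcs.items():
                multi_umis[(cell, seq)] = numi
    if multi:
        assignments.extend(resolve_multibarcode(multi, multi_umis, samples))
    assignments.sort(key=lambda a: a.cell_id)

    # cross-sample elimination (impossible lineages in independently barcoded samples)
    if sharing_design == "independent_samples":
        lineage_samples: dict = defaultdict(set)
        for a in assignments:
            if a.retained:
                lineage_samples[a.lineage_id].add(a.sample_id)
        assignments = [
            replace(a, drop_reason=DROP_CROSS_SAMPLE)
            if a.retained and len(lineage_samples[a.lineage_id]) > 1
            else a
            for a in assignments
        ]

    # minimum lineage size
    sizes: dict = defaultdict(int)
    for a in assignments:
        if a.retained:
            sizes[a.lineage_id] += 1
    assignments = [
        replace(a, drop_reason=DROP_TOO_FEW)
        if a.retained and sizes[a.lineage_id] < min_cells
        else a
        for a in assignments
    ]
    return assignments


def filter_oversized(
    assignments: Sequence[LineageAssignment],
    doublings: float,
    slack: float = 2.0,
) -> tuple:
    """Drop lineages larger than ``slack * 2**doublings`` cells.

    Lineages bigger than expected from the available proliferation time are
    likely barcode collisions. Returns ``(assignments, report)`` where the
    report maps each removed lineage id to its size. ``slack=inf`` is the
    identity.
    """
    if doublings < 1:
        raise ValueError("doublings must be >= 1")
    threshold = slack * 2.0 ** doublings
    sizes: dict = defaultdict(int)
    for a in assignments:
        if a.retained:
            sizes[a.lineage_id] += 1
    removed = {lid: n for lid, n in sizes.items() if n > threshold}
    out = [
        replace(a, drop_reason=DROP_OVERSIZED)
        if a.retained and a.lineage_id in removed
        else a
        for a in assignments
    ]
    return out, removed


def assignments_to_table(assignments: Sequence[LineageAssignment]) -> pd.DataFrame:
    """All assignments (retained and dropped) as a flat table."""
    return pd.DataFrame(
        {
            "cell_id": [a.cell_id for a in assignments],
            "sample_id": [a.sample_id for a in assignments],
            "lineage_id": [a.lineage_id for a in assignments],
            "n_supporting_umis": [a.n_supporting_umis for a in assignments],
            "drop_reason": [a.drop_reason for a in assignments],
        }
    )


def retained(assignments: Iterable[LineageAssignment]) -> list:
    return [a for a in assignments if a.retained]
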