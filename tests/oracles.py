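"""Independent reference implementations used as test oracles.

Deliberately naive and separate from the package internals: plain dynamic
programming, exhaustive enumeration and direct formula evaluation, so that
each oracle checks the optimized implementation from the outside.
"""

from __future__ import annotations

import itertools

import numpy as np


def levenshtein(a: str, b: str) -> int:
    """Classic O(len(a)*len(b)) edit-distance DP (numpy row recurrence)."""
    if len(a) < len(b):
        a, b = b, a
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    prev = np.arange(len(b) + 1)
    for i, ca in enumerate(a.encode(), start=1):
        cur = np.empty(len(b) + 1, dtype=int)
        cur[0] = i
        sub = prev[:-1] + (bb != ca)
        np.minimum(sub, prev[1:] + 1, out=cur[1:])
        # insertion needs a left-to-right scan
        for j in range(1, len(b) + 1):
            if cur[j - 1] + 1 < cur[j]:
                cur[j] = cur[j - 1] + 1
        prev = cur
    return int(prev[-1])


def min_pairwise_levenshtein(seqs) -> int:
    return min(
        levenshtein(x, y) for x, y in itertools.combinations(seqs, 2)
    )


def greedy_cluster(totals: dict, max_dist: int, merge_ratio: float) -> dict:
    """Reference greedy sphere clustering (descending count, lexicographic ties)."""
    order = sorted(totals, key=lambda s: (-totals[s], s))
    canonical = []
    mapping = {}
    for s in order:
        target = None
        for c in canonical:
            if totals[c] >= merge_ratio * totals[s] and levenshtein(s, c) <= max_dist:
                target = c
                break
        if target is None:
            canonical.append(s)
            mapping[s] = s
        else:
            mapping[s] = target
    return mapping


def sliding_hamming_scan(seq: str, anchor: str, max_mismatch: int) -> int:
    """Brute-force anchor scan: leftmost window with <= max_mismatch, else -1."""
    best_pos, best_mm = -1, len(anchor) + 1
    for i in range(len(seq) - len(anchor) + 1):
        mm = sum(x != y for x, y in zip(seq[i : i + len(anchor)], anchor))
        if mm < best_mm:
            best_pos, best_mm = i, mm
    return best_pos if best_mm <= max_mismatch else -1


def purity_by_enumeration(p: float, doublings: int) -> float:
    """P(lineage stays pure) by exhaustive enumeration of every daughter draw.

    A complete binary tree of `doublings` levels has 2*(2**doublings - 1)
    daughter draws; the lineage is pure iff none switched.
    """
    n_draws = 2 * (2 ** doublings - 1)
    total = 0.0
    for outcome in itertools.product((0, 1), repeat=n_draws):
        k = sum(outcome)
        if k == 0:
            total += (1 - p) ** n_draws
    return total


def rank_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC by direct pairwise comparison (ties count half)."""
    pos = np.asarray(pos, float)[:, None]
    neg = np.asarray(neg, float)[None, :]
    return float(((pos > neg).sum() + 0.5 * (pos == neg).sum()) / (pos.size * neg.size))
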