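"""Expression normalization, signature scoring, state calling, DE, flow gating.

State calling here is signature-based rather than graph-cluster-based: each
cell is scored against a primed gene set with a rank-based (UCell-style)
statistic, and the primed/susceptible boundary comes either from a
two-component Gaussian mixture on the scores or from a fixed top-quantile.
The chosen method is echoed in the returned metadata so runs are auditable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.mixture import GaussianMixture

from .containers import CountMatrix, NormalizedMatrix


def lognormalize(counts: CountMatrix, scale: float = 10_000.0) -> NormalizedMatrix:
    """Library-size log normalization: ``log(1 + scale * count / column_sum)``.

    Natural log; zero counts stay exactly zero. An all-zero cell has no
    library size and is rejected by id.
    """
    dense = counts.to_dense().astype(float)
    colsum = dense.sum(axis=0)
    zero = np.nonzero(colsum == 0)[0]
    if zero.size:
        ids = [counts.cells[i] for i in zero[:5]]
        raise ValueError(f"cells with zero total counts: {ids}")
    values = np.log1p(scale * dense / colsum)
    return NormalizedMatrix(values, genes=list(counts.genes), cells=list(counts.cells))


def signature_score(
    normalized: NormalizedMatrix,
    gene_set: Iterable[str],
    rmax: int = 1500,
    name: str = "signature",
) -> pd.Series:
    """Rank-based gene-set score per cell (UCell-style Mann-Whitney statistic).

    Per cell, all genes are ranked by decreasing expression (ties get the
    average rank); ranks above ``rmax`` are clipped to ``rmax + 1``. With
    signature size ``m`` and rank-sum ``U = sum(ranks) - m(m+1)/2``, the
    score is ``1 - U / (m * rmax)`` clipped to [0, 1]. Being rank-based, the
    score is invariant to any monotone transform of expression.

    Signature genes absent from the matrix are listed in a warning and the
    score is computed over the intersection.
    """
    gene_set = list(dict.fromkeys(gene_set))
    present = [g for g in gene_set if g in set(normalized.genes)]
    missing = [g for g in gene_set if g not in set(normalized.genes)]
    if missing:
        warnings.warn(f"signature genes absent from matrix: {missing}")
    if not present:
        raise ValueError("no signature genes present in the matrix")
    idx = normalized.gene_indices(present)
    ranks = scipy.stats.rankdata(-normalized.values, axis=0, method="average")
    capped = np.minimum(ranks, rmax + 1)
    m = len(present)
    u = capped[idx, :].sum(axis=0) - m * (m + 1) / 2.0
    score = np.clip(1.0 - u / (m * rmax), 0.0, 1.0)
    return pd.Series(score, index=list(normalized.cells), name=name)


def call_states(
    scores: pd.Series,
    method: str = "mixture",
    q: float = 0.02,
) -> pd.Series:
    """Label each cell "P" (primed) or "S" (drug-susceptible) from scores.

    ``mixture`` fits a two-component 1-D Gaussian mixture; the component
    with the higher mean is primed and cells are labelled by posterior
    (the boundary is the equal-posterior point). ``quantile`` labels the
    top ``q`` fraction of scores primed. Constant scores degenerate to all
    susceptible with a warning.
    """
    if len(scores) < 20:
        raise ValueError(f"need >= 20 cells to call states, got {len(scores)}")
    x = np.asarray(scores, dtype=float)
    labels = np.full(x.size, "S", dtype=object)
    if np.ptp(x) < 1e-12:
        warnings.warn("constant scores: all cells called susceptible")
        return pd.Series(labels, index=scores.index, name="state")
    if method == "mixture":
        gm = GaussianMixture(n_components=2, random_state=0, n_init=3)
        comp = gm.fit_predict(x[:, None])
        primed_comp = int(np.argmax(gm.means_.ravel()))
        labels[comp == primed_comp] = "P"
    elif method == "quantile":
        k = math.ceil(q * x.size) if q > 0 else 0
        if k > 0:
            top = np.argsort(-x, kind="stable")[:k]
            labels[top] = "P"
    else:
        raise ValueError(f"unknown method {method!r}; expected 'mixture' or 'quantile'")
    return pd.Series(labels, index=scores.index, name="state")


def de_wilcoxon(
    normalized: NormalizedMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    alpha: float = 0.05,
    lfc_cutoff: float = 0.25,
    min_expressed_fraction: float = 0.10,
) -> pd.DataFrame:
    """Per-gene two-sided Wilcoxon rank-sum differential expression.

    The test is exact for groups of <= 10 cells each (when the gene has no
    ties), and a tie-corrected normal approximation otherwise. Fold change
    is ``log2`` of group means of normalized expression with pseudocount 1.
    Genes expressed (non-zero) in fewer than ``min_expressed_fraction`` of
    the cells of *both* groups are excluded before testing (reported with
    NA p-values), and Bonferroni correction runs over the tested genes.
    A gene is significant when its adjusted p-value is below ``alpha`` and
    ``|log2 fold change| >= lfc_cutoff``.
    """
    cells = set(normalized.cells)
    a = [c for c in group_a if c in cells]
    b = [c for c in group_b if c in cells]
    if not a or not b:
        raise ValueError("a group has no cells present in the matrix")
    if len(a) < 3 or len(b) < 3:
        raise ValueError("both groups need >= 3 cells present in the matrix")
    xa = normalized.values[:, normalized.cell_indices(a)]
    xb = normalized.values[:, normalized.cell_indices(b)]

    frac_a = (xa > 0).mean(axis=1)
    frac_b = (xb > 0).mean(axis=1)
    pooled = np.concatenate([xa, xb], axis=1)
    constant = np.ptp(pooled, axis=1) < 1e-12
    tested = (~constant) & ((frac_a >= min_expressed_fraction) | (frac_b >= min_expressed_fraction))

    n_genes = len(normalized.genes)
    pvals = np.full(n_genes, np.nan)
    lfc = np.log2((xa.mean(axis=1) + 1.0) / (xb.mean(axis=1) + 1.0))

    idx = np.nonzero(tested)[0]
    if idx.size:
        small = xa.shape[1] <= 10 and xb.shape[1] <= 10
        if small:
            for i in idx:
                combined = pooled[i]
                has_ties = np.unique(combined).size < combined.size
                method = "asymptotic" if has_ties else "exact"
                pvals[i] = scipy.stats.mannwhitneyu(
                    xa[i], xb[i], alternative="two-sided", method=method
                ).pvalue
        else:
            res = scipy.stats.mannwhitneyu(
                xa[idx], xb[idx], alternative="two-sided", method="asymptotic", axis=1
            )
            pvals[idx] = res.pvalue

    n_tested = int(tested.sum())
    p_adj = np.minimum(pvals * n_tested, 1.0)
    significant = (p_adj < alpha) & (np.abs(lfc) >= lfc_cutoff)
    significant = np.where(np.isnan(p_adj), False, significant)
    return pd.DataFrame(
        {
            "gene": list(normalized.genes),
            "log2_fold_change": lfc,
            "p_value": pvals,
            "p_adjusted": p_adj,
            "significant": significant.astype(bool),
        }
    )


def derive_primed_geneset(de: pd.DataFrame) -> set:
    """Significant genes with positive log2 fold change (primed as group A)."""
    out = set(de.loc[de["significant"] & (de["log2_fold_change"] > 0), "gene"])
    if not out:
        warnings.warn("no significant up-regulated genes; primed gene set is empty")
    return out


def intermediate_call(
    normalized: NormalizedMatrix,
    states: pd.Series,
    crossing_up_genes: Iterable[str],
    q: float = 0.02,
    rmax: int = 1500,
) -> pd.Series:
    """Relabel the top-scoring susceptible cells as intermediate ("I").

    All cells are scored against the crossing-lineage gene set; among
    susceptible cells only, the top ``q`` fraction by score becomes "I"
    (at least one cell when any susceptible cells exist and ``q > 0``).
    Primed labels are never touched.
    """
    crossing_up_genes = list(crossing_up_genes)
    if not crossing_up_genes:
        raise ValueError("crossing_up_genes must be non-empty")
    scores = signature_score(normalized, crossing_up_genes, rmax=rmax, name="crossing")
    out = states.copy()
    s_cells = [c for c in states.index if states[c] == "S"]
    if q <= 0 or not s_cells:
        return out
    k = math.ceil(q * len(s_cells))
    s_scores = scores.loc[s_cells]
    top = s_scores.sort_values(ascending=False, kind="stable").index[:k]
    out.loc[top] = "I"
    return out


@dataclass
class FlowGateResult:
    threshold: float
    percent_primed: dict  # condition -> percent of events at/above threshold
    q: float


def flow_gate(
    control_intensities,
    treated_intensities: Mapping | None = None,
    q: float = 0.02,
) -> FlowGateResult:
    """Untreated-calibrated intensity gate.

    The threshold is the ``ceil(q * N)``-th largest control intensity, so
    that a fraction ``q`` of control events land at or above it (exactly
    ``ceil(qN)/N`` when control values are distinct). An event is primed
    iff its intensity is >= the threshold. Returns the threshold and the
    percent primed for the control and every treated condition.
    """
    control = np.asarray(control_intensities, dtype=float)
    if not 0 < q <= 1:
        raise ValueError(f"q must be in (0, 1], got {q}")
    if control.size < 1.0 / q:
        raise ValueError(f"control needs at least {math.ceil(1 / q)} events for q={q}")
    k = math.ceil(q * control.size)
    threshold = float(np.sort(control)[::-1][k - 1])
    percents = {"control": 100.0 * float(np.mean(control >= threshold))}
    for cond, vals in (treated_intensities or {}).items():
        vals = np.asarray(vals, dtype=float)
        if vals.size == 0:
            warnings.warn(f"condition {cond!r} has no events; percent primed is NA")
            percents[cond] = float("nan")
        else:
            percents[cond] = 100.0 * float(np.mean(vals >= threshold))
    return FlowGateResult(threshold=threshold, percent_primed=percents, q=q)
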