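"""Lineage memory classification and matched-lineage treatment comparisons.

A lineage's endpoint composition, together with its founder state, places
it in one of four memory categories:

* ``PURE_S`` -- susceptible founder, all cells still susceptible;
* ``PURE_P`` -- primed founder, all cells still primed;
* ``S_TO_P`` -- susceptible founder, lineage now mixed (a switch happened);
* ``P_TO_S`` -- primed founder, lineage no longer pure primed.

Intermediate ("I") cells count as susceptible for category purposes: the
intermediate state is a subset of the drug-susceptible population.
The module also provides the crossing-lineage DE cell selection, matched
split-plate lineage comparisons, a moment estimator of the per-division
switch probability from lineage purity, and a per-gene memory score
(one-way intraclass correlation with lineage as the grouping factor).
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import NormalizedMatrix

CATEGORIES = ("PURE_S", "PURE_P", "S_TO_P", "P_TO_S")


def classify_lineages(table: pd.DataFrame, founder_states: Mapping[str, str]) -> pd.DataFrame:
    """Classify every lineage into one of the four memory categories.

    ``table`` is a cell table (cells with NA lineage are ignored) and
    ``founder_states`` maps lineage id to the founder's state ("S"/"P"),
    known from sorted-sample identity or simulator truth. Lineages absent
    from the founder map are reported in a warning and excluded.

    Returns a frame indexed by lineage id with columns ``founder_state``,
    ``category``, ``size`` and ``primed_fraction``.
    """
    t = table.dropna(subset=["lineage_id"])
    rows = []
    missing = []
    for lid, grp in t.groupby("lineage_id", sort=True):
        if lid not in founder_states:
            missing.append(lid)
            continue
        founder = founder_states[lid]
        if founder not in ("S", "P"):
            raise ValueError(f"founder state for {lid} must be 'S' or 'P', got {founder!r}")
        n = len(grp)
        n_primed = int((grp["state"] == "P").sum())  # I counts as S
        if founder == "S":
            cat = "PURE_S" if n_primed == 0 else "S_TO_P"
        else:
            cat = "PURE_P" if n_primed == n else "P_TO_S"
        rows.append((lid, founder, cat, n, n_primed / n))
    if missing:
        warnings.warn(f"{len(missing)} lineages missing from founder map, excluded")
    out = pd.DataFrame(
        rows, columns=["lineage_id", "founder_state", "category", "size", "primed_fraction"]
    ).set_index("lineage_id")
    return out


def crossing_de_inputs(table: pd.DataFrame, classes: pd.DataFrame) -> tuple:
    """Cell sets for the crossing-lineage differential expression.

    Group A: susceptible cells from pure susceptible lineages. Group B:
    the susceptible cells only from lineages that switched from the
    susceptible to the primed state (their primed cells are excluded --
    the comparison looks for a transcriptional pre-switching signature in
    cells that have not yet switched).
    """
    pure_s = classes.index[classes["category"] == "PURE_S"]
    s_to_p = classes.index[classes["category"] == "S_TO_P"]
    if len(pure_s) == 0 or len(s_to_p) == 0:
        raise ValueError("need at least one PURE_S and one S_TO_P lineage")
    t = table.dropna(subset=["lineage_id"])
    not_primed = t["state"] != "P"
    a = t.loc[t["lineage_id"].isin(pure_s) & not_primed, "cell_id"].tolist()
    b = t.loc[t["lineage_id"].isin(s_to_p) & not_primed, "cell_id"].tolist()
    if not b:
        raise ValueError("no susceptible cells available in switching lineages")
    return a, b


def matched_lineage_fractions(
    tables: Mapping[str, pd.DataFrame],
    reference: str,
    ref_state: str | None = "S",
) -> pd.DataFrame:
    """Per-lineage primed fractions across conditions of a split-plate design.

    Lineages are selected whose reference-condition cells are 100% in
    ``ref_state`` ("S" treats intermediate cells as susceptible); pass
    ``ref_state=None`` to keep every lineage present in the reference.
    The returned frame has one row per selected lineage and one column per
    condition holding the primed fraction there (NaN where the lineage was
    not captured).
    """
    if reference not in tables:
        raise ValueError(f"reference condition {reference!r} not among {list(tables)}")
    if ref_state not in ("S", "P", None):
        raise ValueError("ref_state must be 'S', 'P' or None")
    ref = tables[reference].dropna(subset=["lineage_id"])
    selected = []
    for lid, grp in ref.groupby("lineage_id", sort=True):
        states = grp["state"].replace({"I": "S"})
        if ref_state is None or (states == ref_state).all():
            selected.append(lid)
    out = pd.DataFrame(index=pd.Index(selected, name="lineage_id"), dtype=float)
    for cond, t in tables.items():
        t = t.dropna(subset=["lineage_id"])
        frac = t.groupby("lineage_id")["state"].agg(lambda s: float((s == "P").mean()))
        out[cond] = frac.reindex(selected)
    return out


def fraction_reduced(fractions: pd.DataFrame, condition: str, reference: str) -> float:
    """Proportion of lineages with strictly lower primed fraction under treatment.

    Computed over lineages observed in both conditions; ties count as
    not-reduced. Returns NaN when no lineage is comparable.
    """
    for col in (condition, reference):
        if col not in fractions.columns:
            raise ValueError(f"condition {col!r} not in fractions table")
    both = fractions[[condition, reference]].dropna()
    if both.empty:
        warnings.warn("no lineages comparable between the two conditions")
        return float("nan")
    return float((both[condition] < both[reference]).mean())


def estimate_switch_prob_from_purity(purity: float, doublings: int) -> float:
    """Per-division (per-daughter) switch probability from lineage purity.

    A complete tree of ``d`` doublings performs ``2 * (2**d - 1)``
    independent daughter draws; a lineage stays pure with probability
    ``(1 - p) ** n_draws``, so ``p_hat = 1 - purity ** (1 / n_draws)``.
    Small-p approximation: back-switching is ignored. ``purity == 0``
    carries no information under this approximation and returns NaN.
    """
    if doublings < 1:
        raise ValueError("doublings must be >= 1")
    if not 0.0 <= purity <= 1.0:
        raise ValueError(f"purity must be in [0, 1], got {purity}")
    if purity == 0.0:
        return float("nan")
    n_draws = 2 * (2 ** int(doublings) - 1)
    return float(1.0 - purity ** (1.0 / n_draws))


def gene_memory_icc(normalized: NormalizedMatrix, table: pd.DataFrame) -> pd.Series:
    """Per-gene memory score: one-way intraclass correlation across lineages.

    For each gene, expression is decomposed into between-lineage and
    within-lineage variance (one-way random-effects ANOVA with the
    unbalanced group-size correction); the ICC is clipped to [0, 1].
    Genes with zero variance score 0. Requires >= 10 lineages with >= 2
    cells each.
    """
    t = table.dropna(subset=["lineage_id"])
    t = t[t["cell_id"].isin(normalized.cells)]
    sizes = t.groupby("lineage_id")["cell_id"].count()
    keep = sizes.index[sizes >= 2]
    if len(keep) < 10:
        raise ValueError(f"need >= 10 lineages with >= 2 cells, got {len(keep)}")
    t = t[t["lineage_id"].isin(keep)]
    cells = t["cell_id"].tolist()
    x = normalized.values[:, normalized.cell_indices(cells)]
    groups, codes = np.unique(t["lineage_id"].to_numpy(), return_inverse=True)
    k = len(groups)
    n = x.shape[1]
    n_i = np.bincount(codes, minlength=k).astype(float)

    # per-gene group sums -> means
    gsum = np.zeros((x.shape[0], k))
    np.add.at(gsum.T, codes, x.T)
    gmean = gsum / n_i
    grand = x.mean(axis=1, keepdims=True)

    ssb = ((gmean - grand) ** 2 * n_i).sum(axis=1)
    ssw = ((x - gmean[:, codes]) ** 2).sum(axis=1)
    msb = ssb / (k - 1)
    msw = ssw / (n - k)
    n0 = (n - (n_i ** 2).sum() / n) / (k - 1)

    with np.errstate(divide="ignore", invalid="ignore"):
        icc = (msb - msw) / (msb + (n0 - 1) * msw)
    total_var = x.var(axis=1)
    icc = np.where(total_var < 1e-300, 0.0, icc)
    icc = np.clip(np.nan_to_num(icc, nan=0.0), 0.0, 1.0)
    return pd.Series(icc, index=list(normalized.genes), name="memory_icc")
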