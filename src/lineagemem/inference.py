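"""Simulation-based (ABC-style) grid inference for the two-state model.

Lineage data are compressed into a fixed :class:`SummaryStats` vector
(population primed fraction, the four lineage memory category fractions,
lineage-size quartiles per founder state, and a 10-bin histogram of
per-lineage primed fractions). Fitting simulates the experimental design
at every point of a (log-spaced) parameter grid, averages the simulated
summary vectors, and minimises a standardized Euclidean distance to the
observed vector. The set of grid points within the best 1% is reported as
a crude uncertainty region -- deliberately not a posterior.

Scenario selection asks which single-parameter change best explains a
treatment effect: each named scenario frees exactly one parameter, is
fitted on its own 1-D grid against the treated summary, and scenarios are
ranked by best-fit distance (ties broken toward the null modification).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _gillespie
from .twostate import TwoStateParams, _capacity, _run_phase

_MAX_SEED = 2**31 - 1

CATEGORY_ORDER = ("PURE_S", "PURE_P", "S_TO_P", "P_TO_S")

_N_HIST_BINS = 10


@dataclass
class SummaryStats:
    """The statistic vector compared between observed and simulated data.

    ``matched`` is empty for single-plate summaries; paired split-plate
    designs append matched-lineage components (see
    :func:`matched_components`), which carry the information that
    separates state switching from selective death.
    """

    percent_primed: float
    category_fractions: np.ndarray  # over CATEGORY_ORDER, sums to 1
    size_quantiles_s: np.ndarray  # (q25, q50, q75) of S-founder lineage sizes
    size_quantiles_p: np.ndarray
    primed_fraction_hist: np.ndarray  # 10 bins over per-lineage primed fractions
    matched: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def vector(self) -> np.ndarray:
        return np.concatenate(
            [
                [self.percent_primed],
                self.category_fractions,
                self.size_quantiles_s,
                self.size_quantiles_p,
                self.primed_fraction_hist,
                self.matched,
            ]
        )

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "SummaryStats":
        v = np.asarray(v, float)
        return cls(float(v[0]), v[1:5], v[5:8], v[8:11], v[11:21], v[21:])


def stats_from_arrays(
    states: np.ndarray,
    lineage_codes: np.ndarray,
    founder_states: np.ndarray,
    min_cells: int = 1,
) -> SummaryStats:
    """Summary statistics from raw simulator arrays (fast path).

    ``states`` is 0/1 per cell, ``lineage_codes`` integer lineage per cell,
    ``founder_states`` 0/1 per lineage. Lineages smaller than ``min_cells``
    are excluded from lineage statistics; all cells count toward the
    population primed fraction.
    """
    n_lin = founder_states.size
    states = np.asarray(states)
    pp = float(states.mean()) if states.size else 0.0
    tot = np.bincount(lineage_codes, minlength=n_lin)
    prim = np.bincount(lineage_codes, weights=states.astype(float), minlength=n_lin)
    keep = tot >= max(min_cells, 1)
    tot_k = tot[keep].astype(float)
    prim_k = prim[keep]
    founder_p = founder_states[keep] == 1

    pure = np.where(founder_p, prim_k == tot_k, prim_k == 0)
    n_kept = tot_k.size
    cats = np.zeros(4)
    if n_kept:
        cats[0] = float((pure & ~founder_p).sum())  # PURE_S
        cats[1] = float((pure & founder_p).sum())  # PURE_P
        cats[2] = float((~pure & ~founder_p).sum())  # S_TO_P
        cats[3] = float((~pure & founder_p).sum())  # P_TO_S
        cats /= n_kept

    def _quart(sizes):
        if sizes.size == 0:
            return np.zeros(3)
        return np.quantile(sizes, [0.25, 0.5, 0.75])

    q_s = _quart(tot_k[~founder_p])
    q_p = _quart(tot_k[founder_p])
    if n_kept:
        frac = prim_k / tot_k
        hist, _ = np.histogram(frac, bins=_N_HIST_BINS, range=(0.0, 1.0))
        hist = hist / n_kept
    else:
        hist = np.zeros(_N_HIST_BINS)
    return SummaryStats(pp, cats, q_s, q_p, hist)


def summary_stats(table: pd.DataFrame, classes: pd.DataFrame) -> SummaryStats:
    """Summary statistics from a cell table and its lineage classification.

    Cells with NA lineage count toward the primed fraction but are excluded
    from lineage statistics (which come from ``classes``).
    """
    pp = float((table["state"] == "P").mean()) if len(table) else 0.0
    n = len(classes)
    cats = np.zeros(4)
    if n:
        vc = classes["category"].value_counts()
        for i, cat in enumerate(CATEGORY_ORDER):
            cats[i] = vc.get(cat, 0) / n

    def _quart(sizes):
        if len(sizes) == 0:
            return np.zeros(3)
        return np.quantile(np.asarray(sizes, float), [0.25, 0.5, 0.75])

    q_s = _quart(classes.loc[classes["founder_state"] == "S", "size"])
    q_p = _quart(classes.loc[classes["founder_state"] == "P", "size"])
    if n:
        hist, _ = np.histogram(classes["primed_fraction"], bins=_N_HIST_BINS, range=(0, 1))
        hist = hist / n
    else:
        hist = np.zeros(_N_HIST_BINS)
    return SummaryStats(pp, cats, q_s, q_p, hist)


@dataclass
class InferenceDesign:
    """Simulation design used inside the fit loop.

    With ``treatment_days == 0`` the whole run (``doublings`` susceptible
    doublings from the stated founders) uses the candidate parameters --
    the expansion-phase fit. With ``treatment_days > 0`` the expansion
    runs under ``base_params`` and only the treatment phase uses the
    candidate parameters -- the split-plate treatment fit. ``paired``
    additionally simulates an untreated sister plate (same founders,
    ``base_params``) and appends matched-lineage components to the
    summary vector: lineages shared across plates act as copies of the
    same founder cell under the two conditions.
    """

    founders_s: int
    founders_p: int
    doublings: float
    treatment_days: float = 0.0
    base_params: TwoStateParams | None = None
    paired: bool = False

    def __post_init__(self) -> None:
        if self.founders_s + self.founders_p < 1:
            raise ValueError("need at least one founder")
        if self.treatment_days > 0 and self.base_params is None:
            raise ValueError("treatment-phase design needs base_params for the expansion")
        if self.paired and self.treatment_days <= 0:
            raise ValueError("paired designs need a treatment phase")


def matched_components(
    tot_u: np.ndarray,
    prim_u: np.ndarray,
    tot_t: np.ndarray,
    prim_t: np.ndarray,
) -> np.ndarray:
    """Matched-lineage summary components for a paired split-plate design.

    Over lineages that contained primed cells on the untreated plate:

    1. primed-mass retention -- treated-plate lineage sizes weighted by
       the lineage's untreated primed fraction, per untreated primed
       cell, normalized by the overall treated/untreated growth ratio.
       This attributes treated-plate cells to primed ancestry in
       proportion to how primed the lineage was on the sister plate:
       selective killing of primed cells pushes it below 1, whereas
       switching leaves the cells alive (as susceptible) and keeps it
       near 1;
    2. residual primed fraction -- primed cells / all cells on the
       treated plate within those lineages;
    3. fraction reduced -- the fraction of those lineages whose
       per-lineage primed fraction is strictly lower treated than
       untreated;
    4. high-primed growth -- log relative growth of lineages that were
       mostly (>= 50%) primed untreated. Faster P -> S switching
       *accelerates* these lineages (ex-primed cells divide at the
       susceptible rate) while primed killing shrinks them, so the two
       mechanisms move this component in opposite directions.
    """
    grow = tot_t.sum() / max(tot_u.sum(), 1)
    had_primed = prim_u > 0
    if not had_primed.any() or grow == 0:
        return np.zeros(4)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_all = np.where(tot_u > 0, prim_u / np.maximum(tot_u, 1), 0.0)
    retention = (tot_t * f_all).sum() / max(prim_u.sum(), 1) / grow
    t_tot = tot_t[had_primed].sum()
    residual = prim_t[had_primed].sum() / max(t_tot, 1)
    both = had_primed & (tot_t > 0)
    if both.any():
        f_u = prim_u[both] / tot_u[both]
        f_t = prim_t[both] / tot_t[both]
        reduced = float((f_t < f_u).mean())
    else:
        reduced = 0.0
    hi = f_all >= 0.5
    if hi.any() and tot_u[hi].sum() > 0:
        ratio = tot_t[hi].sum() / tot_u[hi].sum() / grow
        hi_growth = math.log(max(ratio, 1e-3))
    else:
        hi_growth = 0.0
    return np.array([retention, residual, reduced, hi_growth])


def simulate_design_stats(
    params: TwoStateParams,
    design: InferenceDesign,
    seed: int,
    min_cells: int = 1,
) -> SummaryStats | None:
    """One simulation of the design -> summary stats (None if extinct)."""
    n0 = design.founders_s + design.founders_p
    f_states = np.concatenate(
        [np.zeros(design.founders_s, np.uint8), np.ones(design.founders_p, np.uint8)]
    )
    f_lineages = np.arange(n0, dtype=np.int64)
    rng = np.random.default_rng(seed)

    phase1 = design.base_params if design.treatment_days > 0 else params
    t1 = design.doublings * math.log(2.0) / (phase1.r_s - phase1.d_s)
    total_t = t1 + design.treatment_days
    cap = _capacity(n0, phase1, total_t) + 1024
    states = np.zeros(cap, np.uint8)
    lineages = np.zeros(cap, np.int64)
    birth = np.zeros(cap, np.float64)
    states[:n0] = f_states
    lineages[:n0] = f_lineages
    st, li, bt, n, t, ev, status = _run_phase(
        states, lineages, birth, n0, 0.0, t1, phase1, int(rng.integers(_MAX_SEED)), n0
    )
    if status == _gillespie.STATUS_EXTINCT or n == 0:
        return None
    if design.treatment_days == 0:
        return stats_from_arrays(st[:n], li[:n], f_states, min_cells=min_cells)

    def _plate(sel_states, sel_lineages, plate_params):
        k = sel_states.size
        st2 = np.zeros(cap, np.uint8)
        li2 = np.zeros(cap, np.int64)
        bt2 = np.zeros(cap, np.float64)
        st2[:k] = sel_states
        li2[:k] = sel_lineages
        return _run_phase(
            st2, li2, bt2, k, 0.0, design.treatment_days, plate_params,
            int(rng.integers(_MAX_SEED)), n0,
        )

    if not design.paired:
        st, li, bt, n, t, ev, status = _plate(st[:n], li[:n], params)
        if status == _gillespie.STATUS_EXTINCT or n == 0:
            return None
        return stats_from_arrays(st[:n], li[:n], f_states, min_cells=min_cells)

    # paired: split expanded cells into an untreated and a treated plate
    to_treated = rng.random(n) < 0.5
    stu, liu, btu, nu, tu, evu, su = _plate(st[:n][~to_treated], li[:n][~to_treated], phase1)
    stt, lit, btt, nt_, tt, evt, st_ = _plate(st[:n][to_treated], li[:n][to_treated], params)
    if nt_ == 0 or nu == 0:
        return None
    stats = stats_from_arrays(stt[:nt_], lit[:nt_], f_states, min_cells=min_cells)
    tot_u = np.bincount(liu[:nu], minlength=n0)
    prim_u = np.bincount(liu[:nu], weights=stu[:nu].astype(float), minlength=n0)
    tot_t = np.bincount(lit[:nt_], minlength=n0)
    prim_t = np.bincount(lit[:nt_], weights=stt[:nt_].astype(float), minlength=n0)
    stats.matched = matched_components(tot_u, prim_u, tot_t, prim_t)
    return stats


@dataclass
class InferenceResult:
    best_params: TwoStateParams
    best_values: dict  # free parameter name -> fitted value
    best_distance: float
    grid: pd.DataFrame  # one row per grid point: free params + distance
    accepted: pd.DataFrame  # points within the tolerance (best accept_frac)
    n_simulations: int
    seed: int
    scale: np.ndarray = field(repr=False, default=None)

    def estimate(self, name: str) -> float:
        """Point estimate for a fitted parameter: the accepted-set mean.

        Geometric mean over the tolerance-accepted grid points (arithmetic
        when values can be zero), the usual ABC posterior-mean estimator;
        smoother than the raw argmin on a coarse grid.
        """
        vals = self.accepted[name].to_numpy(dtype=float)
        if (vals > 0).all():
            return float(np.exp(np.mean(np.log(vals))))
        return float(vals.mean())


def _grid_axis(spec, grid_size: int) -> np.ndarray:
    if isinstance(spec, tuple) and len(spec) == 2:
        lo, hi = spec
        if lo <= 0 or hi <= 0:
            raise ValueError("grid ranges must be positive (log-spaced)")
        return np.geomspace(lo, hi, grid_size)
    return np.asarray(spec, dtype=float)


def _observed_vector(observed):
    """Mean vector (and spread when enough replicates are given).

    Spread estimated from fewer than 5 replicates is too unstable to
    standardize with; in that case the caller falls back to
    simulation-estimated spread.
    """
    if isinstance(observed, SummaryStats):
        return observed.vector(), None
    vecs = np.array([o.vector() for o in observed])
    if vecs.shape[0] < 5:
        return vecs.mean(axis=0), None
    return vecs.mean(axis=0), vecs.std(axis=0, ddof=1)


def fit_grid(
    observed,
    free_params: Mapping,
    fixed: TwoStateParams,
    design: InferenceDesign,
    grid_size: int = 20,
    sims_per_point: int = 10,
    seed: int = 0,
    accept_frac: float = 0.01,
    scale: np.ndarray | None = None,
    min_cells: int = 1,
) -> InferenceResult:
    """ABC-style grid fit of the two-state model to observed summary stats.

    ``free_params`` maps parameter names to either a ``(lo, hi)`` range
    (log-spaced with ``grid_size`` points) or an explicit value array. At
    every grid point ``sims_per_point`` replicate simulations of
    ``design`` are run and their summary vectors averaged; the distance is
    Euclidean after per-component standardization. The standardization
    spread comes from observed replicates when several are given;
    otherwise it is estimated once from replicate simulations at the
    geometric midpoint of the grid. Components with zero spread are
    standardized by 1. Grid points where every simulation goes extinct
    get infinite distance.
    """
    obs_vec, obs_spread = _observed_vector(observed)
    axes = {name: _grid_axis(spec, grid_size) for name, spec in free_params.items()}
    names = list(axes)
    mesh = np.meshgrid(*[axes[n] for n in names], indexing="ij")
    points = np.stack([m.ravel() for m in mesh], axis=1)

    rng = np.random.default_rng(seed)
    n_sims = 0

    if scale is None:
        if obs_spread is not None:
            scale = obs_spread
        else:
            mid = {
                n: float(np.exp(np.mean(np.log(axes[n]))))
                if (axes[n] > 0).all()
                else float(np.mean(axes[n]))
                for n in names
            }
            mid_params = replace(fixed, **mid)
            reps = []
            for _ in range(max(sims_per_point, 10)):
                s = simulate_design_stats(
                    mid_params, design, int(rng.integers(_MAX_SEED)), min_cells
                )
                n_sims += 1
                if s is not None:
                    reps.append(s.vector())
            if len(reps) < 2:
                raise ValueError("could not estimate standardization spread (extinctions)")
            scale = np.array(reps).std(axis=0, ddof=1)
    scale = np.where(np.asarray(scale, float) <= 0, 1.0, scale)

    distances = np.empty(points.shape[0])
    n_extinct_points = 0
    for i, row in enumerate(points):
        params_i = replace(fixed, **dict(zip(names, row)))
        vecs = []
        for _ in range(sims_per_point):
            s = simulate_design_stats(params_i, design, int(rng.integers(_MAX_SEED)), min_cells)
            n_sims += 1
            if s is not None:
                vecs.append(s.vector())
        if not vecs:
            distances[i] = np.inf
            n_extinct_points += 1
            continue
        mean_vec = np.mean(vecs, axis=0)
        distances[i] = float(np.linalg.norm((mean_vec - obs_vec) / scale))
    if n_extinct_points:
        warnings.warn(f"{n_extinct_points} grid points were fully extinct (distance inf)")

    grid_df = pd.DataFrame(points, columns=names)
    grid_df["distance"] = distances
    best_i = int(np.argmin(distances))
    best_values = dict(zip(names, points[best_i]))
    n_accept = max(1, math.ceil(accept_frac * len(grid_df)))
    accepted = grid_df.nsmallest(n_accept, "distance")
    return InferenceResult(
        best_params=replace(fixed, **best_values),
        best_values=best_values,
        best_distance=float(distances[best_i]),
        grid=grid_df,
        accepted=accepted,
        n_simulations=n_sims,
        seed=int(seed),
        scale=scale,
    )


@dataclass
class ScenarioFit:
    name: str
    param: str
    fitted_value: float
    null_value: float
    distance: float
    result: InferenceResult


def scenario_selection(
    untreated: SummaryStats,
    treated: SummaryStats,
    scenarios: Mapping,
    base: TwoStateParams,
    design: InferenceDesign,
    seed: int = 0,
    grid_size: int = 12,
    sims_per_point: int = 5,
) -> list:
    """Rank single-parameter explanations of a treatment effect.

    ``scenarios`` maps a scenario name to ``(param_name, grid)`` where the
    grid is a value array or a ``(lo, hi)`` log range that should include
    the null (untreated) value. Each scenario fits only its parameter
    against the treated summary via :func:`fit_grid`; scenarios are
    returned sorted by best distance, with exact ties broken toward the
    scenario whose best fit deviates least from the null.
    """
    if len(scenarios) < 2:
        raise ValueError("need at least 2 scenarios to compare")
    rng = np.random.default_rng(seed)
    # one shared standardization so scenario distances are comparable
    scale = None
    fits = []
    for name, (param, grid) in scenarios.items():
        res = fit_grid(
            treated,
            {param: grid},
            base,
            design,
            grid_size=grid_size,
            sims_per_point=sims_per_point,
            seed=int(rng.integers(_MAX_SEED)),
            scale=scale,
        )
        if scale is None:
            scale = res.scale
        null = float(getattr(base, param))
        fits.append(
            ScenarioFit(
                name=name,
                param=param,
                fitted_value=float(res.best_values[param]),
                null_value=null,
                distance=res.best_distance,
                result=res,
            )
        )

    def _null_dev(f: ScenarioFit) -> float:
        if f.null_value > 0 and f.fitted_value > 0:
            return abs(math.log(f.fitted_value / f.null_value))
        return abs(f.fitted_value - f.null_value)

    fits.sort(key=lambda f: (f.distance, _null_dev(f)))
    return fits


def scenario_study(
    base: TwoStateParams,
    design: InferenceDesign,
    direction: str,
    n_replicates: int,
    effect: float = 10.0,
    seed: int = 0,
    grid_size: int = 10,
    sims_per_point: int = 8,
    n_observed_replicates: int = 2,
) -> pd.DataFrame:
    """Repeated synthetic scenario-selection experiments.

    For each replicate, treated data are simulated under the generating
    scenario (``direction`` "induction": S->P switching increased
    ``effect``-fold, the TGFB1-like perturbation; "depletion": P->S
    switching increased ``effect``-fold, the PI3K-inhibitor-like
    perturbation), averaging ``n_observed_replicates`` parallel observed
    experiments, and :func:`scenario_selection` is asked to recover it.
    Returns one row per replicate with the winning scenario and whether
    it matches the generator.
    """
    if direction == "induction":
        truth = replace(base, p_on=min(base.p_on * effect, 1.0))
        builder, expected = induction_scenarios, "kon_increase"
    elif direction == "depletion":
        truth = replace(base, p_off=min(base.p_off * effect, 1.0))
        builder, expected = depletion_scenarios, "koff_increase"
    else:
        raise ValueError("direction must be 'induction' or 'depletion'")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        observed = [
            simulate_design_stats(truth, design, int(rng.integers(_MAX_SEED)))
            for _ in range(n_observed_replicates)
        ]
        observed = [o for o in observed if o is not None]
        untreated = simulate_design_stats(base, design, int(rng.integers(_MAX_SEED)))
        fits = scenario_selection(
            untreated,
            observed if len(observed) > 1 else observed[0],
            builder(base, grid_size=grid_size),
            base,
            design,
            seed=int(rng.integers(_MAX_SEED)),
            grid_size=grid_size,
            sims_per_point=sims_per_point,
        )
        rows.append(
            {
                "replicate": rep,
                "direction": direction,
                "winner": fits[0].name,
                "expected": expected,
                "correct": fits[0].name == expected,
                "best_distance": fits[0].distance,
            }
        )
    return pd.DataFrame(rows)


def induction_scenarios(
    base: TwoStateParams, max_mult: float = 30.0, grid_size: int = 12
) -> dict:
    """Canonical single-parameter explanations for a primed-fraction increase.

    A rise in the primed share of the population can come from faster
    S->P switching, faster primed proliferation, or selective killing of
    susceptible cells. Grids start at the null value.
    """
    return {
        "kon_increase": ("p_on", np.geomspace(base.p_on, min(base.p_on * max_mult, 0.5), grid_size)),
        "primed_growth_increase": ("r_p", np.geomspace(base.r_p, base.r_s * 2.0, grid_size)),
        "susceptible_death_increase": ("d_s", np.linspace(0.0, base.r_s * 0.9, grid_size)),
    }


def depletion_scenarios(
    base: TwoStateParams, max_mult: float = 30.0, grid_size: int = 12
) -> dict:
    """Canonical single-parameter explanations for a primed-fraction decrease."""
    return {
        "koff_increase": ("p_off", np.geomspace(base.p_off, min(base.p_off * max_mult, 1.0), grid_size)),
        "susceptible_growth_increase": ("r_s", np.geomspace(base.r_s, base.r_s * 4.0, grid_size)),
        "primed_death_increase": ("d_p", np.linspace(0.0, base.r_p * 3.0, grid_size)),
    }
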