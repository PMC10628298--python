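"""Stochastic two-state branching model of phenotype switching.

The model follows a population of cells that are either drug-susceptible
(S) or primed for drug resistance (P). Each state has its own division and
death rate; switching happens at division, where each daughter
independently adopts the other state with a small probability. Because
rates in this field are quoted in divisions ("one switch every N cell
divisions"), the conversion convention used everywhere in this package is

    one switching event per N divisions  <=>  per-daughter probability 1/(2N)

(each division gives two daughters a chance to switch). The primed state
is rare and slow-dividing; it is maintained at steady state by a fast
P -> S rate balanced against a slow S -> P rate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from . import _gillespie
from .containers import make_cell_table

_MAX_SEED = 2**31 - 1


@dataclass(frozen=True)
class TwoStateParams:
    """Rates and switching probabilities of the two-state model.

    ``r_s`` / ``r_p``: division rates (per day) of susceptible and primed
    cells; ``d_s`` / ``d_p``: death rates (per day); ``p_on`` / ``p_off``:
    per-daughter switch probabilities at division (S->P and P->S);
    ``gamma``: lineage-coupling coefficient (0 disables it) making
    susceptible cells in partially primed lineages switch more easily;
    ``switching``: "division" (default) or "continuous" (switching as a
    separate exponential event at the flux-equivalent rates
    ``k_on = 2 p_on r_s``, ``k_off = 2 p_off r_p``).
    """

    r_s: float
    r_p: float
    p_on: float
    p_off: float
    d_s: float = 0.0
    d_p: float = 0.0
    gamma: float = 0.0
    switching: str = "division"

    def __post_init__(self) -> None:
        if self.r_s <= 0:
            raise ValueError("r_s must be > 0")
        for name in ("r_p", "d_s", "d_p"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("p_on", "p_off"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.switching not in ("division", "continuous"):
            raise ValueError("switching must be 'division' or 'continuous'")

    @property
    def divisions_per_on_event(self) -> float:
        """Expected susceptible divisions per S->P event (1 / (2 p_on))."""
        return math.inf if self.p_on == 0 else 1.0 / (2.0 * self.p_on)

    @property
    def divisions_per_off_event(self) -> float:
        return math.inf if self.p_off == 0 else 1.0 / (2.0 * self.p_off)

    @classmethod
    def from_divisions(cls, divisions_per_on: float, divisions_per_off: float, **kw):
        """Build params from divisions-per-event (the field's usual units)."""
        return cls(p_on=1.0 / (2.0 * divisions_per_on), p_off=1.0 / (2.0 * divisions_per_off), **kw)


#: Default drug-naive melanoma-like parameters: ~3.5-day susceptible
#: doubling time, primed cells dividing at about half that rate, one S->P
#: event per ~177 divisions and one P->S event per ~6.3 divisions.
DEFAULT_PARAMS = TwoStateParams(r_s=0.2, r_p=0.1, p_on=1.0 / 354.0, p_off=1.0 / 12.6)


@dataclass
class SimulatedPopulation:
    """Simulator output: per-cell state/lineage plus event bookkeeping."""

    states: np.ndarray  # uint8, 0 = S, 1 = P
    lineages: np.ndarray  # int32 founder index per cell
    birth_times: np.ndarray
    founder_states: np.ndarray  # uint8 per lineage (founder index)
    events: dict
    params: TwoStateParams
    seed: int
    t_final: float
    extinct: bool = False

    @property
    def size(self) -> int:
        return int(self.states.size)

    @property
    def primed_fraction(self) -> float:
        return float(self.states.mean()) if self.size else float("nan")

    @property
    def n_lineages(self) -> int:
        return int(self.founder_states.size)

    def to_table(self, sample_id: str = "sim") -> pd.DataFrame:
        """Cell table with string ids (``cell_id``, ``lineage_id`` etc.)."""
        state = np.where(self.states == 1, "P", "S")
        return make_cell_table(
            cell_id=[f"{sample_id}_c{i:06d}" for i in range(self.size)],
            sample_id=[sample_id] * self.size,
            lineage_id=[f"L{int(l):05d}" for l in self.lineages],
            state=state,
        )

    def founder_state_map(self) -> dict:
        return {
            f"L{i:05d}": ("P" if s == 1 else "S")
            for i, s in enumerate(self.founder_states)
        }

    def lineage_compositions(self) -> pd.DataFrame:
        tot = np.bincount(self.lineages, minlength=self.n_lineages)
        prim = np.bincount(
            self.lineages, weights=self.states.astype(float), minlength=self.n_lineages
        ).astype(int)
        return pd.DataFrame(
            {
                "lineage_id": [f"L{i:05d}" for i in range(self.n_lineages)],
                "founder_state": np.where(self.founder_states == 1, "P", "S"),
                "size": tot,
                "n_primed": prim,
            }
        )


_EVENT_NAMES = ("divisions_s", "divisions_p", "deaths_s", "deaths_p", "switches_on", "switches_off")


def _founder_arrays(founders) -> tuple:
    """Initial (states, lineages) from a composition mapping or explicit arrays."""
    if isinstance(founders, Mapping):
        n_s = int(founders.get("S", 0))
        n_p = int(founders.get("P", 0))
        if n_s + n_p < 1:
            raise ValueError("need at least one founder")
        states = np.concatenate([np.zeros(n_s, np.uint8), np.ones(n_p, np.uint8)])
        lineages = np.arange(n_s + n_p, dtype=np.int64)
        return states, lineages
    states, lineages = founders
    states = np.asarray(states, np.uint8)
    lineages = np.asarray(lineages, np.int64)
    if states.size < 1:
        raise ValueError("need at least one founder")
    return states, lineages


def _stop_duration(stop, params: TwoStateParams) -> float:
    """Resolve a stop rule into a simulation duration (days).

    ``{"duration": t}`` runs for ``t`` days; ``{"doublings": d}`` runs for
    the time the susceptible state needs for ``d`` doublings,
    ``d * ln 2 / (r_s - d_s)``.
    """
    if isinstance(stop, (int, float)):
        return float(stop)
    if "duration" in stop:
        return float(stop["duration"])
    if "doublings" in stop:
        net = params.r_s - params.d_s
        if net <= 0:
            raise ValueError("doublings stop rule needs positive net susceptible growth")
        return float(stop["doublings"]) * math.log(2.0) / net
    raise ValueError("stop must specify 'duration' or 'doublings'")


def _run_phase(states, lineages, birth_times, n0, t0, t_end, params, seed, n_lineages):
    """Run the kernel with automatic capacity growth; returns trimmed arrays."""
    cap = states.shape[0]
    div = params.switching == "division"
    k_on = 2.0 * params.p_on * params.r_s
    k_off = 2.0 * params.p_off * params.r_p
    while True:
        st = states.copy()
        li = lineages.copy()
        bt = birth_times.copy()
        lin_tot = np.bincount(li[:n0], minlength=n_lineages).astype(np.int64)
        lin_p = np.bincount(
            li[:n0], weights=st[:n0].astype(np.float64), minlength=n_lineages
        ).astype(np.int64)
        events = np.zeros(6, np.int64)
        n, t, status = _gillespie.run_kernel(
            st, li, bt, lin_tot, lin_p, events,
            n0, t0, t_end,
            params.r_s, params.r_p, params.d_s, params.d_p,
            params.p_on, params.p_off, params.gamma,
            div, k_on, k_off, int(seed),
        )
        if status != _gillespie.STATUS_OVERFLOW:
            return st, li, bt, n, t, events, status
        cap = 2 * cap + 1024
        grown = np.zeros(cap, np.uint8), np.zeros(cap, np.int64), np.zeros(cap, np.float64)
        grown[0][: states.shape[0]] = states
        grown[1][: states.shape[0]] = lineages
        grown[2][: states.shape[0]] = birth_times
        states, lineages, birth_times = grown


def _capacity(n0: int, params: TwoStateParams, duration: float) -> int:
    growth = max(params.r_s - params.d_s, params.r_p - params.d_p, 0.0)
    return int(n0 * math.exp(growth * duration) * 4) + 1024


def simulate_population(
    params: TwoStateParams,
    founders,
    stop,
    seed: int = 0,
) -> SimulatedPopulation:
    """Exact event-driven simulation of the two-state model.

    ``founders`` is a composition mapping like ``{"S": 1000, "P": 20}``
    (each founder starting its own lineage) or a ``(states, lineages)``
    array pair. ``stop`` is ``{"duration": days}`` or ``{"doublings": d}``.
    Deterministic given ``seed``. If the population dies out before the
    stop time the result carries ``extinct=True``.
    """
    f_states, f_lineages = _founder_arrays(founders)
    n0 = f_states.size
    n_lineages = int(f_lineages.max()) + 1
    founder_states = np.zeros(n_lineages, np.uint8)
    founder_states[f_lineages] = f_states
    duration = _stop_duration(stop, params)
    cap = _capacity(n0, params, duration)
    states = np.zeros(cap, np.uint8)
    lineages = np.zeros(cap, np.int64)
    birth_times = np.zeros(cap, np.float64)
    states[:n0] = f_states
    lineages[:n0] = f_lineages
    st, li, bt, n, t, events, status = _run_phase(
        states, lineages, birth_times, n0, 0.0, duration, params, seed % _MAX_SEED, n_lineages
    )
    return SimulatedPopulation(
        states=st[:n].copy(),
        lineages=li[:n].copy(),
        birth_times=bt[:n].copy(),
        founder_states=founder_states,
        events=dict(zip(_EVENT_NAMES, events.tolist())),
        params=params,
        seed=int(seed),
        t_final=float(t),
        extinct=status == _gillespie.STATUS_EXTINCT,
    )


def steady_state_fraction(params: TwoStateParams) -> float:
    """Deterministic-limit primed fraction.

    In the deterministic (large-population) limit the model reduces to a
    two-type linear ODE with per-time switching fluxes ``2 p_on r_s S``
    and ``2 p_off r_p P`` (per-daughter-pair convention). The primed
    fraction ``f = P / (S + P)`` obeys a Riccati equation whose stable
    fixed point in [0, 1] is returned (the unique attracting root of the
    quadratic). Parameter pathologies with no such root raise.
    """
    a = params.r_p * (1.0 - 2.0 * params.p_off) - params.d_p
    b = 2.0 * params.p_on * params.r_s
    c = params.r_s * (1.0 - 2.0 * params.p_on) - params.d_s
    e = 2.0 * params.p_off * params.r_p
    # f' = A f^2 + B f + C
    A = (c + b) - (a + e)
    B = a - 2.0 * b - c
    C = b

    def deriv(f):
        return 2.0 * A * f + B

    eps = 1e-12
    if abs(A) < 1e-300:
        if abs(B) < 1e-300:
            if abs(C) < 1e-300:
                return 0.0
            raise ValueError("no steady-state primed fraction in [0, 1]")
        root = -C / B
        if -eps <= root <= 1 + eps and B < 0:
            return float(min(max(root, 0.0), 1.0))
        raise ValueError("no stable steady-state primed fraction in [0, 1]")
    disc = B * B - 4.0 * A * C
    if disc < 0:
        raise ValueError("no real steady-state primed fraction")
    roots = [(-B - math.sqrt(disc)) / (2 * A), (-B + math.sqrt(disc)) / (2 * A)]
    stable = [
        r for r in roots if -1e-9 <= r <= 1 + 1e-9 and deriv(r) <= 1e-12
    ]
    if not stable:
        raise ValueError("no stable steady-state primed fraction in [0, 1]")
    return float(min(max(stable[0], 0.0), 1.0))


def sample_cells(
    pop: SimulatedPopulation,
    n: int,
    detection: float = 1.0,
    seed: int = 0,
    sample_id: str = "sim",
) -> pd.DataFrame:
    """Capture model: uniform subsample, lineage masked at 1 - detection.

    Returns a cell table; undetected lineages are NA.
    """
    if n > pop.size:
        raise ValueError(f"cannot sample {n} cells from population of {pop.size}")
    if not 0.0 <= detection <= 1.0:
        raise ValueError("detection must be in [0, 1]")
    rng = np.random.default_rng(seed)
    idx = rng.choice(pop.size, size=n, replace=False)
    detected = rng.random(n) < detection
    lineage = np.array([f"L{int(l):05d}" for l in pop.lineages[idx]], dtype=object)
    lineage[~detected] = None
    return make_cell_table(
        cell_id=[f"{sample_id}_c{i:06d}" for i in range(n)],
        sample_id=[sample_id] * n,
        lineage_id=lineage,
        state=np.where(pop.states[idx] == 1, "P", "S"),
    )


@dataclass
class ExperimentDesign:
    """Expansion / split / treatment experimental layout.

    Founders are expanded for ``expansion_doublings`` (susceptible
    doublings) under the base parameters, multinomially split across the
    named plates, and each plate then runs for ``treatment_days`` under
    the base parameters overridden per plate. ``capture`` cells per plate
    are sampled at the endpoint (all cells if None) and each captured
    cell's lineage is observed with probability ``barcode_detection_rate``
    (default 0.60, the typical fraction of profiled cells whose barcode is
    recovered).
    """

    founders: Mapping
    expansion_doublings: float
    plates: Mapping[str, Mapping] = field(default_factory=lambda: {"untreated": {}})
    treatment_days: float = 5.0
    capture: int | None = None
    barcode_detection_rate: float = 0.60

    def __post_init__(self) -> None:
        if len(self.plates) < 1:
            raise ValueError("need at least one plate")
        if not 0.0 <= self.barcode_detection_rate <= 1.0:
            raise ValueError("barcode_detection_rate must be in [0, 1]")


@dataclass
class ExperimentResult:
    tables: dict  # condition -> captured cell table (lineage NA where undetected)
    truth: dict  # condition -> SimulatedPopulation at endpoint
    founder_states: dict  # lineage id -> "S"/"P"
    design: ExperimentDesign
    params: TwoStateParams
    seed: int


def simulate_experiment(
    design: ExperimentDesign,
    base_params: TwoStateParams,
    seed: int = 0,
) -> ExperimentResult:
    """Simulate an expand/split/treat design with ground truth retained."""
    rng = np.random.default_rng(seed)

    def _seed() -> int:
        return int(rng.integers(_MAX_SEED))

    expanded = simulate_population(
        base_params, design.founders, {"doublings": design.expansion_doublings}, seed=_seed()
    )
    plate_names = list(design.plates)
    plate_of = rng.integers(len(plate_names), size=expanded.size)
    tables = {}
    truth = {}
    for pi, cond in enumerate(plate_names):
        params_c = replace(base_params, **dict(design.plates[cond]))
        sel = plate_of == pi
        n0 = int(sel.sum())
        if n0 == 0:
            warnings.warn(f"plate {cond!r} received no cells at the split")
            continue
        duration = design.treatment_days
        cap = _capacity(n0, params_c, duration)
        states = np.zeros(cap, np.uint8)
        lineages = np.zeros(cap, np.int64)
        birth = np.zeros(cap, np.float64)
        states[:n0] = expanded.states[sel]
        lineages[:n0] = expanded.lineages[sel]
        birth[:n0] = expanded.birth_times[sel]
        st, li, bt, n, t, events, status = _run_phase(
            states, lineages, birth, n0, 0.0, duration, params_c, _seed(),
            expanded.n_lineages,
        )
        pop = SimulatedPopulation(
            states=st[:n].copy(),
            lineages=li[:n].copy(),
            birth_times=bt[:n].copy(),
            founder_states=expanded.founder_states,
            events=dict(zip(_EVENT_NAMES, events.tolist())),
            params=params_c,
            seed=seed,
            t_final=float(t),
            extinct=status == _gillespie.STATUS_EXTINCT,
        )
        truth[cond] = pop
        n_cap = pop.size if design.capture is None else design.capture
        if n_cap > pop.size:
            warnings.warn(
                f"capture {n_cap} exceeds plate population {pop.size} on {cond!r}; capped"
            )
            n_cap = pop.size
        tables[cond] = sample_cells(
            pop, n_cap, detection=design.barcode_detection_rate, seed=_seed(), sample_id=cond
        )
    return ExperimentResult(
        tables=tables,
        truth=truth,
        founder_states=expanded.founder_state_map(),
        design=design,
        params=base_params,
        seed=int(seed),
    )
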