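"""Evolutionary optimization of regulatory parameters and regime phase maps.

"Mutations" perturb one evolvable regulatory parameter at a time
(multiplicatively, in log space, since the biologically permissible windows
span orders of magnitude) and are fixed iff they strictly increase the net
cost-benefit fitness of one signal cycle.  Two evolvable sets mirror the two
ways a promoter can rewire:

* ``PROMOTER_STRENGTH`` — maximal promoter strengths and activation
  thresholds (b1, b2, Km1, Km2) evolve;
* ``BINDING_AFFINITY`` — the DNA-binding on-rates (k_on1, k_on2) evolve with
  k_off fixed, so Km_i = k_off / k_on_i; promoter strengths stay fixed.

The optimum found for a given environment is classified into one of three
regulatory regimes by which promoter terms survive: control of the target
entirely by the first-signal regulator (``R1_ONLY``), entirely by its
cognate regulator (``R2_ONLY``), or by both (``ANTICIPATORY`` —
conditioning).  Sweeping the target-protein turnover rate kd2, and the
maximal benefit E_max, produces the regime phase diagrams.

Random-restart hill climbing is used (the landscape is low-dimensional and
smooth), with three deterministic archetype starts (both terms mid-window,
and each single-regulator corner), an optional warm start (used by the
sweeps to seed the full design with the best reduced design, which makes the
nested-design dominance property hold by construction), a deterministic
Nelder-Mead polish in log space, and a final exact-zero snap of the
promoter-strength terms.  An exhaustive log-grid search is provided as an
independent oracle for testing.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .errors import ConfigurationError, ContractError, IntegrationError, SearchError
from .fitness import FitnessParams, FitnessResult, evaluate_fitness
from .model import ModelParameters, SignalSchedule, default_parameters, simulate

__all__ = [
    "Regime",
    "SearchMode",
    "ParameterBounds",
    "SearchConfig",
    "Optimum",
    "RegimeMap",
    "default_bounds",
    "default_kd_grid",
    "default_emax_grid",
    "mutate_parameters",
    "hill_climb",
    "grid_search_oracle",
    "classify_regime",
    "sweep_kd",
    "sweep_emax_kd",
    "anticipatory_window_width",
    "majority_smooth",
    "band_structure",
]

K_OFF_FIXED = 1.0
ZERO_FLOOR_REL = 1e-6  # effective log-space floor for bounds whose lower edge is 0


class Regime(str, Enum):
    R1_ONLY = "R1_ONLY"
    ANTICIPATORY = "ANTICIPATORY"
    R2_ONLY = "R2_ONLY"


class SearchMode(str, Enum):
    PROMOTER_STRENGTH = "b"
    BINDING_AFFINITY = "kon"


@dataclass(frozen=True)
class ParameterBounds:
    """Named box bounds for the evolvable parameters (lower may be 0)."""

    bounds: dict

    def __post_init__(self):
        if not self.bounds:
            raise ConfigurationError("empty evolvable parameter set")
        for name, (lo, hi) in self.bounds.items():
            if lo < 0 or hi < lo:
                raise ConfigurationError(
                    f"bad bounds for {name}: ({lo}, {hi}); need 0 <= lo <= hi"
                )

    @property
    def names(self):
        return sorted(self.bounds)

    def lo(self, name):
        return self.bounds[name][0]

    def hi(self, name):
        return self.bounds[name][1]

    def floor(self, name):
        """Smallest positive value used for log-space moves."""
        lo, hi = self.bounds[name]
        return lo if lo > 0 else hi * ZERO_FLOOR_REL

    def pinned(self, name, value=0.0) -> "ParameterBounds":
        new = dict(self.bounds)
        if name not in new:
            raise ConfigurationError(f"{name} not in bounds")
        new[name] = (value, value)
        return ParameterBounds(new)


def default_bounds(mode: SearchMode = SearchMode.PROMOTER_STRENGTH) -> ParameterBounds:
    """Biologically permissible windows used throughout the sweeps.

    Zero is included in the promoter-strength windows so that "no regulation
    by R_i" is a reachable design.  All values are package defaults chosen to
    make the three regimes visible on the default environment, not measured
    constants.
    """
    if mode == SearchMode.PROMOTER_STRENGTH:
        return ParameterBounds(
            {
                "b1": (0.0, 10.0),
                "b2": (0.0, 10.0),
                "Km1": (1e-2, 1e2),
                "Km2": (1e-2, 1e2),
            }
        )
    return ParameterBounds({"k_on1": (1e-2, 1e2), "k_on2": (1e-2, 1e2)})


def default_kd_grid(n: int = 25) -> np.ndarray:
    return np.geomspace(1e-3, 10.0, n)


def default_emax_grid(n: int = 8) -> np.ndarray:
    return np.geomspace(0.5, 10.0, n)


@dataclass(frozen=True)
class SearchConfig:
    """Hill-climbing budget and mode.

    ``step`` is the standard deviation of the Gaussian log-space perturbation.
    ``fixed_b`` is the promoter strength used for both terms in
    ``BINDING_AFFINITY`` mode (where strengths do not evolve).
    """

    mode: SearchMode = SearchMode.PROMOTER_STRENGTH
    restarts: int = 3
    iterations: int = 150
    step: float = 0.4
    seed: int = 0
    polish: bool = True
    fixed_b: float = 5.0
    epsilon_rel: float = 1e-3
    n_points: int = 1001

    def __post_init__(self):
        if self.restarts < 1 or self.iterations < 1:
            raise ConfigurationError("restarts and iterations must be >= 1")
        if self.step <= 0:
            raise ConfigurationError("step scale must be positive")


@dataclass
class Optimum:
    """Best evolvable-parameter assignment found for one environment."""

    values: dict
    params: ModelParameters
    fitness: FitnessResult
    regime: Regime | None = None
    restart_index: int = -1
    n_evaluations: int = 0
    seed: int = 0


def apply_values(
    base: ModelParameters, values: dict, mode: SearchMode, fixed_b: float = 5.0
) -> ModelParameters:
    """Materialize an evolvable-parameter assignment into full model parameters."""
    if mode == SearchMode.PROMOTER_STRENGTH:
        return base.with_(**{k: values[k] for k in ("b1", "b2", "Km1", "Km2") if k in values})
    km1 = K_OFF_FIXED / values["k_on1"]
    km2 = K_OFF_FIXED / values["k_on2"]
    return base.with_(b1=fixed_b, b2=fixed_b, Km1=km1, Km2=km2)


class _Objective:
    """Net cycle fitness as a function of the evolvable values; counts evals."""

    def __init__(self, schedule, base_params, fp, cfg):
        self.schedule = schedule
        self.base = base_params
        self.fp = fp
        self.cfg = cfg
        self.n_evals = 0
        self.n_failures = 0
        self.last_error = None

    def __call__(self, values: dict) -> float:
        self.n_evals += 1
        try:
            params = apply_values(self.base, values, self.cfg.mode, self.cfg.fixed_b)
            traj = simulate(params, self.schedule, n_points=self.cfg.n_points)
            return evaluate_fitness(traj, self.fp, kd2=params.target.kd2).net
        except (IntegrationError, ValueError) as exc:  # pragma: no cover - defensive
            self.n_failures += 1
            self.last_error = exc
            return -np.inf

    def result(self, values: dict) -> FitnessResult:
        params = apply_values(self.base, values, self.cfg.mode, self.cfg.fixed_b)
        traj = simulate(params, self.schedule, n_points=self.cfg.n_points)
        return evaluate_fitness(traj, self.fp, kd2=params.target.kd2)


def _clip(value: float, lo: float, hi: float, floor: float) -> float:
    """Clip a proposed value into bounds; below the log floor snaps to lo."""
    if value > hi:
        return hi
    if value < floor:
        return lo
    return value


def mutate_parameters(
    values: dict, bounds: ParameterBounds, step: float, rng: np.random.Generator
) -> dict:
    """Perturb one randomly chosen parameter multiplicatively in log space.

    The perturbed value is clipped to its window; proposals that fall below
    the log-space floor of a window whose lower edge is 0 snap to exactly 0,
    and a parameter currently at 0 re-enters at the floor (otherwise 0 would
    be absorbing).
    """
    names = bounds.names
    if not names:
        raise ConfigurationError("empty evolvable parameter set")
    out = dict(values)
    name = names[int(rng.integers(len(names)))]
    lo, hi = bounds.bounds[name]
    if lo == hi:
        out[name] = lo
        return out
    floor = bounds.floor(name)
    current = out[name]
    base = current if current > 0 else floor
    proposal = base * float(np.exp(rng.normal(0.0, step)))
    out[name] = _clip(proposal, lo, hi, floor)
    return out


def _start_points(bounds: ParameterBounds, cfg: SearchConfig, rng, extra_starts):
    """Deterministic archetype starts + warm starts + random restarts."""
    names = bounds.names
    mid = {
        n: float(np.sqrt(bounds.floor(n) * bounds.hi(n)))
        if bounds.lo(n) < bounds.hi(n)
        else bounds.lo(n)
        for n in names
    }
    starts = [dict(mid)]
    first, second = _term_names(bounds)
    for off in (first, second):
        if off is not None:
            corner = dict(mid)
            corner[off] = bounds.lo(off)
            starts.append(corner)
    for s in extra_starts or []:
        starts.append(dict(s))
    for _ in range(cfg.restarts):
        pt = {}
        for n in names:
            lo, hi = bounds.bounds[n]
            if lo == hi:
                pt[n] = lo
            else:
                f = bounds.floor(n)
                pt[n] = float(np.exp(rng.uniform(np.log(f), np.log(hi))))
        starts.append(pt)
    return starts


def _term_names(bounds: ParameterBounds):
    """The two parameters that gate the R1- and R2-driven promoter terms."""
    names = bounds.names
    first = "b1" if "b1" in names else ("k_on1" if "k_on1" in names else None)
    second = "b2" if "b2" in names else ("k_on2" if "k_on2" in names else None)
    return first, second


def _polish(obj, values, bounds, best_f):
    """Deterministic Nelder-Mead refinement in log space; never worse."""
    free = [n for n in bounds.names if bounds.lo(n) < bounds.hi(n)]
    if not free:
        return values, best_f
    z0 = np.array(
        [np.log(max(values[n], bounds.floor(n))) for n in free]
    )

    def fun(z):
        cand = dict(values)
        for n, zi in zip(free, z):
            lo, hi = bounds.bounds[n]
            cand[n] = float(np.clip(np.exp(min(zi, 500.0)), bounds.floor(n), hi))
        return -obj(cand)

    res = minimize(
        fun,
        z0,
        method="Nelder-Mead",
        options={"maxfev": 400, "xatol": 1e-7, "fatol": 1e-12},
    )
    cand = dict(values)
    for n, zi in zip(free, res.x):
        cand[n] = float(np.clip(np.exp(min(zi, 500.0)), bounds.floor(n), bounds.hi(n)))
    f = obj(cand)
    if f > best_f:
        return cand, f
    return values, best_f


def _snap_zeros(obj, values, bounds, best_f):
    """Try pinning each promoter term to its lower edge exactly.

    A term polished down to the log floor almost always does strictly better
    at exactly 0 (same negligible production, no residual cost), and exact
    zeros make the regime classification crisp.  Ties prefer more zeros.
    """
    first, second = _term_names(bounds)
    candidates = [n for n in (first, second) if n is not None and bounds.lo(n) < bounds.hi(n)]
    best_values, best = dict(values), best_f
    for k in range(1, len(candidates) + 1):
        for combo in itertools.combinations(candidates, k):
            cand = dict(values)
            for n in combo:
                cand[n] = bounds.lo(n)
            if all(cand[n] == values[n] for n in combo):
                continue
            f = obj(cand)
            if f > best or (f == best and sum(v == 0 for v in cand.values()) > sum(v == 0 for v in best_values.values())):
                best_values, best = cand, f
    return best_values, best


def hill_climb(
    schedule: SignalSchedule,
    base_params: ModelParameters,
    bounds: ParameterBounds,
    fp: FitnessParams,
    cfg: SearchConfig,
    extra_starts=None,
) -> Optimum:
    """Seeded random-restart hill climbing over the evolvable parameters.

    A mutation is accepted iff it strictly increases net fitness.  The best
    point over all restarts is polished (Nelder-Mead in log space) and the
    promoter terms are offered an exact-zero snap.  Reruns with the same
    config are bitwise identical.
    """
    rng = np.random.default_rng(cfg.seed)
    obj = _Objective(schedule, base_params, fp, cfg)
    starts = _start_points(bounds, cfg, rng, extra_starts)

    best_values, best_f, best_idx = None, -np.inf, -1
    for idx, start in enumerate(starts):
        current = {n: _clip(start[n], *bounds.bounds[n], bounds.floor(n)) for n in bounds.names}
        f = obj(current)
        for _ in range(cfg.iterations):
            cand = mutate_parameters(current, bounds, cfg.step, rng)
            fc = obj(cand)
            if fc > f:
                current, f = cand, fc
        if f > best_f:
            best_values, best_f, best_idx = current, f, idx

    if best_values is None or not np.isfinite(best_f):
        raise SearchError(
            f"all {obj.n_evals} fitness evaluations failed "
            f"(last error: {obj.last_error})"
        )

    if cfg.polish:
        best_values, best_f = _polish(obj, best_values, bounds, best_f)
    best_values, best_f = _snap_zeros(obj, best_values, bounds, best_f)

    opt = Optimum(
        values=best_values,
        params=apply_values(base_params, best_values, cfg.mode, cfg.fixed_b),
        fitness=obj.result(best_values),
        restart_index=best_idx,
        n_evaluations=obj.n_evals,
        seed=cfg.seed,
    )
    opt.regime = classify_regime(opt, bounds, cfg.epsilon_rel)
    return opt


def grid_search_oracle(
    schedule: SignalSchedule,
    base_params: ModelParameters,
    bounds: ParameterBounds,
    fp: FitnessParams,
    points_per_axis: int,
    cfg: SearchConfig | None = None,
) -> Optimum:
    """Exhaustive log-spaced grid search; independent oracle for the climber.

    Ties break to the lexicographically smallest parameter vector (axes
    iterate in ascending order over sorted names; only strict improvements
    replace the incumbent).
    """
    if points_per_axis < 2:
        raise ContractError("points_per_axis must be >= 2")
    names = bounds.names
    if len(names) > 4:
        raise ContractError("grid oracle refuses more than 4 evolvable dimensions")
    cfg = cfg or SearchConfig()
    obj = _Objective(schedule, base_params, fp, cfg)

    axes = []
    for n in names:
        lo, hi = bounds.bounds[n]
        if lo == hi:
            axes.append(np.array([lo]))
        elif lo > 0:
            axes.append(np.geomspace(lo, hi, points_per_axis))
        else:
            axes.append(
                np.concatenate(
                    ([0.0], np.geomspace(hi * 1e-4, hi, points_per_axis - 1))
                )
            )

    best_values, best_f = None, -np.inf
    for combo in itertools.product(*axes):
        values = {n: float(v) for n, v in zip(names, combo)}
        f = obj(values)
        if f > best_f:
            best_values, best_f = values, f
    if best_values is None or not np.isfinite(best_f):
        raise SearchError("all grid evaluations failed")

    opt = Optimum(
        values=best_values,
        params=apply_values(base_params, best_values, cfg.mode, cfg.fixed_b),
        fitness=obj.result(best_values),
        n_evaluations=obj.n_evals,
        seed=cfg.seed,
    )
    opt.regime = classify_regime(opt, bounds, cfg.epsilon_rel)
    return opt


def classify_regime(
    opt: Optimum, bounds: ParameterBounds, epsilon_rel: float = 1e-3
) -> Regime:
    """Label an optimum by which promoter terms survived.

    A term counts as absent when its gating parameter is below
    ``epsilon_rel`` times its upper window edge.  If both terms are absent
    (degenerate optimum, e.g. zero benefit) the label follows the larger
    term, with a warning.
    """
    first, second = _term_names(bounds)
    if first is None or second is None:
        raise ContractError("bounds do not contain the promoter-gating parameters")
    v1, v2 = opt.values[first], opt.values[second]
    thr1 = epsilon_rel * bounds.hi(first)
    thr2 = epsilon_rel * bounds.hi(second)
    # a term whose window is collapsed at 0 is absent by construction
    off1 = v1 < thr1 or bounds.hi(first) == 0
    off2 = v2 < thr2 or bounds.hi(second) == 0
    if off1 and off2:
        warnings.warn(
            "degenerate optimum: both promoter terms below threshold",
            RuntimeWarning,
            stacklevel=2,
        )
        return Regime.R2_ONLY if v2 >= v1 else Regime.R1_ONLY
    if off2:
        return Regime.R1_ONLY
    if off1:
        return Regime.R2_ONLY
    return Regime.ANTICIPATORY


# ---------------------------------------------------------------------------
# sweeps and regime maps


@dataclass
class RegimeMap:
    """Optimal design per grid point of a (E_max ×) kd2 sweep."""

    table: pd.DataFrame
    kd_grid: np.ndarray
    emax_grid: np.ndarray | None = None
    mode: SearchMode = SearchMode.PROMOTER_STRENGTH

    def labels(self, emax: float | None = None):
        df = self.table
        if emax is not None:
            df = df[np.isclose(df["emax"], emax)]
        df = df.sort_values("kd2")
        return [Regime(r) for r in df["regime"]]

    def smoothed_labels(self, emax: float | None = None, window: int = 3):
        return majority_smooth(self.labels(emax), window)

    def window_width(self, emax: float | None = None, window: int = 3) -> float:
        return anticipatory_window_width(
            self.smoothed_labels(emax, window), self.kd_grid
        )

    def to_csv(self, path):
        self.table.to_csv(path, index=False)


def majority_smooth(labels, window: int = 3):
    """Majority vote in a centered window; the original label wins ties."""
    if window < 1 or window % 2 == 0:
        raise ContractError("smoothing window must be odd and >= 1")
    half = window // 2
    out = []
    for i in range(len(labels)):
        neigh = labels[max(0, i - half): i + half + 1]
        counts = {}
        for lab in neigh:
            counts[lab] = counts.get(lab, 0) + 1
        best = max(counts.values())
        winners = [lab for lab, c in counts.items() if c == best]
        out.append(labels[i] if labels[i] in winners else winners[0])
    return out


def band_structure(labels):
    """Collapse a label sequence into its ordered contiguous runs."""
    runs = []
    for lab in labels:
        if not runs or runs[-1] != lab:
            runs.append(lab)
    return runs


def anticipatory_window_width(labels, kd_grid) -> float:
    """log10 extent of the longest contiguous anticipatory run (0 if none).

    A run spanning cells i..j gets width log10(kd_j) − log10(kd_i) plus one
    grid spacing (half a cell on each side), so a single anticipatory cell
    has width equal to one grid spacing.
    """
    kd = np.asarray(kd_grid, dtype=float)
    if len(labels) != len(kd):
        raise ContractError("labels and kd grid lengths differ")
    log_kd = np.log10(kd)
    spacing = float(np.mean(np.diff(log_kd))) if len(kd) > 1 else 0.0
    best = (0, -1)  # (length, start)
    i = 0
    while i < len(labels):
        if labels[i] == Regime.ANTICIPATORY:
            j = i
            while j + 1 < len(labels) and labels[j + 1] == Regime.ANTICIPATORY:
                j += 1
            if j - i + 1 > best[0]:
                best = (j - i + 1, i)
            i = j + 1
        else:
            i += 1
    if best[0] == 0:
        return 0.0
    i = best[1]
    j = i + best[0] - 1
    return float(log_kd[j] - log_kd[i] + spacing)


def _optimize_point(schedule, base_params, bounds, fp, cfg, point_seed):
    """Reduced (first-term-pinned) search, then full search warm-started by it."""
    first, _ = _term_names(bounds)
    pin_value = bounds.lo(first)
    pinned_bounds = bounds.pinned(first, pin_value)
    cfg_point = replace(cfg, seed=point_seed)
    pinned_opt = hill_climb(schedule, base_params, pinned_bounds, fp, cfg_point)
    warm = dict(pinned_opt.values)
    free_opt = hill_climb(
        schedule, base_params, bounds, fp, cfg_point, extra_starts=[warm]
    )
    return pinned_opt, free_opt


def _row(kd2, emax, pinned_opt, free_opt, mode, fixed_b):
    prom = free_opt.params.promoter
    row = {
        "kd2": kd2,
        "b1_opt": prom.b1,
        "b2_opt": prom.b2,
        "Km1_opt": prom.Km1,
        "Km2_opt": prom.Km2,
        "net_fitness": free_opt.fitness.net,
        "net_fitness_plain": pinned_opt.fitness.net,
        "regime": free_opt.regime.value,
    }
    if emax is not None:
        row = {"emax": emax, **row}
    if mode == SearchMode.BINDING_AFFINITY:
        row["k_on1_opt"] = free_opt.values["k_on1"]
        row["k_on2_opt"] = free_opt.values["k_on2"]
    return row


def sweep_kd(
    kd_grid,
    schedule: SignalSchedule | None = None,
    base_params: ModelParameters | None = None,
    bounds: ParameterBounds | None = None,
    fp: FitnessParams | None = None,
    cfg: SearchConfig | None = None,
    emax: float | None = None,
) -> RegimeMap:
    """Optimize and classify the regulatory design across a kd2 grid.

    Each grid point is seeded as ``cfg.seed + index`` so the sweep is
    reproducible point-by-point.  Both the full design and the reduced
    (first-term-pinned) design are optimized; the reduced optimum also warm
    starts the full search, so full >= reduced holds exactly at every point.
    """
    kd_grid = np.asarray(kd_grid, dtype=float)
    if np.any(kd_grid <= 0) or np.any(np.diff(kd_grid) <= 0):
        raise ContractError("kd grid must be positive and strictly increasing")
    schedule = schedule or SignalSchedule()
    base_params = base_params or default_parameters()
    cfg = cfg or SearchConfig()
    bounds = bounds or default_bounds(cfg.mode)
    fp = fp or FitnessParams()
    if emax is not None:
        fp = replace(fp, E_max=float(emax))

    rows = []
    for i, kd2 in enumerate(kd_grid):
        params_i = base_params.with_(kd2=float(kd2))
        try:
            pinned_opt, free_opt = _optimize_point(
                schedule, params_i, bounds, fp, cfg, cfg.seed + i
            )
        except SearchError as exc:
            raise SearchError(f"search failed at kd2={kd2:g}: {exc}") from exc
        rows.append(_row(float(kd2), emax, pinned_opt, free_opt, cfg.mode, cfg.fixed_b))
    return RegimeMap(
        table=pd.DataFrame(rows), kd_grid=kd_grid, emax_grid=None, mode=cfg.mode
    )


def sweep_emax_kd(
    emax_grid,
    kd_grid,
    schedule: SignalSchedule | None = None,
    base_params: ModelParameters | None = None,
    bounds: ParameterBounds | None = None,
    fp: FitnessParams | None = None,
    cfg: SearchConfig | None = None,
) -> RegimeMap:
    """2-D regime map over (E_max, kd2); per-point seed = seed + flat index."""
    emax_grid = np.asarray(emax_grid, dtype=float)
    kd_grid = np.asarray(kd_grid, dtype=float)
    if np.any(emax_grid < 0) or (len(emax_grid) > 1 and np.any(np.diff(emax_grid) <= 0)):
        raise ContractError("E_max grid must be non-negative and strictly increasing")
    cfg = cfg or SearchConfig()
    maps = []
    for j, emax in enumerate(emax_grid):
        cfg_row = replace(cfg, seed=cfg.seed + j * len(kd_grid))
        maps.append(
            sweep_kd(
                kd_grid,
                schedule=schedule,
                base_params=base_params,
                bounds=bounds,
                fp=fp,
                cfg=cfg_row,
                emax=float(emax),
            )
        )
    table = pd.concat([m.table for m in maps], ignore_index=True)
    return RegimeMap(
        table=table,
        kd_grid=kd_grid,
        emax_grid=emax_grid,
        mode=(cfg or SearchConfig()).mode,
    )
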