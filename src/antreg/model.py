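"""Deterministic dynamics of a two-module regulatory circuit under sequential signals.

The circuit abstracts a cell that experiences two environmental signals in a
fixed order: s1 (e.g. a carbon source) on ``[t0, t1)`` and s2 (e.g. an
oxidative stress) on ``[t1, t2]``.  Each signal reversibly activates its own
transcription factor,

    dRi*/dt = kf_i · (Ri_total − Ri*) · s_i(t) − kr_i · Ri*,

and the stress-response target protein T2 is produced from its promoter with
Michaelis–Menten (saturating) activation by the active regulators:

    dT2/dt = b1 · R1*/(R1* + Km1) + b2 · R2*/(R2* + Km2) − kd2 · T2.

With ``b1 = 0`` this is the conventional design in which each target is
controlled only by its cognate regulator; ``b1 > 0`` wires the first
regulator onto the second module's target, i.e. anticipatory (conditioned)
regulation.

Two integration back ends are provided.  ``method="analytic"`` (default)
exploits the fact that the activation kinetics are linear within each signal
segment — R*(t) is closed-form — and propagates T2 with an exponential
integrator that is exact for piecewise-linear production input; it is fast
enough for the evolutionary sweeps.  ``method="ivp"`` integrates the full
three-state system with a stiff-capable adaptive solver and is used as a
cross-check.  Both restart at ``t1`` so the signal discontinuity is handled
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.signal import lfilter

from .errors import ConfigurationError, ContractError, DomainError, IntegrationError

__all__ = [
    "SignalSchedule",
    "RegulatorKinetics",
    "PromoterControl",
    "TargetProteinParams",
    "ModelParameters",
    "Trajectory",
    "signal_levels",
    "regulator_equilibrium",
    "production_rate",
    "steady_state_T2",
    "simulate",
    "default_parameters",
    "default_schedule",
]


@dataclass(frozen=True)
class SignalSchedule:
    """Step-function timing of the two signals.

    s1 is present at level ``s1_level`` exactly on ``[t0, t1)`` and s2 at
    ``s2_level`` exactly on ``[t1, t2]``.  The boundary ``t1`` is assigned to
    s2 (half-open convention; the choice is arbitrary but fixed).
    """

    t0: float = 0.0
    t1: float = 6.0
    t2: float = 12.0
    s1_level: float = 1.0
    s2_level: float = 1.0

    def __post_init__(self):
        if not (self.t0 < self.t1 < self.t2):
            raise DomainError(
                f"require t0 < t1 < t2, got ({self.t0}, {self.t1}, {self.t2})"
            )
        if self.s1_level < 0 or self.s2_level < 0:
            raise DomainError("signal levels must be non-negative")

    def levels(self, t):
        return signal_levels(self, t)


def signal_levels(schedule: SignalSchedule, t):
    """Signal levels ``(s1, s2)`` at time(s) ``t`` within ``[t0, t2]``."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < schedule.t0) or np.any(t_arr > schedule.t2):
        raise DomainError(f"t outside [{schedule.t0}, {schedule.t2}]")
    in_first = t_arr < schedule.t1
    s1 = np.where(in_first, schedule.s1_level, 0.0)
    s2 = np.where(in_first, 0.0, schedule.s2_level)
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(s1), float(s2)
    return s1, s2


@dataclass(frozen=True)
class RegulatorKinetics:
    """Reversible signal-activation kinetics of one transcription factor.

    ``kf`` and ``kr`` are the association/dissociation rate constants between
    regulator and signal; ``R_total`` is the conserved total (inactive +
    active) regulator concentration, which closes the binding reaction.
    """

    kf: float = 1.0
    kr: float = 1.0
    R_total: float = 1.0

    def __post_init__(self):
        if self.kf <= 0 or self.kr <= 0 or self.R_total <= 0:
            raise DomainError("kf, kr and R_total must all be positive")

    def equilibrium(self, s: float) -> float:
        return regulator_equilibrium(self, s)


def regulator_equilibrium(kin: RegulatorKinetics, s) -> float:
    """Fixed point R* = R_total · kf·s / (kf·s + kr) of the activation ODE."""
    s_arr = np.asarray(s, dtype=float)
    if np.any(s_arr < 0):
        raise DomainError("signal concentration must be non-negative")
    out = kin.R_total * kin.kf * s_arr / (kin.kf * s_arr + kin.kr)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class PromoterControl:
    """Promoter of T2: two saturating activation terms, one per regulator.

    ``b1 = 0`` recovers the non-anticipatory design exactly.  ``hill1`` is an
    optional Hill exponent on the R1* term (default 1, plain hyperbolic).
    Each Km may alternatively be specified through its binding decomposition
    ``Km = k_off / k_on``.
    """

    b1: float = 0.0
    b2: float = 1.0
    Km1: float = 1.0
    Km2: float = 1.0
    hill1: float = 1.0
    k_on1: float | None = None
    k_off1: float | None = None
    k_on2: float | None = None
    k_off2: float | None = None

    def __post_init__(self):
        if self.b1 < 0 or self.b2 < 0:
            raise DomainError("b1 and b2 must be non-negative")
        if self.Km1 <= 0 or self.Km2 <= 0:
            raise DomainError("Km1 and Km2 must be positive")
        if self.hill1 <= 0:
            raise DomainError("hill1 must be positive")
        for km, k_on, k_off, tag in (
            (self.Km1, self.k_on1, self.k_off1, "1"),
            (self.Km2, self.k_on2, self.k_off2, "2"),
        ):
            if (k_on is None) != (k_off is None):
                raise ConfigurationError(
                    f"k_on{tag}/k_off{tag} must be supplied together"
                )
            if k_on is not None:
                if k_on <= 0 or k_off <= 0:
                    raise DomainError("k_on and k_off must be positive")
                if abs(km - k_off / k_on) > 1e-12 * km:
                    raise DomainError(
                        f"Km{tag}={km} inconsistent with k_off{tag}/k_on{tag}"
                        f"={k_off / k_on}"
                    )

    @classmethod
    def from_binding(cls, b1, b2, k_on1, k_off1, k_on2, k_off2, hill1=1.0):
        return cls(
            b1=b1,
            b2=b2,
            Km1=k_off1 / k_on1,
            Km2=k_off2 / k_on2,
            hill1=hill1,
            k_on1=k_on1,
            k_off1=k_off1,
            k_on2=k_on2,
            k_off2=k_off2,
        )


@dataclass(frozen=True)
class TargetProteinParams:
    """Turnover of T2: combined degradation + dilution rate and initial level."""

    kd2: float = 1.0
    T2_init: float = 0.0

    def __post_init__(self):
        if self.kd2 <= 0:
            raise DomainError("kd2 must be positive")
        if self.T2_init < 0:
            raise DomainError("T2_init must be non-negative")


@dataclass(frozen=True)
class ModelParameters:
    """All kinetic, promoter, turnover constants of the circuit."""

    reg1: RegulatorKinetics = field(default_factory=RegulatorKinetics)
    reg2: RegulatorKinetics = field(default_factory=RegulatorKinetics)
    promoter: PromoterControl = field(default_factory=PromoterControl)
    target: TargetProteinParams = field(default_factory=TargetProteinParams)

    def with_(self, **kwargs) -> "ModelParameters":
        """Return a copy with flat kinetic fields replaced.

        Accepts any of: kf1, kr1, R1_total, kf2, kr2, R2_total, b1, b2, Km1,
        Km2, hill1, kd2, T2_init.
        """
        reg1 = {k[:-1]: v for k, v in kwargs.items() if k in ("kf1", "kr1")}
        if "R1_total" in kwargs:
            reg1["R_total"] = kwargs["R1_total"]
        reg2 = {k[:-1]: v for k, v in kwargs.items() if k in ("kf2", "kr2")}
        if "R2_total" in kwargs:
            reg2["R_total"] = kwargs["R2_total"]
        prom = {
            k: v
            for k, v in kwargs.items()
            if k in ("b1", "b2", "Km1", "Km2", "hill1")
        }
        if prom:
            # drop a stored binding decomposition once Km is overridden
            prom.setdefault("k_on1", None)
            prom.setdefault("k_off1", None)
            prom.setdefault("k_on2", None)
            prom.setdefault("k_off2", None)
        targ = {k: v for k, v in kwargs.items() if k in ("kd2", "T2_init")}
        known = set(
            ["kf1", "kr1", "R1_total", "kf2", "kr2", "R2_total", "kd2", "T2_init"]
        ) | {"b1", "b2", "Km1", "Km2", "hill1"}
        unknown = set(kwargs) - known
        if unknown:
            raise ConfigurationError(f"unknown parameter names: {sorted(unknown)}")
        out = self
        if reg1:
            out = replace(out, reg1=replace(out.reg1, **reg1))
        if reg2:
            out = replace(out, reg2=replace(out.reg2, **reg2))
        if prom:
            out = replace(out, promoter=replace(out.promoter, **prom))
        if targ:
            out = replace(out, target=replace(out.target, **targ))
        return out


def default_parameters() -> ModelParameters:
    """Reference parameter set.

    Association is unit rate; dissociation is faster (kr = 4, i.e. regulator
    deactivation within ~15 min) so the regulator state tracks its signal on
    the 6 h epoch timescale and the two wiring designs stay distinct —
    otherwise the first regulator keeps driving the target hours into the
    second epoch.
    """
    return ModelParameters(
        reg1=RegulatorKinetics(kf=1.0, kr=4.0, R_total=1.0),
        reg2=RegulatorKinetics(kf=1.0, kr=4.0, R_total=1.0),
        promoter=PromoterControl(b1=0.0, b2=1.0, Km1=1.0, Km2=1.0),
        target=TargetProteinParams(kd2=1.0, T2_init=0.0),
    )


def default_schedule() -> SignalSchedule:
    return SignalSchedule()


@dataclass
class Trajectory:
    """Time-resolved solution (R1*, R2*, T2) over the signal schedule."""

    times: np.ndarray
    R1_star: np.ndarray
    R2_star: np.ndarray
    T2: np.ndarray
    schedule: SignalSchedule

    def signals(self):
        return signal_levels(self.schedule, self.times)

    def to_frame(self):
        import pandas as pd

        s1, s2 = self.signals()
        return pd.DataFrame(
            {
                "time": self.times,
                "s1": s1,
                "s2": s2,
                "R1_star": self.R1_star,
                "R2_star": self.R2_star,
                "T2": self.T2,
            }
        )

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    def index_of_t1(self) -> int:
        i = int(np.searchsorted(self.times, self.schedule.t1))
        if i >= len(self.times) or not np.isclose(
            self.times[i], self.schedule.t1, rtol=0, atol=1e-9
        ):
            raise ContractError("t1 is not a grid point of this trajectory")
        return i


def production_rate(promoter: PromoterControl, R1_star, R2_star):
    """Instantaneous T2 production b1·R1*^h/(R1*^h+Km1^h) + b2·R2*/(R2*+Km2)."""
    r1 = np.asarray(R1_star, dtype=float)
    r2 = np.asarray(R2_star, dtype=float)
    h = promoter.hill1
    if h == 1.0:
        term1 = promoter.b1 * r1 / (r1 + promoter.Km1)
    else:
        r1h = np.power(r1, h)
        term1 = promoter.b1 * r1h / (r1h + promoter.Km1**h)
    term2 = promoter.b2 * r2 / (r2 + promoter.Km2)
    out = np.where(r1 + r2 >= 0, term1 + term2, np.nan)
    return float(out) if out.ndim == 0 else out


def steady_state_T2(params: ModelParameters, R1_star: float, R2_star: float) -> float:
    """Fixed point of the T2 equation with the active-regulator levels frozen."""
    if params.target.kd2 <= 0:
        raise DomainError("kd2 must be positive")
    if R1_star < 0 or R2_star < 0:
        raise DomainError("active regulator levels must be non-negative")
    return production_rate(params.promoter, R1_star, R2_star) / params.target.kd2


def _regulator_segment(kin: RegulatorKinetics, s: float, r0: float, tau: np.ndarray):
    """Closed-form R*(t0+tau) at constant signal level s."""
    alpha = kin.kf * s + kin.kr
    req = kin.R_total * kin.kf * s / alpha
    return req + (r0 - req) * np.exp(-alpha * tau)


def _t2_segment_analytic(kd2: float, t2_0: float, prod: np.ndarray, h: float):
    """Propagate dT2/dt = P(t) − kd2·T2 on a uniform grid (spacing h).

    Exponential integrator, exact when P is linear within each step:
    T2[n+1] = E·T2[n] + w0·P[n] + w1·P[n+1] with E = exp(−kd2·h).
    """
    a = kd2
    ah = a * h
    e = np.exp(-ah)
    one_minus_e = -np.expm1(-ah)
    # w1 = (ah − 1 + E)/(a²h); the numerator is computed cancellation-free
    w1 = (np.expm1(-ah) + ah) / (a * a * h)
    w0 = one_minus_e / a - w1
    c = w0 * prod[:-1] + w1 * prod[1:]
    x = np.concatenate(([t2_0], c))
    y = lfilter([1.0], [1.0, -e], x)
    return y


def simulate(
    params: ModelParameters,
    schedule: SignalSchedule,
    method: str = "analytic",
    n_points: int = 1001,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    R1_init: float = 0.0,
    R2_init: float = 0.0,
) -> Trajectory:
    """Integrate the circuit over ``[t0, t2]`` with a restart at ``t1``.

    Parameters
    ----------
    method : {"analytic", "ivp"}
        ``analytic`` uses the per-segment closed form for R* plus an
        exponential integrator for T2 (fast, used by the sweeps); ``ivp``
        uses ``scipy.integrate.solve_ivp`` with LSODA.
    n_points : int
        Output grid points per signal segment (uniform); also the quadrature
        grid used downstream by the fitness evaluator.
    """
    if n_points < 2:
        raise ContractError("n_points must be at least 2")
    if rtol <= 0 or atol <= 0:
        raise ContractError("solver tolerances must be positive")
    if R1_init < 0 or R2_init < 0:
        raise DomainError("initial regulator activities must be non-negative")

    segments = [
        (schedule.t0, schedule.t1, schedule.s1_level, 0.0),
        (schedule.t1, schedule.t2, 0.0, schedule.s2_level),
    ]
    state = (float(R1_init), float(R2_init), float(params.target.T2_init))
    all_t, all_r1, all_r2, all_t2 = [], [], [], []

    for seg_idx, (ta, tb, s1, s2) in enumerate(segments):
        t_local = np.linspace(ta, tb, n_points)
        tau = t_local - ta
        if method == "analytic":
            r1 = _regulator_segment(params.reg1, s1, state[0], tau)
            r2 = _regulator_segment(params.reg2, s2, state[1], tau)
            prod = production_rate(params.promoter, r1, r2)
            t2 = _t2_segment_analytic(
                params.target.kd2, state[2], np.asarray(prod), tau[1] - tau[0]
            )
        elif method == "ivp":

            def rhs(_t, y, s1=s1, s2=s2):
                r1v, r2v, t2v = y
                d1 = params.reg1.kf * (params.reg1.R_total - r1v) * s1 - params.reg1.kr * r1v
                d2 = params.reg2.kf * (params.reg2.R_total - r2v) * s2 - params.reg2.kr * r2v
                dT = production_rate(params.promoter, max(r1v, 0.0), max(r2v, 0.0))
                dT -= params.target.kd2 * t2v
                return (d1, d2, dT)

            sol = solve_ivp(
                rhs,
                (ta, tb),
                state,
                method="LSODA",
                t_eval=t_local,
                rtol=rtol,
                atol=atol,
            )
            if not sol.success:
                raise IntegrationError(
                    f"solver failed on segment {seg_idx}: {sol.message}",
                    segment=seg_idx,
                )
            r1, r2, t2 = sol.y
        else:
            raise ContractError(f"unknown method {method!r}")

        neg_tol = 100 * atol
        for name, series in (("R1*", r1), ("R2*", r2), ("T2", t2)):
            if np.min(series) < -neg_tol:
                raise IntegrationError(
                    f"{name} went negative ({np.min(series):.3e}) on segment "
                    f"{seg_idx}",
                    segment=seg_idx,
                )
        r1 = np.clip(r1, 0.0, None)
        r2 = np.clip(r2, 0.0, None)
        t2 = np.clip(t2, 0.0, None)
        for kin, series, name in ((params.reg1, r1, "R1*"), (params.reg2, r2, "R2*")):
            if np.max(series) > kin.R_total * (1 + 1e-9) + neg_tol:
                raise IntegrationError(
                    f"{name} exceeded its conserved total on segment {seg_idx}",
                    segment=seg_idx,
                )

        keep = slice(None) if seg_idx == 0 else slice(1, None)
        all_t.append(t_local[keep])
        all_r1.append(r1[keep])
        all_r2.append(r2[keep])
        all_t2.append(t2[keep])
        state = (float(r1[-1]), float(r2[-1]), float(t2[-1]))

    return Trajectory(
        times=np.concatenate(all_t),
        R1_star=np.concatenate(all_r1),
        R2_star=np.concatenate(all_r2),
        T2=np.concatenate(all_t2),
        schedule=schedule,
    )
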