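"""Cost-benefit fitness of a target-protein expression trajectory.

The target protein T2 confers a saturating benefit while the second signal
is present, E(T2) = E_max·T2/(T2 + Km_T2), and costs the cell linearly in
its abundance, c(T2) = c0·T2, at all times.  Net fitness for one signal
cycle is the accumulated benefit over the s2 window [t1, t2] minus the
accumulated cost over the whole cycle [t0, t2]:

    f = ∫_{t1}^{t2} E(T2(t)) dt − ∫_{t0}^{t2} c(T2(t)) dt.

Protein made during [t0, t1) — before the benefit-conferring signal arrives
— therefore contributes cost only, which is exactly what makes pre-emptive
(anticipatory) expression a trade-off.

Two cost accountings are supported.  The default, ``cost_basis =
"synthesis"``, charges c0 per unit of protein synthesized, so the
accumulated cost is c0·∫P(t)dt where P is the production rate; by the T2
ODE this equals exactly c0·(T2(t2) − T2(t0) + kd2·∫T2 dt), so it is
evaluated from the trajectory and the turnover rate alone.  Under this
accounting a rapidly turned-over protein is expensive to hold at a given
level — maintaining it during the pre-signal window is increasingly futile
as kd2 grows — which is what carves out the three regulatory regimes.
``cost_basis = "abundance"`` charges c0 per unit of standing protein per
unit time, cost = ∫c0·T2 dt (the pointwise :func:`cost_rate`); under that
accounting holding a stable protein costs the same regardless of turnover,
and one can show the cognate-only top-up is always worth adding at small
kd2, so the storage-only regime disappears.

Integrals are composite-trapezoid quadrature on the solver's output grid
(>= 1000 points per segment by default in :func:`antreg.model.simulate`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractError, DomainError
from .model import Trajectory

__all__ = ["FitnessParams", "FitnessResult", "benefit_rate", "cost_rate", "evaluate_fitness"]


@dataclass(frozen=True)
class FitnessParams:
    """E_max: maximal benefit rate; Km_T2: half-benefit T2 level; c0: unit cost.

    ``cost_basis`` selects what c0 is charged on: protein synthesized
    ("synthesis", default) or standing protein abundance per time
    ("abundance").
    """

    E_max: float = 5.0
    Km_T2: float = 1.0
    c0: float = 0.05
    cost_basis: str = "synthesis"

    def __post_init__(self):
        if self.E_max < 0:
            raise DomainError("E_max must be non-negative")
        if self.Km_T2 <= 0:
            raise DomainError("Km_T2 must be positive")
        if self.c0 < 0:
            raise DomainError("c0 must be non-negative")
        if self.cost_basis not in ("synthesis", "abundance"):
            raise DomainError("cost_basis must be 'synthesis' or 'abundance'")


@dataclass(frozen=True)
class FitnessResult:
    benefit: float
    cost: float
    net: float

    def __post_init__(self):
        if not np.isclose(self.net, self.benefit - self.cost, rtol=0, atol=1e-12 * (1 + abs(self.benefit) + abs(self.cost))):
            raise ContractError("net must equal benefit - cost")


def benefit_rate(T2, fp: FitnessParams):
    """Saturating benefit rate E_max·T2/(T2 + Km_T2); bounded by E_max."""
    arr = np.asarray(T2, dtype=float)
    if np.any(arr < 0):
        raise DomainError("T2 must be non-negative")
    out = fp.E_max * arr / (arr + fp.Km_T2)
    return float(out) if out.ndim == 0 else out


def cost_rate(T2, fp: FitnessParams):
    """Linear production/maintenance cost rate c0·T2."""
    arr = np.asarray(T2, dtype=float)
    if np.any(arr < 0):
        raise DomainError("T2 must be non-negative")
    out = fp.c0 * arr
    return float(out) if out.ndim == 0 else out


def evaluate_fitness(
    traj: Trajectory, fp: FitnessParams, kd2: float | None = None
) -> FitnessResult:
    """Accumulate benefit over [t1, t2] and cost over [t0, t2] by quadrature.

    ``kd2`` (the T2 turnover rate) is required for the synthesis cost basis,
    where cost = c0·(T2(t2) − T2(t0) + kd2·∫T2 dt) = c0·∫production dt.
    """
    sched = traj.schedule
    if not np.isclose(traj.times[0], sched.t0, rtol=0, atol=1e-9) or not np.isclose(
        traj.times[-1], sched.t2, rtol=0, atol=1e-9
    ):
        raise ContractError("trajectory does not span [t0, t2]")
    i1 = traj.index_of_t1()
    benefit = float(
        np.trapezoid(benefit_rate(traj.T2[i1:], fp), traj.times[i1:])
    )
    abundance_integral = float(np.trapezoid(traj.T2, traj.times))
    if fp.cost_basis == "abundance":
        cost = fp.c0 * abundance_integral
    else:
        if kd2 is None:
            raise ContractError("synthesis cost basis requires kd2")
        cost = fp.c0 * (
            float(traj.T2[-1]) - float(traj.T2[0]) + kd2 * abundance_integral
        )
    cost = max(cost, 0.0)
    return FitnessResult(benefit=benefit, cost=cost, net=benefit - cost)
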