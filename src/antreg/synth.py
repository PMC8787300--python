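"""Seeded synthetic plate-reader datasets emulating the evolution experiment.

The generator reproduces the statistical structure of the assay, not its
biochemistry: ten lines (ancestor WT; Alt1-3 evolved in alternating
rhamnose/paraquat; Rha1-3 rhamnose-only; PQ1-3 paraquat-only), each grown in
paraquat after pre-growth with or without rhamnose, in triplicate, sampled
every 30 min.  Growth is logistic — so plateau and never-crossing edge cases
occur naturally — with multiplicative log-normal noise of mean exactly 1
(proportional plate-reader error).  The anticipatory phenotype is injected
as a relative rate increase applied ONLY to Alt lines pre-exposed to
rhamnose, and the reporter phenotype as a fold-induction of fluorescence per
OD applied only to Alt lines in rhamnose.  Baseline rates, effect sizes and
noise levels are package choices calibrated to make the qualitative pattern
detectable; the source experiment reports its values only as figure bars.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError
from .growth import Condition, PLATE_COLUMNS

__all__ = [
    "ExperimentDesign",
    "EffectModel",
    "generate_growth_curve",
    "generate_experiment",
    "generations_per_transfer",
    "logistic_od",
    "line_type",
]

DEFAULT_LINES = (
    "WT",
    "Alt1",
    "Alt2",
    "Alt3",
    "Rha1",
    "Rha2",
    "Rha3",
    "PQ1",
    "PQ2",
    "PQ3",
)

# Baseline Malthusian rates (1/h) by line type: rhamnose-only lines grow the
# slowest in paraquat; alternating and PQ-evolved lines are PQ-adapted.
DEFAULT_BASELINE_RATES = {"WT": 0.45, "Alt": 0.55, "Rha": 0.35, "PQ": 0.55}


@dataclass(frozen=True)
class ExperimentDesign:
    """Plate layout: lines x {pre-rhamnose, naive} x replicates."""

    lines: tuple = DEFAULT_LINES
    replicates: int = 3
    interval_h: float = 0.5
    horizon_h: float = 12.0
    dilution_factor: float = 100.0
    od_init: float = 0.1

    def __post_init__(self):
        if self.replicates < 2:
            raise DomainError("need at least 2 replicates")
        if self.interval_h <= 0 or self.horizon_h <= self.interval_h:
            raise DomainError("need interval > 0 and horizon > interval")
        if self.dilution_factor <= 1:
            raise DomainError("dilution factor must exceed 1")


@dataclass(frozen=True)
class EffectModel:
    """Effect sizes and noise of the emulated phenotypes."""

    baseline_rates: dict = field(default_factory=lambda: dict(DEFAULT_BASELINE_RATES))
    anticipatory_effect: float = 0.20  # relative rate gain, Alt x pre-rhamnose only
    capacity_od: float = 2.0
    noise_sd: float = 0.02  # multiplicative log-normal, mean 1
    reporter_per_od: float = 200.0  # fluorescence units per OD unit, uninduced
    reporter_fold_induction: float = 3.0  # Alt lines in rhamnose only
    reporter_noise_sd: float = 5.0  # additive fluorescence noise, floored at 0
    seed: int = 0

    def __post_init__(self):
        if any(r <= 0 for r in self.baseline_rates.values()):
            raise DomainError("baseline rates must be positive")
        if self.noise_sd < 0 or self.reporter_noise_sd < 0:
            raise DomainError("noise levels must be non-negative")
        if self.reporter_fold_induction < 1:
            raise DomainError("fold induction must be >= 1")


def line_type(line: str) -> str:
    for prefix in ("Alt", "Rha", "PQ", "WT"):
        if line.startswith(prefix):
            return prefix
    raise DomainError(f"unrecognized line label {line!r}")


def logistic_od(t, r, od0, capacity):
    """Logistic growth OD(t) = K·od0·e^{rt} / (K + od0·(e^{rt} − 1))."""
    t = np.asarray(t, dtype=float)
    if np.isinf(capacity):
        return od0 * np.exp(r * t)
    # overflow-safe form: K / (1 + (K/od0 - 1) e^{-rt})
    return capacity / (1.0 + (capacity / od0 - 1.0) * np.exp(-r * t))


def _lognormal_factors(rng, sd, size):
    """Multiplicative noise factors with mean exactly 1 and sd ``sd``."""
    if sd == 0:
        return np.ones(size)
    sigma2 = np.log1p(sd * sd)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def generate_growth_curve(
    r: float,
    od0: float,
    capacity: float,
    interval: float,
    horizon: float,
    noise_sd: float,
    rng: np.random.Generator,
):
    """One noisy logistic growth curve sampled on a uniform grid."""
    if r <= 0 or od0 <= 0:
        raise DomainError("growth rate and inoculation OD must be positive")
    if capacity <= od0:
        raise DomainError("carrying capacity must exceed the inoculation OD")
    times = np.arange(0.0, horizon + 0.5 * interval, interval)
    od = logistic_od(times, r, od0, capacity) * _lognormal_factors(
        rng, noise_sd, len(times)
    )
    return times, od


def generate_experiment(
    design: ExperimentDesign | None = None,
    effects: EffectModel | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Full synthetic plate table, one curve per (line, condition, replicate).

    The anticipatory rate bonus applies only to Alt lines under
    PRE_RHAMNOSE; reporter fold-induction only to Alt lines in rhamnose.
    Deterministic given the seed (``effects.seed`` unless overridden).
    """
    design = design or ExperimentDesign()
    effects = effects or EffectModel()
    rng = np.random.default_rng(effects.seed if seed is None else seed)
    rows = []
    well_idx = 0
    for line in design.lines:
        ltype = line_type(line)
        r0 = effects.baseline_rates[ltype]
        for cond in (Condition.PRE_RHAMNOSE, Condition.NO_PRE_RHAMNOSE):
            induced = ltype == "Alt" and cond == Condition.PRE_RHAMNOSE
            r = r0 * (1.0 + effects.anticipatory_effect) if induced else r0
            per_od = effects.reporter_per_od * (
                effects.reporter_fold_induction if induced else 1.0
            )
            for rep in range(1, design.replicates + 1):
                well_idx += 1
                times, od = generate_growth_curve(
                    r,
                    design.od_init,
                    effects.capacity_od,
                    design.interval_h,
                    design.horizon_h,
                    effects.noise_sd,
                    rng,
                )
                fluor = np.maximum(
                    per_od * od
                    + rng.normal(0.0, effects.reporter_noise_sd, len(times)),
                    0.0,
                )
                rows.append(
                    pd.DataFrame(
                        {
                            "time_h": times,
                            "well": f"W{well_idx:03d}",
                            "od600": od,
                            "fluorescence": fluor,
                            "line": line,
                            "condition": cond.value,
                            "replicate": rep,
                        }
                    )
                )
    table = pd.concat(rows, ignore_index=True)
    assert all(c in table.columns for c in PLATE_COLUMNS)
    return table


def generations_per_transfer(dilution_factor: float) -> float:
    """Doublings needed to regrow after a 1:N serial transfer, log2(N).

    A 1:100 dilution implies ~6.6 generations per 12-h cycle, consistent
    with the 6-7 generations per transfer of the emulated experiment.
    """
    if dilution_factor <= 1:
        raise DomainError("dilution factor must exceed 1")
    return float(np.log2(dilution_factor))
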