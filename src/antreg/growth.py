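"""Plate-reader growth-phenotype analysis.

Mirrors the analysis stage of a serial-transfer evolution experiment in
which lines evolved under alternating rhamnose/paraquat (Alt), rhamnose-only
(Rha) or paraquat-only (PQ) regimes are assayed for anticipatory regulation:
each line is pre-grown with or without rhamnose, transferred into paraquat
medium at OD600 0.1, and its Malthusian growth rate r is computed from the
time taken to reach OD600 1.0 assuming exponential growth over that span,

    r = ln(OD_target / OD_init) / t_cross,

with the crossing time interpolated linearly in log-OD between the
bracketing samples.  Pre-exposed and naive rates are compared with a
two-tailed t-test; a line is called anticipatory when the pre-exposed mean
rate is the larger AND the p-value clears the significance level.

The default test is the pooled two-sample t-test (df = nA + nB − 2, i.e. 4
for triplicates); a paired test (df = n − 1) is available by flag.  Reporter
(promoter-fusion) expression is summarized as blank-corrected fluorescence
per blank-corrected OD averaged over a time window.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ContractError,
    DegenerateDenominatorError,
    DomainError,
    NoCrossingError,
)

__all__ = [
    "Condition",
    "TestMethod",
    "GrowthRateEstimate",
    "ComparisonResult",
    "PromoterActivity",
    "AnticipationResult",
    "malthusian_rate",
    "compare_growth_rates",
    "promoter_activity",
    "anticipation_test",
    "read_plate_table",
    "plate_growth_rates",
    "PLATE_COLUMNS",
]

PLATE_COLUMNS = ("time_h", "well", "od600", "line", "condition", "replicate")


class Condition(str, Enum):
    PRE_RHAMNOSE = "PRE_RHAMNOSE"
    NO_PRE_RHAMNOSE = "NO_PRE_RHAMNOSE"


class TestMethod(str, Enum):
    TWO_SAMPLE_POOLED = "TWO_SAMPLE_POOLED"
    PAIRED = "PAIRED"


@dataclass(frozen=True)
class GrowthRateEstimate:
    """Malthusian rate r = ln(od_target/od_init)/t_cross (units 1/h)."""

    r: float
    t_cross: float
    od_init: float
    od_target: float


@dataclass(frozen=True)
class ComparisonResult:
    mean_a: float
    mean_b: float
    t: float
    df: int
    p: float
    method: TestMethod


@dataclass(frozen=True)
class PromoterActivity:
    """Blank-corrected fluorescence per OD, averaged over a time window."""

    activity: float
    window: tuple
    n_points: int


@dataclass(frozen=True)
class AnticipationResult:
    line: str
    comparison: ComparisonResult
    anticipatory: bool
    alpha: float
    rates_pre: tuple
    rates_no_pre: tuple


def malthusian_rate(
    times,
    od,
    od_init: float = 0.1,
    od_target: float = 1.0,
    blank: float = 0.0,
) -> GrowthRateEstimate:
    """Growth rate from the time a culture takes to reach the target OD.

    ``od_init`` is the inoculation density the rate formula assumes (the
    plate wells are seeded at OD 0.1), not necessarily the first reading.
    The crossing time is measured from the first sample and interpolated in
    log-OD space (exponential-growth assumption) between the bracketing
    readings; a curve that never reaches the target raises
    :class:`NoCrossingError` reporting the maximum OD seen.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(od, dtype=float) - blank
    if t.ndim != 1 or t.shape != y.shape or len(t) < 2:
        raise ContractError("need matching 1-D time/OD series with >= 2 points")
    if np.any(np.diff(t) <= 0):
        raise ContractError("times must be strictly increasing")
    if od_init <= 0 or od_target <= 0:
        raise DomainError("od_init and od_target must be positive")
    if np.any(y <= 0):
        raise DomainError("blank-corrected OD must be positive everywhere")
    if y[0] >= od_target:
        raise ContractError("curve must start below the target OD")

    above = np.nonzero(y >= od_target)[0]
    if len(above) == 0:
        raise NoCrossingError(
            f"curve never reaches OD {od_target:g} (max {np.max(y):g})",
            max_od=float(np.max(y)),
        )
    k = int(above[0])  # first crossing; robust to later non-monotone noise
    if y[k] == od_target or y[k] == y[k - 1]:
        t_hit = t[k]
    else:
        frac = (np.log(od_target) - np.log(y[k - 1])) / (np.log(y[k]) - np.log(y[k - 1]))
        t_hit = t[k - 1] + frac * (t[k] - t[k - 1])
    t_cross = float(t_hit - t[0])
    r = float(np.log(od_target / od_init) / t_cross)
    return GrowthRateEstimate(r=r, t_cross=t_cross, od_init=od_init, od_target=od_target)


def compare_growth_rates(
    group_a, group_b, method: TestMethod = TestMethod.TWO_SAMPLE_POOLED
) -> ComparisonResult:
    """Two-tailed t-test between two groups of rates.

    Pooled two-sample by default (df = nA + nB − 2; triplicates give the
    familiar 4 df); paired (df = n − 1) requires equal group sizes.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    method = TestMethod(method)
    if len(a) < 2 or len(b) < 2:
        raise ContractError("each group needs at least 2 observations")
    if method == TestMethod.PAIRED:
        if len(a) != len(b):
            raise ContractError("paired test requires equal group sizes")
        df = len(a) - 1
        d = a - b
        if np.ptp(d) == 0:  # constant differences: no within-pair variance
            if d[0] == 0:
                t_stat, p = 0.0, 1.0
            else:
                t_stat, p = float(np.sign(d[0]) * np.inf), 0.0
        else:
            res = stats.ttest_rel(a, b)
            t_stat, p = float(res.statistic), float(res.pvalue)
    else:
        df = len(a) + len(b) - 2
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            if a.mean() == b.mean():
                t_stat, p = 0.0, 1.0
            else:
                t_stat, p = float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
        else:
            res = stats.ttest_ind(a, b, equal_var=True)
            t_stat, p = float(res.statistic), float(res.pvalue)
    return ComparisonResult(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        t=t_stat,
        df=int(df),
        p=float(min(max(p, 0.0), 1.0)),
        method=method,
    )


def promoter_activity(culture: pd.DataFrame, blank: pd.DataFrame, window) -> PromoterActivity:
    """Mean of (F − F_blank)/(OD − OD_blank) over a time window, floored at 0.

    ``culture`` and ``blank`` must share the same time grid and carry
    ``time_h``, ``od600`` and ``fluorescence`` columns.
    """
    lo, hi = float(window[0]), float(window[1])
    for df, tag in ((culture, "culture"), (blank, "blank")):
        for col in ("time_h", "od600", "fluorescence"):
            if col not in df.columns:
                raise ContractError(f"{tag} table lacks column {col!r}")
    c = culture.sort_values("time_h").reset_index(drop=True)
    b = blank.sort_values("time_h").reset_index(drop=True)
    if len(c) != len(b) or not np.allclose(c["time_h"], b["time_h"]):
        raise ContractError("culture and blank must share the same time grid")
    mask = (c["time_h"] >= lo) & (c["time_h"] <= hi)
    if not mask.any():
        raise ContractError("window contains no samples")
    denom = (c.loc[mask, "od600"] - b.loc[mask, "od600"]).to_numpy()
    numer = (c.loc[mask, "fluorescence"] - b.loc[mask, "fluorescence"]).to_numpy()
    bad = np.nonzero(denom <= 0)[0]
    if len(bad):
        rows = c.loc[mask].iloc[bad]["time_h"].tolist()
        raise DegenerateDenominatorError(
            f"blank-corrected OD non-positive at t = {rows}", rows=rows
        )
    activity = float(max(np.mean(numer / denom), 0.0))
    return PromoterActivity(activity=activity, window=(lo, hi), n_points=int(mask.sum()))


def read_plate_table(path) -> pd.DataFrame:
    """Read a long-format plate CSV and validate the required columns."""
    df = pd.read_csv(path)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ContractError(f"plate table lacks columns {missing}")
    if (df["time_h"] < 0).any():
        raise ContractError("times must be non-negative")
    return df


def plate_growth_rates(
    plate: pd.DataFrame,
    od_init: float = 0.1,
    od_target: float = 1.0,
    blank: float = 0.0,
) -> pd.DataFrame:
    """Per-(line, condition, replicate) Malthusian rates from a plate table."""
    rows = []
    for (line, cond, rep), grp in plate.groupby(
        ["line", "condition", "replicate"], sort=True
    ):
        grp = grp.sort_values("time_h")
        est = malthusian_rate(
            grp["time_h"], grp["od600"], od_init=od_init, od_target=od_target, blank=blank
        )
        rows.append(
            {
                "line": line,
                "condition": cond,
                "replicate": rep,
                "r": est.r,
                "t_cross": est.t_cross,
            }
        )
    return pd.DataFrame(rows)


def anticipation_test(
    plate: pd.DataFrame,
    line: str,
    alpha: float = 0.05,
    od_init: float = 0.1,
    od_target: float = 1.0,
    method: TestMethod = TestMethod.TWO_SAMPLE_POOLED,
) -> AnticipationResult:
    """Test one line for an anticipatory growth phenotype.

    Computes per-replicate rates under both pre-growth conditions and calls
    the line anticipatory iff the rhamnose-pre-exposed mean rate is greater
    and the two-tailed p-value is below ``alpha``.
    """
    sub = plate[plate["line"] == line]
    if sub.empty:
        raise ContractError(f"line {line!r} not present in plate table")
    conds = set(sub["condition"])
    needed = {Condition.PRE_RHAMNOSE.value, Condition.NO_PRE_RHAMNOSE.value}
    if not needed <= conds:
        raise ContractError(f"line {line!r} lacks conditions {sorted(needed - conds)}")
    rates = plate_growth_rates(sub, od_init=od_init, od_target=od_target)
    pre = rates[rates["condition"] == Condition.PRE_RHAMNOSE.value]["r"].to_numpy()
    no = rates[rates["condition"] == Condition.NO_PRE_RHAMNOSE.value]["r"].to_numpy()
    if len(pre) != len(no):
        raise ContractError("replicate counts differ between conditions")
    cmp = compare_growth_rates(pre, no, method=method)
    verdict = (cmp.mean_a > cmp.mean_b) and (cmp.p < alpha)
    return AnticipationResult(
        line=line,
        comparison=cmp,
        anticipatory=bool(verdict),
        alpha=alpha,
        rates_pre=tuple(pre),
        rates_no_pre=tuple(no),
    )
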