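"""Scenario comparison engine: YLL/YLD/DALY, incremental cost, ICER.

For each baseline CD4 stratum the engine evaluates two strategies:

* Scenario A — initiate cART immediately at the entry CD4 count.
* Scenario B — defer until a biannual measurement falls strictly below the
  threshold; the lifespan is the waiting time plus the (lower) life
  expectancy attached to the CD4 count at initiation.

Health loss from deferral is expressed in DALYs averted by early start:
YLL = discounted life expectancy A − B; YLD = disability-weighted
discounted years B − A (signed; negative when the longer-lived early
starter accrues more disability mass); DALY = YLL + YLD.  Costs follow the
cost model; the ICER is the incremental net cost per DALY averted, a ratio
of means for aggregate rows.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .costs import CostBreakdown, scenario_cost
from .life_expectancy import (
    disability_weighted_years,
    discount_years,
    interpolate_life_expectancy,
)
from .params import ModelParameters
from .waiting import CD4Bin, WaitOutcome, decline_at_percentile, default_bins, wait_to_initiation

__all__ = [
    "ScenarioOutcome",
    "BinResult",
    "CEARow",
    "CEASummary",
    "CEClassification",
    "evaluate_entry",
    "evaluate_bin",
    "daly_averted",
    "icer",
    "classify_cost_effectiveness",
    "summarize",
    "run_base_case",
]


class CEClassification(str, enum.Enum):
    HIGHLY_COST_EFFECTIVE = "highly cost-effective"
    COST_EFFECTIVE = "cost-effective"
    NOT_COST_EFFECTIVE = "not cost-effective"


@dataclass(frozen=True)
class ScenarioOutcome:
    """Full outcome set of one strategy for one entry CD4 count."""

    wait_years: float
    cd4_at_initiation: float
    life_expectancy: float  # undiscounted years from model entry
    discounted_life_expectancy: float
    yld_mass: float  # disability-weighted discounted years
    costs: CostBreakdown


@dataclass(frozen=True)
class BinResult:
    """Scenario A vs B comparison for one baseline CD4 stratum."""

    bin: CD4Bin
    a: ScenarioOutcome
    b: ScenarioOutcome
    yll: float
    yld: float
    daly_averted: float
    incremental_cost: float


def _scenario_outcome(
    entry_cd4: float, wait: WaitOutcome | None, params: ModelParameters
) -> ScenarioOutcome:
    wait_years = wait.wait_years if wait is not None else 0.0
    cd4_init = wait.cd4_at_initiation if wait is not None else entry_cd4
    if cd4_init > 0:
        le_from_init = interpolate_life_expectancy(cd4_init, params.anchors)
    else:
        # trajectory CD4 floored at 0: the LE clamp plateau applies
        le_from_init = params.anchors[0].life_expectancy
    total_life = wait_years + le_from_init  # lived from model entry
    discounted = discount_years(total_life, 0.0, params.discount)
    yld_mass = disability_weighted_years(total_life, 0.0, params.dw, params.discount)
    post_start_disc = discount_years(le_from_init, wait_years, params.discount)
    costs = scenario_cost(entry_cd4, wait, post_start_disc, params)
    return ScenarioOutcome(
        wait_years=wait_years,
        cd4_at_initiation=cd4_init,
        life_expectancy=total_life,
        discounted_life_expectancy=discounted,
        yld_mass=yld_mass,
        costs=costs,
    )


def daly_averted(a: ScenarioOutcome, b: ScenarioOutcome) -> dict[str, float]:
    """YLL, signed YLD, and DALYs averted by strategy ``a`` over ``b``."""
    yll = a.discounted_life_expectancy - b.discounted_life_expectancy
    yld = b.yld_mass - a.yld_mass
    return {"yll": yll, "yld": yld, "daly": yll + yld}


def evaluate_entry(
    entry_cd4: float,
    params: ModelParameters,
    decline_per_period: float | None = None,
    bin: CD4Bin | None = None,
) -> BinResult:
    """Evaluate both scenarios for one entry CD4 count (bin midpoint or an
    individual patient's baseline)."""
    if decline_per_period is None:
        decline_per_period = params.decline.median_per_period
    wait = wait_to_initiation(
        entry_cd4,
        decline_per_period,
        params.cd4_threshold,
        params.decline.period_length,
    )
    a = _scenario_outcome(entry_cd4, None, params)
    b = _scenario_outcome(entry_cd4, wait, params)
    d = daly_averted(a, b)
    return BinResult(
        bin=bin if bin is not None else CD4Bin(entry_cd4 - 5.0, entry_cd4 + 4.0),
        a=a,
        b=b,
        yll=d["yll"],
        yld=d["yld"],
        daly_averted=d["daly"],
        incremental_cost=a.costs.net - b.costs.net,
    )


def evaluate_bin(
    bin: CD4Bin,
    params: ModelParameters,
    decline_percentile: Literal["q25", "median", "q75"] = "median",
) -> BinResult:
    """Deterministic cohort evaluation of one 10-cell bin at its midpoint."""
    decline = decline_at_percentile(params.decline, decline_percentile)
    return evaluate_entry(bin.midpoint, params, decline, bin=bin)


class UndefinedICERError(ZeroDivisionError):
    """DALYs averted is zero; the ratio is undefined (dominance handled by
    the caller)."""


def icer(incremental_cost: float, dalys: float) -> float:
    """Incremental cost-effectiveness ratio, USD per DALY averted."""
    if dalys == 0:
        raise UndefinedICERError("DALYs averted is zero; ICER undefined")
    return incremental_cost / dalys


def classify_cost_effectiveness(icer_value: float, gdp: float) -> CEClassification:
    """WHO-CHOICE GDP-multiple rule: <1× GDP highly cost-effective,
    <3× cost-effective, else not (strict inequalities)."""
    if icer_value < 0:
        raise ValueError("classification expects a non-negative ICER")
    if icer_value < gdp:
        return CEClassification.HIGHLY_COST_EFFECTIVE
    if icer_value < 3 * gdp:
        return CEClassification.COST_EFFECTIVE
    return CEClassification.NOT_COST_EFFECTIVE


@dataclass(frozen=True)
class CEARow:
    """One summary row (a single bin, or the unweighted bin mean)."""

    label: str
    le_a: float
    le_b: float
    dle_a: float
    dle_b: float
    yll: float
    yld: float
    daly: float
    cart_monitoring_a: float  # lifetime cART + monitoring (B includes waiting monitoring)
    cart_monitoring_b: float
    hosp_a: float
    hosp_b: float
    net_a: float
    net_b: float
    incremental_cost: float
    icer: float | None  # None when dominance applies

    @property
    def dominance(self) -> str | None:
        if self.daly > 0 and self.incremental_cost <= 0:
            return "dominant"  # cheaper and better
        if self.daly <= 0 and self.incremental_cost >= 0:
            return "dominated"
        return None


@dataclass(frozen=True)
class CEASummary:
    """Lowest/mean/highest roll-up plus the cost-effectiveness verdict."""

    lowest: CEARow
    mean: CEARow
    highest: CEARow
    bins: tuple[BinResult, ...]
    classification: CEClassification

    @property
    def rows(self) -> tuple[CEARow, CEARow, CEARow]:
        return (self.lowest, self.mean, self.highest)


def _row_from_aggregates(label: str, results: Sequence[BinResult]) -> CEARow:
    def mean(f):
        return float(np.mean([f(r) for r in results]))

    le_a = mean(lambda r: r.a.life_expectancy)
    le_b = mean(lambda r: r.b.life_expectancy)
    dle_a = mean(lambda r: r.a.discounted_life_expectancy)
    dle_b = mean(lambda r: r.b.discounted_life_expectancy)
    yll = mean(lambda r: r.yll)
    yld = mean(lambda r: r.yld)
    daly = mean(lambda r: r.daly_averted)
    cm_a = mean(lambda r: r.a.costs.cart_and_monitoring + r.a.costs.waiting_monitoring)
    cm_b = mean(lambda r: r.b.costs.cart_and_monitoring + r.b.costs.waiting_monitoring)
    hosp_a = mean(lambda r: r.a.costs.hospitalization_24mo)
    hosp_b = mean(lambda r: r.b.costs.hospitalization_24mo)
    net_a = mean(lambda r: r.a.costs.net)
    net_b = mean(lambda r: r.b.costs.net)
    inc = net_a - net_b
    row_icer = inc / daly if daly != 0 else None
    if row_icer is not None and (daly <= 0 or inc <= 0):
        row_icer = None  # dominance: report label, not a signed ratio
    return CEARow(
        label, le_a, le_b, dle_a, dle_b, yll, yld, daly,
        cm_a, cm_b, hosp_a, hosp_b, net_a, net_b, inc, row_icer,
    )


def summarize(bin_results: Sequence[BinResult], params: ModelParameters) -> CEASummary:
    """Roll ten bin results into lowest / unweighted-mean / highest rows.

    The mean row averages the bins (uniform baseline CD4 across bins); its
    ICER is the ratio of row aggregates, not a mean of per-bin ratios.
    """
    expected = [b.label for b in default_bins(params)]
    got = [r.bin.label for r in bin_results]
    if got != expected:
        raise ValueError(f"expected the ten base bins {expected}, got {got}")
    lowest = _row_from_aggregates(f"Lowest ({bin_results[0].bin.label})", bin_results[:1])
    mean = _row_from_aggregates(
        f"Mean ({bin_results[0].bin.low:.0f}-{bin_results[-1].bin.high:.0f})",
        bin_results,
    )
    highest = _row_from_aggregates(
        f"Highest ({bin_results[-1].bin.label})", bin_results[-1:]
    )
    if mean.icer is not None:
        cls = classify_cost_effectiveness(mean.icer, params.gdp_per_capita)
    else:
        cls = (
            CEClassification.HIGHLY_COST_EFFECTIVE
            if mean.dominance == "dominant"
            else CEClassification.NOT_COST_EFFECTIVE
        )
    return CEASummary(
        lowest=lowest,
        mean=mean,
        highest=highest,
        bins=tuple(bin_results),
        classification=cls,
    )


def run_base_case(
    params: ModelParameters | None = None,
    decline_percentile: Literal["q25", "median", "q75"] = "median",
) -> CEASummary:
    """Full deterministic cohort run over the ten baseline bins."""
    params = params or ModelParameters()
    results = [evaluate_bin(b, params, decline_percentile) for b in default_bins(params)]
    return summarize(results, params)
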