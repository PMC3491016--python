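"""Cost model: lifetime treatment/monitoring, waiting-period monitoring, and
24-month hospitalization costs.

Net cost per scenario = discounted waiting-period monitoring stream
(while deferring) + discounted lifetime cART drug + monitoring stream
(annual total × discounted life-years on treatment) + hospitalization cost
over a fixed horizon of four 6-month intervals from model entry.  The
hospitalization horizon is anchored at model entry for both scenarios, so a
deferring patient's off-treatment admissions fall inside the same window as
the immediate starter's on-treatment ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .life_expectancy import discount_factor, discount_years
from .params import CD4Stratum, CostInputs, DiscountSpec, InpatientRates, ModelParameters
from .waiting import WaitOutcome, on_treatment_cd4

__all__ = [
    "CostBreakdown",
    "IntervalState",
    "lifetime_treatment_cost",
    "inpatient_days_per_year",
    "hospitalization_cost",
    "scenario_trajectory",
    "scenario_cost",
]


@dataclass(frozen=True)
class CostBreakdown:
    """Scenario cost components (USD, discounted to model entry)."""

    waiting_monitoring: float
    cart_and_monitoring: float
    hospitalization_24mo: float

    def __post_init__(self) -> None:
        if min(
            self.waiting_monitoring,
            self.cart_and_monitoring,
            self.hospitalization_24mo,
        ) < 0:
            raise ValueError("cost components must be >= 0")

    @property
    def net(self) -> float:
        return (
            self.waiting_monitoring
            + self.cart_and_monitoring
            + self.hospitalization_24mo
        )


@dataclass(frozen=True)
class IntervalState:
    """(stratum, cART status) governing one 6-month hospitalization interval."""

    time: float  # interval start, years from entry
    stratum: CD4Stratum
    on_cart: bool


def lifetime_treatment_cost(
    wait_years: float,
    post_start_discounted_years: float,
    costs: CostInputs,
    spec: DiscountSpec,
) -> float:
    """Discounted waiting-monitoring stream plus lifetime cART drug +
    monitoring cost (annual total × discounted on-treatment life-years)."""
    if wait_years < 0 or post_start_discounted_years < 0:
        raise ValueError("wait_years and discounted years must be >= 0")
    waiting = costs.waiting_total_annual * discount_years(wait_years, 0.0, spec)
    treatment = costs.treatment_total_annual * post_start_discounted_years
    return waiting + treatment


def inpatient_days_per_year(
    stratum: CD4Stratum, on_cart: bool, rates: InpatientRates
) -> float:
    """Expected annual inpatient days (with-OI plus without-OI admissions)."""
    return rates.days(CD4Stratum(stratum), on_cart)


def scenario_trajectory(
    baseline_cd4: float,
    wait: WaitOutcome | None,
    params: ModelParameters,
) -> list[IntervalState]:
    """Per-interval (stratum, cART) states over the hospitalization horizon.

    ``wait`` is None for the immediate-start scenario.  Each interval's
    state is read at its start: during deferral the patient is off cART with
    the declining CD4 count; after initiation on cART with reconstitution.
    """
    step = params.measurement_interval
    n = round(params.hospitalization_horizon / step)
    wait_years = wait.wait_years if wait is not None else 0.0
    states = []
    for i in range(n):
        t = i * step
        if wait is not None and t < wait_years:
            # off cART: CD4 from the waiting trajectory's last measurement <= t
            cd4 = [c for tm, c in wait.cd4_trajectory if tm <= t + 1e-9][-1]
            states.append(IntervalState(t, CD4Stratum.from_cd4(cd4), on_cart=False))
        else:
            start = wait.cd4_at_initiation if wait is not None else baseline_cd4
            cd4 = on_treatment_cd4(
                start, t - wait_years, params.decline.reconstitution_rate_year1
            )
            states.append(IntervalState(t, CD4Stratum.from_cd4(cd4), on_cart=True))
    return states


def hospitalization_cost(
    trajectory: Sequence[IntervalState],
    rates: InpatientRates,
    cost_per_day: float,
    spec: DiscountSpec,
    horizon: float = 2.0,
    interval: float = 0.5,
) -> float:
    """Discounted inpatient cost over the horizon.

    Each interval contributes ``interval × days_per_year(state) ×
    cost_per_day`` discounted at the interval midpoint.
    """
    n = round(horizon / interval)
    if len(trajectory) < n:
        raise ValueError(
            f"trajectory covers {len(trajectory)} intervals, horizon needs {n}"
        )
    total = 0.0
    for state in trajectory[:n]:
        days = inpatient_days_per_year(state.stratum, state.on_cart, rates)
        t_mid = state.time + interval / 2.0
        total += interval * days * cost_per_day * discount_factor(t_mid, spec.annual_rate)
    return total


def scenario_cost(
    baseline_cd4: float,
    wait: WaitOutcome | None,
    post_start_discounted_years: float,
    params: ModelParameters,
) -> CostBreakdown:
    """Assemble the three cost components for one scenario of one patient."""
    spec = params.discount
    wait_years = wait.wait_years if wait is not None else 0.0
    waiting = params.costs.waiting_total_annual * discount_years(wait_years, 0.0, spec)
    treatment = params.costs.treatment_total_annual * post_start_discounted_years
    hosp = hospitalization_cost(
        scenario_trajectory(baseline_cd4, wait, params),
        params.inpatient,
        params.costs.cost_per_inpatient_day,
        spec,
        horizon=params.hospitalization_horizon,
        interval=params.measurement_interval,
    )
    return CostBreakdown(
        waiting_monitoring=waiting,
        cart_and_monitoring=treatment,
        hospitalization_24mo=hosp,
    )
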