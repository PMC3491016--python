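"""One-way (tornado) sensitivity analysis of the mean cost-per-DALY.

Eight inputs are varied one at a time between published low/high bounds
while everything else stays at base case; the full cohort model is re-run
and the mean-row ICER recorded at each bound.  Entries sorted by the width
of the ICER interval they induce give the tornado ordering.

Scale-type parameters (inpatient-day rates, anchor life expectancies) are
multiplicative factors applied jointly to all their base values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Callable, Mapping, Sequence

from .engine import run_base_case
from .params import ModelParameters, parameters_from_dict

__all__ = ["SensitivityRange", "TornadoEntry", "default_ranges", "one_way", "tornado"]


@dataclass(frozen=True)
class SensitivityRange:
    """One parameter's base value and one-way bounds."""

    parameter_id: str
    label: str
    base: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low <= self.base <= self.high:
            raise ValueError(
                f"{self.parameter_id}: bounds must satisfy low <= base <= high"
            )


@dataclass(frozen=True)
class TornadoEntry:
    """ICER at a parameter's low and high bound, and the induced span."""

    parameter_id: str
    label: str
    icer_at_low: float | None  # None marks dominance at that bound
    icer_at_high: float | None
    span: float


def default_ranges() -> dict[str, SensitivityRange]:
    """The eight published one-way ranges."""
    ranges = [
        SensitivityRange("AC1", "Annual cost of cART", 192.44, 100.0, 300.0),
        SensitivityRange("AC2", "Annual cost of cART maintenance", 113.40, 50.0, 200.0),
        SensitivityRange("IH", "Number of inpatient hospitalizations (scale)", 1.0, 0.5, 1.5),
        SensitivityRange("HC", "Daily hospitalization cost", 31.48, 15.74, 47.22),
        SensitivityRange("DR", "Discount rate", 0.03, 0.0, 0.06),
        SensitivityRange("CD4", "Average CD4 decline in 6 months", 45.75, 30.65, 62.35),
        SensitivityRange("AC3", "Annual monitoring cost while not yet on cART", 84.76, 0.0, 150.0),
        SensitivityRange("LE", "Remaining life expectancy (scale)", 1.0, 0.85, 1.15),
    ]
    return {r.parameter_id: r for r in ranges}


def _set_ac1(d: dict[str, Any], v: float) -> None:
    d["costs"]["cart_drug_annual"] = v
    d["costs"]["treatment_total_annual"] = v + d["costs"]["cart_maintenance_annual"]


def _set_ac2(d: dict[str, Any], v: float) -> None:
    d["costs"]["cart_maintenance_annual"] = v
    d["costs"]["treatment_total_annual"] = d["costs"]["cart_drug_annual"] + v


def _set_ih(d: dict[str, Any], v: float) -> None:
    d["inpatient"] = {k: rate * v for k, rate in d["inpatient"].items()}


def _set_hc(d: dict[str, Any], v: float) -> None:
    d["costs"]["cost_per_inpatient_day"] = v


def _set_dr(d: dict[str, Any], v: float) -> None:
    d["discount"]["annual_rate"] = v


def _set_cd4(d: dict[str, Any], v: float) -> None:
    dec = d["decline"]
    dec["median_per_period"] = v
    # keep the quartile ordering invariant when the median is pushed to a bound
    dec["q25_per_period"] = min(dec["q25_per_period"], v)
    dec["q75_per_period"] = max(dec["q75_per_period"], v)


def _set_ac3(d: dict[str, Any], v: float) -> None:
    total = d["costs"]["waiting_total_annual"]
    factor = v / total if total > 0 else 0.0
    d["costs"]["waiting_components"] = {
        k: c * factor for k, c in d["costs"]["waiting_components"].items()
    }
    d["costs"]["waiting_total_annual"] = v


def _set_le(d: dict[str, Any], v: float) -> None:
    for a in d["anchors"]:
        a["life_expectancy"] *= v


_SETTERS: dict[str, Callable[[dict[str, Any], float], None]] = {
    "AC1": _set_ac1,
    "AC2": _set_ac2,
    "IH": _set_ih,
    "HC": _set_hc,
    "DR": _set_dr,
    "CD4": _set_cd4,
    "AC3": _set_ac3,
    "LE": _set_le,
}


def perturbed(params: ModelParameters, parameter_id: str, value: float) -> ModelParameters:
    """A copy of ``params`` with one sensitivity parameter set to ``value``."""
    if parameter_id not in _SETTERS:
        raise ValueError(f"unknown sensitivity parameter {parameter_id!r}")
    d = params.to_dict()
    _SETTERS[parameter_id](d, value)
    return parameters_from_dict(d)


def mean_icer(params: ModelParameters) -> float | None:
    """Mean-row ICER of a full cohort run (None under dominance)."""
    return run_base_case(params).mean.icer


def one_way(
    param_id: str,
    ranges: Mapping[str, SensitivityRange] | None = None,
    params: ModelParameters | None = None,
) -> TornadoEntry:
    """Re-run the full model with one parameter at its low, then high bound."""
    ranges = ranges or default_ranges()
    params = params or ModelParameters()
    if param_id not in ranges:
        raise ValueError(f"unknown sensitivity parameter {param_id!r}")
    r = ranges[param_id]
    lo = mean_icer(perturbed(params, param_id, r.low))
    hi = mean_icer(perturbed(params, param_id, r.high))
    span = abs(hi - lo) if (lo is not None and hi is not None) else float("inf")
    return TornadoEntry(r.parameter_id, r.label, lo, hi, span)


def tornado(
    ranges: Mapping[str, SensitivityRange] | None = None,
    params: ModelParameters | None = None,
) -> list[TornadoEntry]:
    """All one-way entries, ordered by descending ICER span."""
    ranges = ranges or default_ranges()
    entries = [one_way(pid, ranges, params) for pid in ranges]
    # id tie-break keeps the ordering independent of input order (IH and HC
    # induce identical spans: both scale the same hospitalization product)
    return sorted(entries, key=lambda e: (-e.span, e.parameter_id))
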