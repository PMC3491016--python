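"""Model inputs and their validation.

Every quantity the decision model consumes — life-expectancy anchors, the
pre-treatment CD4 decline, disability weights, inpatient-day rates, unit
costs, the discount specification and the structural conventions (threshold,
bin range, measurement interval, hospitalization horizon) — lives in one
immutable :class:`ModelParameters` object.  Base-case values are the
published model inputs for the Ugandan setting (2011 USD).

Configuration files are YAML with nested sections mirroring the parameter
blocks; unknown keys are an error (fail loud), omitted keys fall back to the
base case.
"""

from __future__ import annotations

import copy
import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

__all__ = [
    "CD4Stratum",
    "DiscountConvention",
    "LifeExpectancyAnchor",
    "DeclineModel",
    "DisabilityWeights",
    "InpatientRates",
    "CostInputs",
    "DiscountSpec",
    "ModelParameters",
    "ConfigurationError",
    "ValidationError",
    "default_parameters",
    "load_parameters",
    "parameters_from_dict",
]


class ConfigurationError(ValueError):
    """A config source is malformed: unparseable, or carries unknown keys."""


class ValidationError(ValueError):
    """A parameter set violates a model invariant."""


class CD4Stratum(str, enum.Enum):
    """CD4 stratum used by the inpatient-day rates (cells/μL)."""

    MID = "201-350"
    HIGH = ">350"

    @classmethod
    def from_cd4(cls, cd4: float) -> "CD4Stratum":
        # Rates exist only for 201-350 and >350; anything at or below 350
        # (including sensitivity trajectories dipping under 201) uses the
        # 201-350 rates, the closest published stratum.
        return cls.HIGH if cd4 > 350 else cls.MID


class DiscountConvention(str, enum.Enum):
    """How a continuous stream of life-years or costs is discretized."""

    SEMIANNUAL_MIDPERIOD = "semiannual_midperiod"
    ANNUAL_ENDPERIOD = "annual_endperiod"
    CONTINUOUS = "continuous"


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass(frozen=True)
class LifeExpectancyAnchor:
    """(CD4 midpoint, undiscounted life expectancy) anchor pair."""

    cd4_midpoint: float  # cells/μL
    life_expectancy: float  # years

    def __post_init__(self) -> None:
        _require(self.cd4_midpoint > 0, "anchor cd4_midpoint must be > 0")
        _require(self.life_expectancy > 0, "anchor life_expectancy must be > 0")


@dataclass(frozen=True)
class DeclineModel:
    """Pre-treatment CD4 decline per 6-month measurement period, and the
    first-year immune-reconstitution rate once treatment starts."""

    median_per_period: float = 45.75  # cells/μL per period
    q25_per_period: float = 30.65
    q75_per_period: float = 62.35
    period_length: float = 0.5  # years
    reconstitution_rate_year1: float = 114.0  # cells/μL per year

    def __post_init__(self) -> None:
        _require(
            0 < self.q25_per_period <= self.median_per_period <= self.q75_per_period,
            "decline quartiles must satisfy 0 < q25 <= median <= q75",
        )
        _require(self.period_length > 0, "period_length must be > 0")
        _require(
            self.reconstitution_rate_year1 >= 0,
            "reconstitution_rate_year1 must be >= 0",
        )


@dataclass(frozen=True)
class DisabilityWeights:
    """Disability weights: chronic HIV years and the terminal AIDS period."""

    hiv_weight: float = 0.123
    aids_weight: float = 0.5
    aids_years_before_death: float = 1.0

    def __post_init__(self) -> None:
        _require(
            0 <= self.hiv_weight < self.aids_weight <= 1,
            "weights must satisfy 0 <= hiv_weight < aids_weight <= 1",
        )
        _require(
            self.aids_years_before_death >= 0,
            "aids_years_before_death must be >= 0",
        )


@dataclass(frozen=True)
class InpatientRates:
    """Annual inpatient days by CD4 stratum × cART status × OI status."""

    mid_on_with_oi: float = 0.52
    mid_off_with_oi: float = 10.8
    mid_on_without_oi: float = 0.39
    mid_off_without_oi: float = 3.0
    high_on_with_oi: float = 0.37
    high_off_with_oi: float = 5.7
    high_on_without_oi: float = 0.14
    high_off_without_oi: float = 1.9

    def __post_init__(self) -> None:
        for name in (
            "mid_on_with_oi",
            "mid_off_with_oi",
            "mid_on_without_oi",
            "mid_off_without_oi",
            "high_on_with_oi",
            "high_off_with_oi",
            "high_on_without_oi",
            "high_off_without_oi",
        ):
            _require(getattr(self, name) >= 0, f"inpatient rate {name} must be >= 0")
        _require(
            self.mid_off_with_oi >= self.mid_on_with_oi
            and self.mid_off_without_oi >= self.mid_on_without_oi
            and self.high_off_with_oi >= self.high_on_with_oi
            and self.high_off_without_oi >= self.high_on_without_oi,
            "off-cART inpatient rates must be >= on-cART rates per stratum/OI cell",
        )

    def days(self, stratum: CD4Stratum, on_cart: bool) -> float:
        """Total annual inpatient days (with-OI + without-OI) for a cell."""
        prefix = "mid" if stratum is CD4Stratum.MID else "high"
        status = "on" if on_cart else "off"
        return getattr(self, f"{prefix}_{status}_with_oi") + getattr(
            self, f"{prefix}_{status}_without_oi"
        )

    def scaled(self, factor: float) -> "InpatientRates":
        return InpatientRates(
            **{
                k: getattr(self, k) * factor
                for k in self.__dataclass_fields__  # type: ignore[attr-defined]
            }
        )


@dataclass(frozen=True)
class CostInputs:
    """Unit costs, 2011 USD."""

    cart_drug_annual: float = 192.44
    cart_maintenance_annual: float = 113.40
    treatment_total_annual: float = 305.84
    waiting_components: Mapping[str, float] = field(
        default_factory=lambda: {
            "clinic_personnel": 14.32,
            "lab": 35.04,
            "other_medication": 33.72,
            "radiology": 1.68,
        }
    )
    waiting_total_annual: float = 84.76
    cost_per_inpatient_day: float = 31.48

    def __post_init__(self) -> None:
        for name in (
            "cart_drug_annual",
            "cart_maintenance_annual",
            "treatment_total_annual",
            "waiting_total_annual",
            "cost_per_inpatient_day",
        ):
            _require(getattr(self, name) >= 0, f"cost {name} must be >= 0")
        _require(
            all(v >= 0 for v in self.waiting_components.values()),
            "waiting cost components must be >= 0",
        )
        _require(
            abs(
                self.treatment_total_annual
                - (self.cart_drug_annual + self.cart_maintenance_annual)
            )
            < 0.005,
            "treatment_total_annual must equal drug + maintenance to the cent",
        )
        _require(
            abs(self.waiting_total_annual - sum(self.waiting_components.values()))
            < 0.005,
            "waiting_total_annual must equal the sum of its components to the cent",
        )
        object.__setattr__(self, "waiting_components", dict(self.waiting_components))


@dataclass(frozen=True)
class DiscountSpec:
    """Annual discount rate and the stream-discretization convention."""

    annual_rate: float = 0.03
    convention: DiscountConvention = DiscountConvention.SEMIANNUAL_MIDPERIOD

    def __post_init__(self) -> None:
        _require(0 <= self.annual_rate <= 0.20, "annual_rate must be in [0, 0.20]")
        object.__setattr__(self, "convention", DiscountConvention(self.convention))


@dataclass(frozen=True)
class ModelParameters:
    """The complete, validated input set for one model run."""

    anchors: tuple[LifeExpectancyAnchor, ...] = (
        LifeExpectancyAnchor(25.0, 7.9),
        LifeExpectancyAnchor(125.0, 9.6),
        LifeExpectancyAnchor(275.0, 19.3),
    )
    decline: DeclineModel = field(default_factory=DeclineModel)
    dw: DisabilityWeights = field(default_factory=DisabilityWeights)
    inpatient: InpatientRates = field(default_factory=InpatientRates)
    costs: CostInputs = field(default_factory=CostInputs)
    discount: DiscountSpec = field(default_factory=DiscountSpec)
    cd4_threshold: float = 250.0  # cells/μL; initiation when a measurement is strictly below
    cd4_range: tuple[float, float] = (250.0, 350.0)
    measurement_interval: float = 0.5  # years between CD4 tests
    hospitalization_horizon: float = 2.0  # years from model entry
    gdp_per_capita: float = 490.0  # USD, cost-effectiveness threshold unit

    def __post_init__(self) -> None:
        anchors = tuple(
            a if isinstance(a, LifeExpectancyAnchor) else LifeExpectancyAnchor(**a)
            for a in self.anchors
        )
        object.__setattr__(self, "anchors", anchors)
        _require(len(anchors) >= 2, "at least two life-expectancy anchors required")
        for a, b in zip(anchors, anchors[1:]):
            _require(
                a.cd4_midpoint < b.cd4_midpoint and a.life_expectancy < b.life_expectancy,
                "anchors must be strictly increasing in CD4 and life expectancy",
            )
        _require(
            0 <= self.cd4_threshold <= self.cd4_range[0],
            "cd4_threshold must lie in [0, cd4_range low]",
        )
        _require(self.cd4_range[0] < self.cd4_range[1], "cd4_range must be increasing")
        _require(self.measurement_interval > 0, "measurement_interval must be > 0")
        ratio = self.hospitalization_horizon / self.measurement_interval
        _require(
            self.hospitalization_horizon > 0
            and math.isclose(ratio, round(ratio), abs_tol=1e-9),
            "hospitalization_horizon must be a positive multiple of measurement_interval",
        )
        _require(self.gdp_per_capita > 0, "gdp_per_capita must be > 0")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        """Plain-dict snapshot (JSON-safe) of every parameter."""
        return {
            "anchors": [
                {"cd4_midpoint": a.cd4_midpoint, "life_expectancy": a.life_expectancy}
                for a in self.anchors
            ],
            "decline": {
                "median_per_period": self.decline.median_per_period,
                "q25_per_period": self.decline.q25_per_period,
                "q75_per_period": self.decline.q75_per_period,
                "period_length": self.decline.period_length,
                "reconstitution_rate_year1": self.decline.reconstitution_rate_year1,
            },
            "disability": {
                "hiv_weight": self.dw.hiv_weight,
                "aids_weight": self.dw.aids_weight,
                "aids_years_before_death": self.dw.aids_years_before_death,
            },
            "inpatient": {
                k: getattr(self.inpatient, k)
                for k in InpatientRates.__dataclass_fields__
            },
            "costs": {
                "cart_drug_annual": self.costs.cart_drug_annual,
                "cart_maintenance_annual": self.costs.cart_maintenance_annual,
                "treatment_total_annual": self.costs.treatment_total_annual,
                "waiting_components": dict(self.costs.waiting_components),
                "waiting_total_annual": self.costs.waiting_total_annual,
                "cost_per_inpatient_day": self.costs.cost_per_inpatient_day,
            },
            "discount": {
                "annual_rate": self.discount.annual_rate,
                "convention": self.discount.convention.value,
            },
            "model": {
                "cd4_threshold": self.cd4_threshold,
                "cd4_range": list(self.cd4_range),
                "measurement_interval": self.measurement_interval,
                "hospitalization_horizon": self.hospitalization_horizon,
                "gdp_per_capita": self.gdp_per_capita,
            },
        }

    def to_json(self, **kwargs: Any) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def default_parameters() -> ModelParameters:
    """The base-case parameter set (all published input values)."""
    return ModelParameters()


# -- config loading -------------------------------------------------------


def _merge(base: dict[str, Any], override: Mapping[str, Any], path: str = "") -> None:
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigurationError(f"unknown configuration key: {here!r}")
        if isinstance(base[key], dict):
            if not isinstance(value, Mapping):
                raise ConfigurationError(f"key {here!r} expects a mapping")
            _merge(base[key], value, here)
        else:
            base[key] = value


def _from_dict(d: Mapping[str, Any]) -> ModelParameters:
    anchors = tuple(
        LifeExpectancyAnchor(float(a["cd4_midpoint"]), float(a["life_expectancy"]))
        for a in d["anchors"]
    )
    model = d["model"]
    return ModelParameters(
        anchors=anchors,
        decline=DeclineModel(**d["decline"]),
        dw=DisabilityWeights(**d["disability"]),
        inpatient=InpatientRates(**d["inpatient"]),
        costs=CostInputs(**d["costs"]),
        discount=DiscountSpec(**d["discount"]),
        cd4_threshold=float(model["cd4_threshold"]),
        cd4_range=tuple(float(x) for x in model["cd4_range"]),
        measurement_interval=float(model["measurement_interval"]),
        hospitalization_horizon=float(model["hospitalization_horizon"]),
        gdp_per_capita=float(model["gdp_per_capita"]),
    )


def parameters_from_dict(d: Mapping[str, Any]) -> ModelParameters:
    """Rebuild a :class:`ModelParameters` from a :meth:`to_dict` snapshot."""
    return _from_dict(d)


def _autocomplete_totals(base: dict[str, Any], override: Mapping[str, Any]) -> None:
    """Recompute cost totals when components are overridden without them.

    The to-the-cent consistency invariants (treatment total = drug +
    maintenance; waiting total = sum of components) would otherwise force
    every override of a component to restate the total.
    """
    costs = override.get("costs")
    if not isinstance(costs, Mapping):
        return
    if (
        "cart_drug_annual" in costs or "cart_maintenance_annual" in costs
    ) and "treatment_total_annual" not in costs:
        base["costs"]["treatment_total_annual"] = (
            base["costs"]["cart_drug_annual"] + base["costs"]["cart_maintenance_annual"]
        )
    if "waiting_components" in costs and "waiting_total_annual" not in costs:
        base["costs"]["waiting_total_annual"] = sum(
            base["costs"]["waiting_components"].values()
        )


def load_parameters(
    source: str | Path | Mapping[str, Any] | None = None,
) -> ModelParameters:
    """Load parameters from a YAML file/text or mapping of overrides.

    Omitted keys take the base-case value; unknown keys raise
    :class:`ConfigurationError`; invariant violations raise
    :class:`ValidationError`.  ``None`` (or an empty mapping) returns the
    base case.
    """
    if source is None:
        override: Mapping[str, Any] = {}
    elif isinstance(source, Mapping):
        override = source
    else:
        if isinstance(source, Path) or (
            isinstance(source, str) and "\n" not in source and Path(source).exists()
        ):
            text = Path(source).read_text()
        else:
            text = str(source)
        try:
            parsed = yaml.safe_load(text)
        except yaml.YAMLError as exc:  # pragma: no cover - message passthrough
            raise ConfigurationError(f"config does not parse as YAML: {exc}") from exc
        if parsed is None:
            parsed = {}
        if not isinstance(parsed, Mapping):
            raise ConfigurationError("config root must be a mapping")
        override = parsed

    base = default_parameters().to_dict()
    # anchors override replaces the whole list
    override = dict(override)
    anchors_override: Sequence[Any] | None = override.pop("anchors", None)
    _merge(base, override)
    _autocomplete_totals(base, override)
    if anchors_override is not None:
        base["anchors"] = copy.deepcopy(list(anchors_override))
    return _from_dict(base)
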