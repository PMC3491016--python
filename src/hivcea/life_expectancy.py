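"""Life expectancy by baseline CD4 count, discounting, and disability weighting.

Undiscounted life expectancy at cART initiation is piecewise-linear in the
baseline CD4 count, interpolated between published anchor points
(CD4 25 → 7.9 yr, CD4 125 → 9.6 yr, CD4 275 → 19.3 yr).  Above the top
anchor the last segment's slope is extended linearly (no cap); below the
bottom anchor the value is clamped, which keeps the function positive.

Life is treated as a continuous stream; ``discount_years`` converts a stream
of length L starting at time ``delay`` into present value at model entry
under one of three conventions:

* ``semiannual_midperiod`` (default) — 6-month slices, each slice of size s
  contributing ``s * (1+r)^(-t_mid)``; a fractional terminal slice is
  discounted at its own midpoint.  This matches the model's 6-month step.
* ``annual_endperiod`` — 1-year slices discounted at slice end (the common
  spreadsheet annuity form).
* ``continuous`` — the closed form ``((1+r)^-d - (1+r)^-(d+L)) / ln(1+r)``.

``disability_weighted_years`` applies the chronic-HIV weight to all but the
terminal AIDS period and the AIDS weight to that terminal period, on the
discounted stream; scenario YLD differences come from these masses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import DisabilityWeights, DiscountConvention, DiscountSpec, ModelParameters

__all__ = [
    "LifeYearsProfile",
    "interpolate_life_expectancy",
    "discount_factor",
    "discount_years",
    "disability_weighted_years",
    "life_years_profile",
    "life_expectancy_table",
]


@dataclass(frozen=True)
class LifeYearsProfile:
    """Undiscounted, discounted, and disability-weighted-discounted years of
    one scenario's remaining life."""

    undiscounted: float
    discounted: float
    disability_weighted_discounted: float

    def __post_init__(self) -> None:
        if not (0 <= self.discounted <= self.undiscounted + 1e-9):
            raise ValueError("discounted years must lie in [0, undiscounted]")
        if not (
            0 <= self.disability_weighted_discounted <= self.discounted + 1e-9
        ):
            raise ValueError("weighted years must lie in [0, discounted]")


def interpolate_life_expectancy(
    cd4: float, anchors: tuple | None = None, params: ModelParameters | None = None
) -> float:
    """Undiscounted life expectancy (years) at cART initiation CD4 ``cd4``.

    Piecewise-linear between anchors; linear extrapolation above the top
    anchor; clamped at the bottom anchor's value below it.
    """
    if anchors is None:
        anchors = (params or ModelParameters()).anchors
    if cd4 <= 0:
        raise ValueError(f"cd4 must be positive, got {cd4}")
    xs = np.array([a.cd4_midpoint for a in anchors], dtype=float)
    ys = np.array([a.life_expectancy for a in anchors], dtype=float)
    if cd4 <= xs[0]:
        return float(ys[0])
    if cd4 >= xs[-1]:
        slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
        return float(ys[-1] + slope * (cd4 - xs[-1]))
    return float(np.interp(cd4, xs, ys))


def discount_factor(t: float, rate: float) -> float:
    """Point present-value factor ``(1+rate)^(-t)``."""
    return (1.0 + rate) ** (-t)


def discount_years(length: float, delay: float, spec: DiscountSpec) -> float:
    """Present value at model entry of a unit-rate stream over
    ``[delay, delay + length]`` years."""
    if length < 0 or delay < 0:
        raise ValueError("length and delay must be non-negative")
    if length == 0:
        return 0.0
    r = spec.annual_rate
    if r == 0:
        return float(length)
    conv = spec.convention
    if conv is DiscountConvention.CONTINUOUS:
        lam = math.log1p(r)
        return (discount_factor(delay, r) - discount_factor(delay + length, r)) / lam
    step = 0.5 if conv is DiscountConvention.SEMIANNUAL_MIDPERIOD else 1.0
    n_full = int(length / step + 1e-12)
    starts = delay + step * np.arange(n_full)
    if conv is DiscountConvention.SEMIANNUAL_MIDPERIOD:
        total = float(np.sum(step * (1.0 + r) ** (-(starts + step / 2.0))))
        rem = length - n_full * step
        if rem > 1e-12:
            t_mid = delay + n_full * step + rem / 2.0
            total += rem * discount_factor(t_mid, r)
    else:
        total = float(np.sum(step * (1.0 + r) ** (-(starts + step))))
        rem = length - n_full * step
        if rem > 1e-12:
            total += rem * discount_factor(delay + n_full * step + rem, r)
    return total


def disability_weighted_years(
    length: float,
    delay: float,
    dw: DisabilityWeights,
    spec: DiscountSpec,
) -> float:
    """Disability-weighted discounted years of a life stream.

    The terminal ``aids_years_before_death`` of the stream carry the AIDS
    weight; everything before carries the chronic-HIV weight.
    """
    if length < dw.aids_years_before_death:
        raise ValueError(
            "life stream shorter than the terminal AIDS period "
            f"({length} < {dw.aids_years_before_death})"
        )
    hiv_span = length - dw.aids_years_before_death
    hiv_part = dw.hiv_weight * discount_years(hiv_span, delay, spec)
    aids_part = dw.aids_weight * discount_years(
        dw.aids_years_before_death, delay + hiv_span, spec
    )
    return hiv_part + aids_part


def life_years_profile(
    length: float, delay: float, params: ModelParameters
) -> LifeYearsProfile:
    """Bundle the three year-measures of a stream ``[delay, delay+length]``.

    ``undiscounted`` includes the delay when the subject is alive during it —
    callers pass the full lifespan from entry (delay = 0) for scenario life
    expectancies, or the on-treatment stream (delay = wait) for costs.
    """
    return LifeYearsProfile(
        undiscounted=length,
        discounted=discount_years(length, delay, params.discount),
        disability_weighted_discounted=disability_weighted_years(
            length, delay, params.dw, params.discount
        ),
    )


def life_expectancy_table(
    params: ModelParameters, cd4_lo: int = 50, cd4_hi: int = 350, step: int = 10
) -> "list[tuple[float, float]]":
    """(CD4, life expectancy) pairs over a CD4 grid — the curve the model
    draws through the published anchors."""
    return [
        (float(c), interpolate_life_expectancy(float(c), params.anchors))
        for c in range(cd4_lo, cd4_hi + 1, step)
    ]
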