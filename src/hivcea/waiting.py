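"""Pre-treatment waiting model and on-treatment CD4 trajectory.

Under the deferred strategy a patient entering with CD4 at or above the
treatment threshold is re-measured every 6 months while the count falls by a
fixed amount per period; therapy starts at the first measurement strictly
below the threshold.  A measurement of exactly the threshold keeps waiting —
this strictness is what produces the 18-month maximum wait for the top bin
(345 → 299.25 → 253.5 → 207.75).

After initiation, immune reconstitution raises the CD4 count linearly for
one year (114 cells/μL per year at base case) and holds it constant after
that; downstream only the hospitalization stratum (≤350 vs >350) reads it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .params import DeclineModel, ModelParameters

__all__ = [
    "CD4Bin",
    "WaitOutcome",
    "default_bins",
    "wait_to_initiation",
    "cohort_wait_summary",
    "decline_at_percentile",
    "on_treatment_cd4",
]


@dataclass(frozen=True)
class CD4Bin:
    """One 10-cell baseline CD4 stratum, e.g. 250–259 cells/μL."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError("bin low must be < high")

    @property
    def midpoint(self) -> float:
        # integer center low+5 of the 10-cell bin (255 for 250-259)
        return self.low + 5.0

    @property
    def label(self) -> str:
        return f"{self.low:.0f}-{self.high:.0f}"


def default_bins(params: ModelParameters | None = None) -> list[CD4Bin]:
    """The ten 10-cell bins partitioning the 250–350 entry range."""
    lo, hi = (params.cd4_range if params else (250.0, 350.0))
    lows = np.arange(lo, hi, 10.0)
    bins = [CD4Bin(low, low + 9.0) for low in lows[:-1]]
    bins.append(CD4Bin(lows[-1], hi))  # top bin 340-350 closes the range
    return bins


@dataclass(frozen=True)
class WaitOutcome:
    """Result of the waiting process for one baseline CD4 count."""

    periods_waited: int
    wait_years: float
    cd4_at_initiation: float
    cd4_trajectory: tuple[tuple[float, float], ...]  # (time yr, cd4) at measurements


def wait_to_initiation(
    baseline_cd4: float,
    decline_per_period: float,
    threshold: float,
    period_length: float = 0.5,
) -> WaitOutcome:
    """Wait in fixed periods until the first measurement strictly below the
    threshold.

    A patient at or above the threshold at entry waits at least one full
    period (the entry measurement itself cannot trigger initiation); one
    already below it starts immediately.  Trajectory CD4 values are floored
    at zero.
    """
    if decline_per_period <= 0:
        raise ValueError("decline_per_period must be > 0")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    trajectory = [(0.0, max(baseline_cd4, 0.0))]
    k = 0
    cd4 = baseline_cd4
    while cd4 >= threshold:
        k += 1
        cd4 = baseline_cd4 - k * decline_per_period
        trajectory.append((k * period_length, max(cd4, 0.0)))
    return WaitOutcome(
        periods_waited=k,
        wait_years=k * period_length,
        cd4_at_initiation=max(cd4, 0.0),
        cd4_trajectory=tuple(trajectory),
    )


def decline_at_percentile(
    decline: DeclineModel, which: Literal["q25", "median", "q75"]
) -> float:
    """Per-period CD4 decline at one of the three published percentiles."""
    try:
        return {
            "q25": decline.q25_per_period,
            "median": decline.median_per_period,
            "q75": decline.q75_per_period,
        }[which]
    except KeyError:
        raise ValueError(f"unknown decline percentile {which!r}") from None


def on_treatment_cd4(
    cd4_start: float, t_since_initiation: float, reconstitution_rate: float
) -> float:
    """CD4 count ``t`` years after initiation: linear first-year gain, then
    constant."""
    if t_since_initiation < 0:
        raise ValueError("t_since_initiation must be >= 0")
    return cd4_start + reconstitution_rate * min(t_since_initiation, 1.0)


def cohort_wait_summary(
    bins: Sequence[CD4Bin],
    decline_per_period: float,
    threshold: float = 250.0,
    period_length: float = 0.5,
) -> dict:
    """Waiting outcomes across bins plus order statistics of the start CD4.

    The median is the mean of the two central order statistics (5th/6th of
    ten bins at base case).
    """
    if not bins:
        raise ValueError("bins must be nonempty")
    outcomes = {
        b.label: wait_to_initiation(b.midpoint, decline_per_period, threshold, period_length)
        for b in bins
    }
    waits_months = [o.wait_years * 12.0 for o in outcomes.values()]
    starts = np.array([o.cd4_at_initiation for o in outcomes.values()])
    q25, q75 = np.percentile(starts, [25, 75])
    return {
        "outcomes": outcomes,
        "wait_range_months": (min(waits_months), max(waits_months)),
        "start_cd4": starts.tolist(),
        "median_start_cd4": float(np.median(starts)),
        "start_cd4_iqr": (float(q25), float(q75)),
    }
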