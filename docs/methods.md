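# Methods

## Model structure

The model is a deterministic decision-analytic comparison of two cART
initiation strategies for a cohort entering care with baseline CD4 between
250 and 350 cells/μL, evaluated per 10-cell baseline bin and rolled up as
an unweighted bin average (the entry distribution is uniform). It is not a
survival model: remaining life expectancy at initiation is a scalar
function of the CD4 count at initiation, and all health and cost streams
are deterministic functions of that lifespan.

**Life expectancy.** *L*(CD4) is piecewise-linear through the anchors
(25, 7.9 yr), (125, 9.6 yr), (275, 19.3 yr). Between 125 and 275 the slope
is 9.7/150 ≈ 0.06467 yr per cell. Above 275 the last segment's slope is
extended with no cap — the published top-bin value (23.85 yr at CD4 345)
requires this; our extrapolation gives 23.83. Below 25 the value is
clamped at 7.9 yr rather than extrapolated toward zero; the clamp also
covers the degenerate case of a trajectory floored at CD4 = 0. Bin
"midpoints" are the integer centres low + 5 (255 for 250–259), which
reproduces the published 18.01 yr exactly.

**Waiting rule (Scenario B).** Patients are measured at entry (t = 0) and
every 6 months; CD4 falls by a fixed per-period amount (median
45.75 cells/μL, quartiles 30.65/62.35 selectable). Initiation occurs at the
first measurement *strictly below* 250 cells/μL; a reading of exactly 250
keeps waiting, and a patient at or above threshold at entry waits at least
one period. This strictness is load-bearing: 345 → 299.25 → 253.5 → 207.75
produces the 18-month maximum wait. Scenario B's lifespan is the wait plus
*L*(CD4 at initiation). Base-case waits across the ten bins are
{6×5, 12×4, 18×1} months and the median start CD4 is 226.375 → 226.

**Discounting.** All streams are discounted at 3 %/yr. The default
convention is *semiannual mid-period*: a stream of length *s* starting at
delay *d* is split into 6-month slices, each contributing
s·(1+r)^(−t_mid); a fractional terminal slice is discounted at its own
midpoint. The original spreadsheet's convention is unrecoverable, so the
convention is configurable (`annual_endperiod`, `continuous` closed-form
annuity); a calibration test confirms the semiannual mid-period form
matches the published discounted life expectancies best (all three
Scenario A values within 0.45 %). Hospitalization intervals are discounted
with point factors (1+r)^(−t_mid) at interval midpoints under every
convention.

**DALYs.** YLL is the difference in discounted lifespans (A − B). YLD is
the signed difference of disability-weighted discounted years (B − A): the
final `aids_years_before_death` (1 yr) of each lifespan carries weight 0.5,
all earlier years 0.123. The HIV weight follows the sourced input table
(0.123), not the 0.1 that appears once in prose; the published mean DALY
(1.98) is only consistent with 0.123. YLD is negative on average (−0.25):
the longer-lived immediate starter accrues more disability mass. DALYs
averted = YLL + YLD.

**Costs** (2011 USD, discounted to entry).

* On treatment: $305.84/yr (drug $192.44 + maintenance $113.40) × the
  discounted life-years lived *on treatment* (delay = wait).
* While waiting: $84.76/yr × discounted waiting years.
* Hospitalization: a fixed window of four 6-month intervals **from model
  entry for both scenarios** — not from each patient's initiation. This is
  the only reading that reproduces the published deferred-scenario
  hospitalization costs, because the waiting patient's off-cART admissions
  (13.8 days/yr in the 201–350 stratum vs 0.91 on cART) fall inside the
  same window. Each interval's (stratum, cART) state is read at the
  interval start, with on-treatment CD4 reconstituting at 114 cells/μL
  over the first year and constant after (only the ≤350 / >350 stratum
  boundary matters). Days/yr × $31.48/day × 0.5 yr, discounted at the
  interval midpoint.

The ICER of an aggregate row is the ratio of that row's aggregates (mean
incremental cost ÷ mean DALYs averted), not a mean of per-bin ratios; it is
reported to the dollar, not rounded to $10. When a perturbation makes DALYs
averted or incremental cost non-positive, the row reports a
dominant/dominated label instead of a signed ratio. Classification follows
the WHO GDP-multiple rule with strict inequalities: ICER < 1× GDP ($490)
"highly cost-effective", < 3× "cost-effective".

## One documented deviation

The published top-bin (340–350) deferred-scenario cells — 17.38 yr
undiscounted, 13.54 discounted, $565 hospitalization, and the derived YLL
3.49 / DALY 3.10 / ICER $262 — do not follow from the stated waiting rule,
which gives 1.5 + *L*(207.75) ≈ 16.45 yr (discounted ≈ 13.03). No
defensible variant of the rule (rounding, one fewer period, non-strict
threshold) yields 17.38 without breaking the 18-month maximum wait that the
same source states. The reconstruction is frozen in a regression test; the
published cells are knowingly not reproduced. All other published cells
replicate within 0.5 % (life expectancy, DALY, treatment costs) or well
within 15 % (the two-year hospitalization rows, whose printed values sit
between interval- and year-granularity readings of the window rule).

## Sensitivity analysis

Eight parameters are varied one at a time over their published bounds, the
full model re-run at each bound: cART drug cost $100–$300; maintenance
$50–$200; inpatient-day rates ±50 % (one factor on all eight rates); bed-day
cost $15.74–$47.22; discount rate 0–6 %; per-period decline 30.65–62.35
(when the median is pushed to a bound the quartiles are clipped to keep
their ordering); waiting monitoring $0–$150 (components scaled
proportionally); anchor life expectancies ±15 % (one factor on all
anchors). Entries are sorted by ICER span with a parameter-id tie-break:
the inpatient-rate scale and the bed-day cost induce *identical* spans
(both scale the same days × price product by the same factors), so the
tie-break keeps the tornado ordering deterministic.

## Synthetic cohort and microsimulation

The microsimulation generates the individuals the cohort model abstracts
over: baseline CD4 ~ Uniform(250, 350) (continuous, to expose the bin
model's discretization error; a bin-midpoint mode exists for exact
equivalence tests) and a per-patient per-period decline drawn from either

* a lognormal with log-median ln(45.75) and
  log-σ = (ln 62.35 − ln 30.65)/(2 Φ⁻¹(0.75)) ≈ 0.527 — the median and the
  quartile *ratio* match the printed values exactly; the individual
  quartiles are 32.1/65.3 rather than 30.65/62.35, because a two-parameter
  lognormal centred on the printed median cannot hit both printed quartiles
  (45.75 is not their geometric mean); or
* a three-point distribution on (30.65, 45.75, 62.35) with weights
  (¼, ½, ¼), the only three rates the deterministic analysis evaluates.

Each patient runs through the identical deterministic pipeline; the module
reports means, Monte-Carlo standard errors, and the ratio-of-means ICER.
With bin-midpoint baselines and a degenerate decline the microsimulation
equals the deterministic mean row to machine precision (the core oracle
test); standard errors scale as 1/√n (checked at n = 1k/4k/16k). Default
validation runs use 10k–20k patients (< 5 s); the heterogeneous cohort's
mean DALYs averted sits ~8 % above the bin model's 1.98, driven by the
convexity of waiting time in the decline rate — slow decliners wait much
longer. The generator deliberately omits measurement noise on CD4 tests,
correlation between baseline CD4 and decline (none is published), treatment
failure, and adherence effects, so its agreement with the cohort engine
validates the arithmetic, not the epidemiology.

## Numerical and interface choices

All parameters live in one immutable, validated object; YAML overrides are
merged over the base case with unknown keys rejected, and cost totals are
recomputed when components are overridden alone (the totals must match
their components to the cent). Random draws use one explicit NumPy
generator per run seeded from the config; repeated runs are byte-identical
(checksummed in the run manifest). Costs render to whole dollars, years to
two decimals; the underlying CSV/JSON carry full precision.

## Limitations

Scalar life expectancy (no survival curves or uncertainty around the
anchors); no HIV-transmission benefit, so cost-effectiveness is
underestimated; no second-line therapy, treatment failure or adherence
effects; costs are 2011 USD with no inflation adjustment; hospitalization
inputs cover only two CD4 strata, and trajectories below 201 cells/μL reuse
the 201–350 rates; probabilistic sensitivity analysis is out of scope.
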