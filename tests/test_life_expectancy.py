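"""Life-expectancy interpolation, discounting, and disability weighting."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hivcea import (
    DisabilityWeights,
    DiscountConvention,
    DiscountSpec,
    disability_weighted_years,
    discount_years,
    interpolate_life_expectancy,
    life_expectancy_table,
)

SLOPE = (19.3 - 9.6) / 150.0  # years per CD4 cell between the 125 and 275 anchors


class TestInterpolation:
    @pytest.mark.parametrize(
        "cd4, expected",
        [
            (275.0, 19.30),  # top anchor
            (125.0, 9.60),  # middle anchor
            (255.0, 18.01),  # lowest bin midpoint
            (345.0, 23.83),  # highest bin midpoint, extrapolated above 275
            (209.25, 9.6 + 84.25 * SLOPE),  # post-wait start CD4 of lowest bin
        ],
    )
    def test_anchor_interpolation(self, params, cd4, expected):
        assert interpolate_life_expectancy(cd4, params.anchors) == pytest.approx(
            expected, abs=0.005
        )

    def test_exactly_linear_between_mid_anchors(self, params):
        le = lambda c: interpolate_life_expectancy(c, params.anchors)
        for c in (130.0, 200.0, 274.0):
            assert le(c) == pytest.approx(9.6 + (c - 125.0) * SLOPE, abs=1e-9)
        assert SLOPE == pytest.approx(0.0646667, abs=5e-7)

    def test_clamped_below_bottom_anchor(self, params):
        assert interpolate_life_expectancy(10.0, params.anchors) == 7.9

    def test_nonpositive_cd4_rejected(self, params):
        with pytest.raises(ValueError):
            interpolate_life_expectancy(0.0, params.anchors)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        lo=st.floats(min_value=1.0, max_value=500.0),
        hi=st.floats(min_value=1.0, max_value=500.0),
    )
    def test_monotone_nondecreasing_in_cd4(self, params, lo, hi):
        lo, hi = sorted((lo, hi))
        assert interpolate_life_expectancy(lo, params.anchors) <= (
            interpolate_life_expectancy(hi, params.anchors) + 1e-12
        )

    def test_export_table_spans_50_to_350(self, params):
        table = life_expectancy_table(params)
        assert table[0][0] == 50.0 and table[-1][0] == 350.0
        les = [v for _, v in table]
        assert les == sorted(les)


SEMI = DiscountSpec(0.03, DiscountConvention.SEMIANNUAL_MIDPERIOD)
CONT = DiscountSpec(0.03, DiscountConvention.CONTINUOUS)
ANNUAL = DiscountSpec(0.03, DiscountConvention.ANNUAL_ENDPERIOD)


class TestDiscounting:
    def test_identity_at_zero_rate(self):
        spec = DiscountSpec(0.0)
        for length in (0.0, 1.0, 15.51, 20.93):
            assert discount_years(length, 0.0, spec) == pytest.approx(length)

    def test_published_discounted_life_expectancies(self):
        # undiscounted rows pair with discounted rows of the same table
        assert discount_years(20.93, 0.0, SEMI) == pytest.approx(15.51, rel=0.01)
        assert discount_years(18.01, 0.0, SEMI) == pytest.approx(13.91, rel=0.01)

    def test_continuous_closed_form_annuity(self):
        lam = math.log(1.03)
        expected = (1.0 - math.exp(-lam)) / lam
        assert discount_years(1.0, 0.0, CONT) == pytest.approx(expected, abs=1e-12)

    def test_midperiod_sum_converges_to_continuous_as_period_shrinks(self):
        # hand-built mid-period Riemann sums against the closed-form annuity
        lam, r, L = math.log(1.03), 0.03, 7.5
        closed = (1.0 - (1 + r) ** (-L)) / lam
        errors = []
        for step in (0.5, 0.05, 0.005):
            n = round(L / step)
            approx = sum(step * (1 + r) ** (-(i + 0.5) * step) for i in range(n))
            errors.append(abs(approx - closed))
        assert errors[0] > errors[1] > errors[2]
        assert discount_years(L, 0.0, SEMI) == pytest.approx(closed, rel=0.01)

    @pytest.mark.parametrize("length", [0.5, 1.0, 12.25, 30.0])
    def test_semiannual_within_1pct_of_continuous(self, length):
        assert discount_years(length, 0.0, SEMI) == pytest.approx(
            discount_years(length, 0.0, CONT), rel=0.01
        )

    def test_monotone_decreasing_in_rate(self):
        for conv in DiscountConvention:
            vals = [
                discount_years(17.0, 0.0, DiscountSpec(r, conv))
                for r in (0.0, 0.03, 0.06)
            ]
            assert vals[0] > vals[1] > vals[2]

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        length=st.floats(min_value=0.0, max_value=40.0),
        delay=st.sampled_from([0.0, 0.5, 1.0, 1.5, 3.0]),
    )
    def test_delay_factorizes_for_separable_kernels(self, length, delay):
        # PV(L, d) = (1+r)^-d * PV(L, 0) when d is a period multiple
        for spec in (SEMI, CONT):
            lhs = discount_years(length, delay, spec)
            rhs = 1.03 ** (-delay) * discount_years(length, 0.0, spec)
            assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-12)

    def test_monotone_decreasing_in_delay(self):
        pv = [discount_years(10.0, d, SEMI) for d in (0.0, 0.5, 1.0, 2.0)]
        assert pv == sorted(pv, reverse=True)

    def test_negative_arguments_rejected(self):
        with pytest.raises(ValueError):
            discount_years(-1.0, 0.0, SEMI)
        with pytest.raises(ValueError):
            discount_years(1.0, -0.5, SEMI)


class TestDisabilityWeighting:
    DW = DisabilityWeights()

    def test_single_terminal_aids_year_undiscounted(self):
        assert disability_weighted_years(1.0, 0.0, self.DW, DiscountSpec(0.0)) == 0.5

    def test_one_hiv_year_plus_terminal_year(self):
        got = disability_weighted_years(2.0, 0.0, self.DW, DiscountSpec(0.0))
        assert got == pytest.approx(0.123 + 0.5)

    def test_shorter_than_terminal_period_rejected(self):
        with pytest.raises(ValueError):
            disability_weighted_years(0.5, 0.0, self.DW, SEMI)

    def test_weighted_mass_bounded_by_discounted_years(self):
        for length in (1.0, 5.5, 16.96):
            mass = disability_weighted_years(length, 0.0, self.DW, SEMI)
            disc = discount_years(length, 0.0, SEMI)
            assert 0 < mass <= disc
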