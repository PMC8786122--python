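"""Closed-form curve properties, checked against brute-force Monte Carlo."""

import datetime as dt
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import norm

import colonycensus as cc
from colonycensus.model_core import OutsideCensusWindowError


def year_params_strategy():
    return st.builds(
        cc.YearParams,
        N=st.floats(10.0, 1e5),
        a_mean=st.floats(30.0, 60.0),
        a_sd=st.floats(2.0, 20.0),
        corr=st.floats(-0.9, 0.9),
        tenure_mean=st.floats(10.0, 45.0),
        tenure_cv=st.floats(0.0, 0.4),
    )


# ---------------------------------------------------------------------------
# season-day calendar
# ---------------------------------------------------------------------------

class TestSeasonDay:
    def test_mid_january_convention(self):
        assert cc.to_season_day(dt.date(2018, 1, 14)) == (2018, 45)
        assert cc.to_season_day(dt.date(2017, 12, 1)) == (2018, 1)

    @given(
        season=st.integers(1970, 2030),
        day=st.integers(1, 120),
    )
    def test_round_trip_is_lossless_including_leap_years(self, season, day):
        date = cc.from_season_day(season, day)
        assert cc.to_season_day(date) == (season, day)

    def test_leap_season_has_extra_february_day(self):
        # season 2020 contains Feb 2020: day 91 is 29 Feb, not 1 Mar
        assert cc.from_season_day(2020, 91) == dt.date(2020, 2, 29)
        assert cc.from_season_day(2019, 91) == dt.date(2019, 3, 1)

    def test_out_of_window_date_rejected(self):
        with pytest.raises(ValueError, match="outside the modeling window"):
            cc.to_season_day(dt.date(2018, 6, 1))


# ---------------------------------------------------------------------------
# parameter validation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "field,value",
    [("N", 0.0), ("N", -5.0), ("a_sd", 0.0), ("tenure_mean", -1.0),
     ("tenure_cv", -0.1), ("corr", 1.0), ("corr", -1.0)],
)
def test_invalid_parameters_name_the_offending_field(field, value):
    kwargs = dict(N=1000.0, a_mean=45.0, a_sd=10.0, corr=0.0,
                  tenure_mean=31.06, tenure_cv=0.1212)
    kwargs[field] = value
    with pytest.raises(ValueError, match=field):
        cc.YearParams(**kwargs)


# ---------------------------------------------------------------------------
# cumulative arrival / departure
# ---------------------------------------------------------------------------

class TestCumulativeCurves:
    def test_half_population_arrived_at_mean_arrival(self, default_params):
        assert cc.cumulative_arrival(45.0, default_params) == pytest.approx(500.0)

    def test_cdf_limits(self, default_params):
        assert cc.cumulative_arrival(-1e3, default_params) == pytest.approx(0.0, abs=1e-9)
        assert cc.cumulative_arrival(1e3, default_params) == pytest.approx(1000.0)
        assert cc.cumulative_departure(1e3, default_params) == pytest.approx(1000.0)

    def test_arrival_matches_monte_carlo_fraction(self, default_params):
        # oracle: fraction of 1e6 Gaussian arrival draws at or before day 55
        rng = np.random.default_rng(2024)
        draws = rng.normal(45.0, 10.0, size=1_000_000)
        mc = 1000.0 * np.mean(draws <= 55.0)
        closed = cc.cumulative_arrival(55.0, default_params)
        assert closed == pytest.approx(1000.0 * norm.cdf(1.0), abs=0.1)
        assert closed == pytest.approx(mc, abs=3 * 1000.0 * 0.5 / math.sqrt(1e6) * 2)

    def test_departure_matches_bivariate_monte_carlo(self, default_params):
        # oracle: arrival + tenure over 1e6 joint draws; median at a+d
        p = default_params
        rng = np.random.default_rng(7)
        ts = p.tenure_cv * p.tenure_mean
        draws = rng.multivariate_normal(
            [p.a_mean, p.tenure_mean],
            [[p.a_sd**2, 0.0], [0.0, ts**2]],
            size=1_000_000,
        )
        dep = draws.sum(axis=1)
        t = p.a_mean + p.tenure_mean
        mc = 1000.0 * np.mean(dep <= t)
        closed = cc.cumulative_departure(t, p)
        assert closed == pytest.approx(500.0, abs=1e-6)
        assert mc == pytest.approx(closed, abs=3 * 1000.0 * 0.5 / math.sqrt(1e6) * 2)

    def test_zero_cv_departure_is_shifted_arrival(self, fixed_tenure_params):
        p = fixed_tenure_params
        t = np.linspace(10, 110, 41)
        np.testing.assert_allclose(
            cc.cumulative_departure(t, p),
            cc.cumulative_arrival(t - p.tenure_mean, p),
            rtol=1e-12,
        )

    @given(p=year_params_strategy())
    def test_monotone_and_ordered(self, p):
        t = np.linspace(1, 120, 240)
        a = cc.cumulative_arrival(t, p)
        d = cc.cumulative_departure(t, p)
        assert np.all(np.diff(a) >= 0)
        assert np.all(np.diff(d) >= 0)
        # departures trail arrivals up to the (negligible) negative-tenure mass
        eps = p.N * norm.cdf(-1.0 / p.tenure_cv) if p.tenure_cv > 0 else 0.0
        assert np.all(d <= a + eps + 1e-9 * p.N)


# ---------------------------------------------------------------------------
# census curve
# ---------------------------------------------------------------------------

class TestCensusCurve:
    @given(p=year_params_strategy())
    def test_census_is_arrivals_minus_departures(self, p):
        curve = cc.census_curve(np.arange(1, 121), p)
        np.testing.assert_allclose(
            curve.census, curve.arrivals_cum - curve.departures_cum
        )
        # untruncated tenures allow a dip bounded by the negative-tenure mass
        mass = norm.cdf(-1.0 / p.tenure_cv) if p.tenure_cv > 0 else 0.0
        assert np.all(curve.census >= -(mass + 1e-9) * p.N)

    def test_vanishes_far_from_the_season(self, default_params):
        p = default_params
        far = p.a_mean + 8 * (p.a_sd + p.tenure_mean)
        assert cc.census(far, p) <= 1e-6 * p.N
        assert cc.census(p.a_mean - 8 * (p.a_sd + p.tenure_mean), p) <= 1e-6 * p.N

    def test_symmetric_maximum_closed_form(self, fixed_tenure_params):
        p = fixed_tenure_params
        t = p.a_mean + p.tenure_mean / 2
        expected = p.N * (2 * norm.cdf(p.tenure_mean / (2 * p.a_sd)) - 1)
        assert cc.census(t, p) == pytest.approx(expected, rel=1e-12)

    def test_grid_must_increase(self, default_params):
        with pytest.raises(ValueError, match="strictly increasing"):
            cc.census_curve([3, 2, 1], default_params)


# ---------------------------------------------------------------------------
# peak date
# ---------------------------------------------------------------------------

class TestPeakDate:
    def test_fixed_tenure_peak_is_midpoint(self, fixed_tenure_params):
        p = fixed_tenure_params
        assert cc.peak_date(p) == pytest.approx(p.a_mean + p.tenure_mean / 2, abs=1e-6)

    def test_matches_exhaustive_fine_grid(self, default_params):
        # oracle: exhaustive 0.001-day grid search of the closed form
        p = default_params
        grid = np.arange(1.0, 120.0, 0.001)
        oracle = grid[np.argmax(cc.census(grid, p))]
        assert cc.peak_date(p) == pytest.approx(oracle, abs=2e-3)
        assert cc.peak_date(p) - p.a_mean == pytest.approx(15.243, abs=0.01)

    def test_peak_offset_in_reported_range(self, default_params):
        offset = cc.peak_date(default_params) - default_params.a_mean
        assert 15.0 <= offset <= 17.0

    @given(p=year_params_strategy())
    def test_peak_is_a_maximum_on_the_grid(self, p):
        pk = cc.peak_date(p)
        grid = np.arange(1, 121, dtype=float)
        assert cc.census(pk, p) >= cc.census(grid, p).max() - 1e-9 * p.N


# ---------------------------------------------------------------------------
# correction factor
# ---------------------------------------------------------------------------

class TestCorrectionFactor:
    @given(p=year_params_strategy(), offset=st.floats(-3.0, 3.0))
    def test_identity_with_census(self, p, offset):
        t = cc.peak_date(p) + offset
        m = cc.correction_factor(t, p)
        assert m * cc.census(t, p) == pytest.approx(p.N, rel=1e-9)
        assert m >= 1.0

    def test_symmetric_peak_multiplier_closed_form(self, fixed_tenure_params):
        p = fixed_tenure_params
        m = cc.correction_factor(cc.peak_date(p), p)
        assert m == pytest.approx(1.0 / (2 * norm.cdf(p.tenure_mean / (2 * p.a_sd)) - 1))

    def test_multipliers_near_peak_in_reported_band(self, default_params):
        # at the published tenure priors the peak-window multiplier is 1.13-1.20
        p = default_params
        pk = cc.peak_date(p)
        for t in np.arange(pk - 2, pk + 2.5, 1.0):
            assert 1.13 <= cc.correction_factor(t, p) <= 1.20

    def test_tail_days_refused(self, default_params):
        with pytest.raises(OutsideCensusWindowError, match="usable census window"):
            cc.correction_factor(5.0, default_params)
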