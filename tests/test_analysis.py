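import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phenossm import (
    StateSummary,
    compare_stations,
    coverage_fraction,
    fit_trend,
    trend_over_draws,
)

from _oracles import ols_normal_equations
from conftest import make_observations


def summary_from_alpha(years, medians, half_width=3.0, phenophase="FFL"):
    per_year = pd.DataFrame(
        {
            "year": years,
            "quantity": "alpha",
            "median": medians,
            "lo95": np.asarray(medians) - half_width,
            "hi95": np.asarray(medians) + half_width,
        }
    )
    coefs = pd.DataFrame(
        {
            "quantity": ["mu", "beta"],
            "pooled_median": [120.0, -3.0],
            "pooled_sd": [1.0, 0.1],
            "time_avg_median": [120.0, -3.0],
            "time_avg_sd": [1.0, 0.1],
        }
    )
    return StateSummary(
        phenophase=phenophase, per_year=per_year, coefficients=coefs, sigmas=pd.DataFrame()
    )


class TestFitTrend:
    def test_constant_medians_have_zero_slope(self):
        res = fit_trend(np.arange(1990, 2000), np.full(10, 95.0))
        assert res.slope_days_per_decade == pytest.approx(0.0)
        assert res.r_squared == pytest.approx(0.0)
        assert res.advance_days_per_decade == 0.0

    def test_exact_line_recovered(self):
        years = np.arange(1924, 2025)
        medians = 100.0 - 0.1 * (years - 1924)
        res = fit_trend(years, medians)
        assert res.advance_days_per_decade == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)
        assert res.p_value < 1e-10
        assert res.n_years == 101

    def test_errors(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_trend([2000, 2001], [1.0, 2.0])
        with pytest.raises(ValueError, match="distinct"):
            fit_trend([2000, 2000, 2001], [1.0, 2.0, 3.0])

    @given(data=st.data())
    @settings(max_examples=30, deadline=None)
    def test_matches_normal_equations_oracle(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        n = data.draw(st.integers(5, 60))
        years = np.sort(rng.choice(np.arange(1900, 2100), size=n, replace=False))
        medians = rng.normal(100, 5, n) + rng.normal(0, 0.2) * (years - years.mean())
        res = fit_trend(years, medians)
        slope_o, _, r2_o = ols_normal_equations(years, medians)
        assert res.slope_days_per_decade == pytest.approx(10 * slope_o, rel=1e-10)
        assert res.r_squared == pytest.approx(r2_o, rel=1e-9, abs=1e-12)

    @given(
        shift=st.floats(-50, 50, allow_nan=False),
        scale=st.floats(0.1, 4.0, allow_nan=False),
    )
    @settings(max_examples=25, deadline=None)
    def test_shift_invariance_and_linear_scaling(self, shift, scale):
        rng = np.random.default_rng(17)
        years = np.arange(1950, 2000)
        medians = rng.normal(100, 4, 50)
        base = fit_trend(years, medians)
        shifted = fit_trend(years, medians + shift)
        scaled = fit_trend(years, medians * scale)
        assert shifted.slope_days_per_decade == pytest.approx(
            base.slope_days_per_decade, abs=1e-8
        )
        assert scaled.slope_days_per_decade == pytest.approx(
            base.slope_days_per_decade * scale, rel=1e-9
        )

    def test_recovers_injected_drift_across_replicates(self):
        # Monte-Carlo oracle: drift -0.19 day/yr, n=101, noise SD 4
        rng = np.random.default_rng(99)
        years = np.arange(1924, 2025)
        advances = []
        for _ in range(50):
            medians = 110.0 - 0.19 * (years - 1924) + rng.normal(0, 4, 101)
            advances.append(fit_trend(years, medians).advance_days_per_decade)
        advances = np.asarray(advances)
        assert abs(advances.mean() - 1.9) < 0.8
        assert advances.std(ddof=1) < 0.8


class TestCoverage:
    def test_all_observations_at_median(self):
        years = np.arange(2000, 2010)
        summary = summary_from_alpha(years, np.full(10, 100.0))
        obs = make_observations([(int(y), "FFL", 100, "website") for y in years])
        assert coverage_fraction(obs, summary) == 1.0

    def test_single_outside_observation(self):
        summary = summary_from_alpha([2000, 2001, 2002], [100.0, 100.0, 100.0])
        obs = make_observations([(2001, "FFL", 120, "website")])
        assert coverage_fraction(obs, summary) == 0.0

    def test_no_overlap_is_an_error(self):
        summary = summary_from_alpha([2000], [100.0])
        obs = make_observations([(1950, "FFL", 100, "website")])
        with pytest.raises(ValueError, match="overlap"):
            coverage_fraction(obs, summary)

    def test_counts_all_sources(self):
        summary = summary_from_alpha([2000], [100.0], half_width=3.0)
        obs = make_observations(
            [(2000, "FFL", 101, "website"), (2000, "FFL", 110, "literature")]
        )
        assert coverage_fraction(obs, summary) == 0.5


class TestCompareStations:
    def test_identical_summaries_have_zero_deltas(self):
        years = np.arange(2000, 2010)
        a = summary_from_alpha(years, np.linspace(95, 100, 10))
        per_year, coefs = compare_stations(a, a)
        assert np.allclose(per_year["delta"], 0.0)
        assert np.allclose(coefs["delta"], 0.0)

    def test_constant_offset_appears_in_alpha_deltas(self):
        years = np.arange(2000, 2010)
        med = np.linspace(95, 100, 10)
        a = summary_from_alpha(years, med + 1.0)
        b = summary_from_alpha(years, med)
        per_year, _ = compare_stations(a, b)
        assert np.allclose(per_year["delta"], 1.0)

    def test_disjoint_years_error(self):
        a = summary_from_alpha([2000], [100.0])
        b = summary_from_alpha([2010], [100.0])
        with pytest.raises(ValueError, match="share no years"):
            compare_stations(a, b)


def test_trend_over_draws_brackets_point_trend():
    rng = np.random.default_rng(8)
    years = np.arange(1960, 2020)
    base = 100.0 - 0.15 * (years - years[0])

    class _D:
        pass

    d = _D()
    d.years = years
    d.alpha = base[None, None, :] + rng.normal(0, 1.0, size=(2, 400, len(years)))
    table = trend_over_draws(d)
    med = table.loc[table["quantile"] == 0.5, "slope_days_per_decade"].iloc[0]
    lo = table.loc[table["quantile"] == 0.025, "slope_days_per_decade"].iloc[0]
    hi = table.loc[table["quantile"] == 0.975, "slope_days_per_decade"].iloc[0]
    assert lo <= med <= hi
    assert med == pytest.approx(-1.5, abs=0.2)
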