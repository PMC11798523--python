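import logging

import numpy as np
import pandas as pd
import pytest

from phenossm import (
    ModelSpec,
    PriorConfig,
    VarianceParams,
    build_model,
    kalman_smoother,
    summarize_posterior,
)
from phenossm.sampler import PosteriorDraws

from _oracles import joint_gaussian_posterior
from conftest import make_observations


def century_predictors(first=1924, last=2024, seed=0):
    rng = np.random.default_rng(seed)
    years = np.arange(first, last + 1)
    return pd.DataFrame(
        {
            "year": years,
            "ex1": rng.normal(2.0, 0.8, len(years)),
            "ex2": rng.normal(7.0, 1.2, len(years)),
            "ex3": rng.normal(13.0, 2.0, len(years)),
        }
    )


class TestBuildModel:
    def test_century_design_with_late_observations(self):
        pred = century_predictors()
        obs = make_observations(
            [(y, "FFL", 92, "website") for y in range(1989, 2025)]
        )
        spec = build_model("FFL", pred, obs)
        assert spec.n_years == 101
        assert spec.n_observed == 36
        assert spec.n_coefs == 3
        assert spec.coef_names == ("mu", "beta", "gamma")

    def test_one_predictor_form_has_no_gamma(self):
        pred = century_predictors()
        obs = make_observations([(2002, "LFL", 106, "website")])
        spec = build_model("LFL", pred, obs)
        assert spec.n_coefs == 2
        assert "gamma" not in spec.coef_names
        assert "sigma_upsilon" not in spec.sigma_names

    def test_observation_outside_coverage_dropped_with_warning(self, caplog):
        pred = century_predictors(first=1950)
        obs = make_observations(
            [(1930, "FFL", 95, "literature"), (1990, "FFL", 92, "website")]
        )
        with caplog.at_level(logging.WARNING):
            spec = build_model("FFL", pred, obs)
        assert spec.n_observed == 1
        assert any("outside predictor coverage" in r.message for r in caplog.records)

    def test_missing_predictor_years_trimmed_to_contiguous_run(self):
        pred = century_predictors(first=1960, last=2000)
        pred.loc[pred["year"] == 1970, "ex1"] = np.nan  # breaks the run
        obs = make_observations([(1990, "FFL", 92, "website")])
        spec = build_model("FFL", pred, obs)
        assert spec.years[0] == 1971 and spec.years[-1] == 2000

    def test_zero_observations_is_an_error(self):
        pred = century_predictors()
        obs = make_observations([(1990, "LFL", 106, "website")])
        with pytest.raises(ValueError, match="observations"):
            build_model("FFL", pred, obs)

    def test_observation_mask_withholds_an_era(self):
        pred = century_predictors()
        rows = [(y, "FFB", 97, "private") for y in range(1955, 1981)]
        rows += [(y, "FFB", 97, "website") for y in range(1989, 2000)]
        obs = make_observations(rows)
        unmasked = build_model("FFB", pred, obs)
        masked = build_model("FFB", pred, obs, observation_mask=[(1955, 1980)])
        assert unmasked.n_observed == 26 + 11
        assert masked.n_observed == 11


class TestKalmanSmoother:
    def test_single_year_conjugate_update(self):
        # alpha = mu with prior N(0,1); y = 2, sigma_phi = 1
        spec = ModelSpec(
            phenophase="LFB",
            years=np.array([2000]),
            design=np.array([[1.0]]),
            y=np.array([2.0]),
            prior=PriorConfig(init_sd=1.0),
        )
        res = kalman_smoother(spec, VarianceParams(sigma_omega=1.0, sigma_tau=1.0, sigma_phi=1.0))
        assert res.alpha_mean[0] == pytest.approx(1.0)
        assert res.alpha_sd[0] == pytest.approx(np.sqrt(0.5))

    def test_trailing_unobserved_years_widen(self):
        years = np.arange(2000, 2010)
        design = np.column_stack([np.ones(10), np.linspace(1, 3, 10)])
        y = np.full(10, np.nan)
        y[:4] = [100.0, 101.0, 99.0, 100.5]
        spec = ModelSpec("LFB", years, design, y, PriorConfig(init_sd=30.0))
        res = kalman_smoother(spec, VarianceParams(0.5, 0.1, 2.0))
        tail = res.alpha_sd[3:]
        assert np.all(np.diff(tail) > 0)

    def test_matches_dense_joint_gaussian_oracle(self, toy_spec):
        var = VarianceParams(sigma_omega=0.4, sigma_tau=0.15, sigma_phi=1.7, sigma_upsilon=0.1)
        res = kalman_smoother(toy_spec, var)
        mean_o, cov_o, alpha_mean_o, alpha_sd_o = joint_gaussian_posterior(toy_spec, var)
        # the dense route inverts a matrix with diffuse-prior variance 2500,
        # so agreement is limited by float round-off, not by either algorithm
        np.testing.assert_allclose(res.state_mean, mean_o, atol=1e-5)
        np.testing.assert_allclose(res.alpha_mean, alpha_mean_o, atol=1e-5)
        np.testing.assert_allclose(res.alpha_sd, alpha_sd_o, atol=1e-5)
        T, k = toy_spec.design.shape
        for t in range(T):
            block = cov_o[t * k : (t + 1) * k, t * k : (t + 1) * k]
            np.testing.assert_allclose(res.state_cov[t], block, atol=1e-5)


def _draws_from_array(alpha, phenophase="FFL", years=None):
    chains, n, T = alpha.shape
    states = np.repeat(alpha[..., None], 3, axis=3)
    sigmas = np.ones((chains, n, 4))
    return PosteriorDraws(
        phenophase=phenophase,
        years=years if years is not None else np.arange(2000, 2000 + T),
        coef_names=("mu", "beta", "gamma"),
        sigma_names=("sigma_omega", "sigma_tau", "sigma_upsilon", "sigma_phi"),
        states=states,
        alpha=alpha,
        sigmas=sigmas,
    )


class TestSummarize:
    def test_constant_draws_collapse(self):
        draws = _draws_from_array(np.full((2, 50, 3), 7.0))
        summary = summarize_posterior(draws)
        alpha = summary.quantity("alpha")
        assert (alpha["median"] == 7.0).all()
        assert (alpha["lo95"] == 7.0).all()
        assert (alpha["hi95"] == 7.0).all()

    def test_type7_quantile_rule(self):
        vals = np.arange(1.0, 101.0).reshape(1, 100, 1)
        summary = summarize_posterior(_draws_from_array(vals))
        alpha = summary.quantity("alpha")
        assert alpha["median"].iloc[0] == pytest.approx(50.5)
        assert alpha["lo95"].iloc[0] == pytest.approx(3.475)
        assert alpha["hi95"].iloc[0] == pytest.approx(97.525)

    def test_interval_ordering_on_random_draws(self):
        rng = np.random.default_rng(5)
        summary = summarize_posterior(_draws_from_array(rng.normal(size=(4, 200, 6))))
        per = summary.per_year
        assert (per["lo95"] <= per["median"]).all()
        assert (per["median"] <= per["hi95"]).all()

    def test_pooled_and_time_averaged_coefficients_both_reported(self):
        rng = np.random.default_rng(6)
        summary = summarize_posterior(_draws_from_array(rng.normal(size=(2, 100, 5))))
        cols = set(summary.coefficients.columns)
        assert {"pooled_median", "pooled_sd", "time_avg_median", "time_avg_sd"} <= cols
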