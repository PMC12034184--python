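"""Synthetic-data generators: determinism, calibration exactness, scale."""

import numpy as np
import pandas as pd
import pytest

from heatrisk import presets
from heatrisk.simulate import (EpiSimConfig, SurveySimConfig, TempConfig,
                               calibrate_truth, expected_deaths,
                               simulate_deaths, simulate_epi_dataset,
                               simulate_survey, simulate_temperature)
from heatrisk.splines import ns_basis


def warm_temps(series):
    months = pd.DatetimeIndex(series["date"]).month
    return series.loc[np.isin(months, [5, 6, 7, 8, 9]), "tmean"].to_numpy()


class TestSimulateTemperature:
    def test_deterministic_limit_is_exact_sinusoid(self):
        cfg = TempConfig(annual_mean=10.0, seasonal_amplitude=8.0,
                         peak_day_of_year=200, ar_coefficient=0.0, noise_sd=0.0,
                         n_years=2, start_year=2015)
        series = simulate_temperature(cfg, seed=0)
        doy = pd.DatetimeIndex(series["date"]).dayofyear.to_numpy()
        expected = 10.0 + 8.0 * np.cos(2 * np.pi * (doy - 200) / 365.25)
        np.testing.assert_allclose(series["tmean"], expected, atol=1e-12)

    def test_seed_contract(self):
        cfg = presets.warsaw_temp_config()
        a = simulate_temperature(cfg, seed=5)
        b = simulate_temperature(cfg, seed=5)
        c = simulate_temperature(cfg, seed=6)
        pd.testing.assert_frame_equal(a, b)
        assert not np.allclose(a["tmean"], c["tmean"])

    def test_warsaw_profile_matches_observed_p90(self):
        series = simulate_temperature(presets.warsaw_temp_config(), seed=1)
        p90 = np.percentile(warm_temps(series), 90)
        assert abs(p90 - 22.7) < 1.5

    def test_rejects_nonfinite_config_naming_field(self):
        with pytest.raises(ValueError, match="annual_mean"):
            TempConfig(annual_mean=np.nan, seasonal_amplitude=5.0)

    def test_covers_full_calendar_years(self):
        cfg = TempConfig(annual_mean=5, seasonal_amplitude=5, n_years=2,
                         start_year=2016)  # leap year
        series = simulate_temperature(cfg, seed=0)
        assert len(series) == 366 + 365


class TestCalibrateTruth:
    def test_null_surface(self):
        warm = np.random.default_rng(0).uniform(10, 30, 500)
        truth = calibrate_truth(warm, 1.0, 1.0, mmt_temp=15.0)
        np.testing.assert_allclose(truth.theta, 0.0, atol=1e-10)
        np.testing.assert_allclose(truth.f(np.linspace(10, 30, 7)), 0.0, atol=1e-10)

    def test_hits_warsaw_anchor_exactly(self):
        series = simulate_temperature(presets.warsaw_temp_config(), seed=1)
        warm = warm_temps(series)
        truth = calibrate_truth(warm, 1.16, 1.39, mmt_temp=8.5)
        p90 = np.percentile(warm, 90)
        assert truth.f(p90)[0] - truth.f(8.5)[0] == pytest.approx(np.log(1.16), abs=1e-10)
        assert truth.f(np.percentile(warm, 99))[0] == pytest.approx(np.log(1.39), abs=1e-10)

    def test_zero_at_mmt_and_oracle_agreement(self):
        """The solved curve is reproduced by an independent truncated-power
        construction of the same constrained natural spline."""
        from test_splines import truncated_power_natural_basis

        rng = np.random.default_rng(4)
        warm = rng.uniform(8, 32, 800)
        truth = calibrate_truth(warm, 1.2, 1.5, cold_rr=1.05, mmt_temp=14.0)
        assert truth.f(14.0)[0] == 0.0
        # oracle: solve the same three value constraints in truncated-power form
        knots = truth.spline_spec.all_knots
        tp = truncated_power_natural_basis(knots)
        anchors = np.array([np.percentile(warm, 90), np.percentile(warm, 99),
                            warm.min()])
        A = tp(anchors) - tp(np.full(3, 14.0))
        # drop the constant column (differences kill it); solve for [x, N1, N2]
        coef = np.linalg.solve(A[:, 1:], np.log([1.2, 1.5, 1.05]))
        grid = np.linspace(warm.min(), warm.max(), 50)
        oracle = (tp(grid)[:, 1:] - tp(np.full(len(grid), 14.0))[:, 1:]) @ coef
        np.testing.assert_allclose(truth.f(grid), oracle, atol=1e-8)

    def test_stationary_mode_puts_minimum_at_mmt(self):
        series = simulate_temperature(presets.madrid_temp_config(), seed=2)
        warm = warm_temps(series)
        truth = calibrate_truth(warm, 1.23, 1.44, mmt_temp=15.5)
        grid = np.arange(np.percentile(warm, 1), np.percentile(warm, 99), 0.01)
        assert abs(grid[np.argmin(truth.f(grid))] - 15.5) < 0.02

    def test_mmt_outside_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            calibrate_truth(np.linspace(10, 30, 100), 1.2, 1.4, mmt_temp=5.0)

    def test_degenerate_temperatures_rejected(self):
        with pytest.raises(ValueError):
            calibrate_truth(np.full(50, 20.0), 1.2, 1.4, mmt_temp=20.0)

    def test_truth_in_fitted_family(self):
        # zero approximation error: f is an exact linear combination of the
        # basis the model will build from the same temperatures
        warm = np.random.default_rng(9).uniform(5, 30, 600)
        truth = calibrate_truth(warm, 1.3, 1.6, mmt_temp=12.0)
        grid = np.linspace(5, 30, 40)
        B = ns_basis(grid, truth.spline_spec) - ns_basis([12.0], truth.spline_spec)
        np.testing.assert_allclose(B @ truth.theta, truth.f(grid), atol=1e-12)


def _flat_config(**over):
    base = dict(
        temp=TempConfig(annual_mean=15, seasonal_amplitude=8, n_years=10,
                        start_year=2010, noise_sd=2.0),
        rr90=1.0, rr99=1.0, mmt_temp=15.0, baseline_daily_deaths=50.0,
        seasonal_baseline_amplitude=0.0, overdispersion=1.0,
    )
    base.update(over)
    return EpiSimConfig(**base)


class TestSimulateDeaths:
    def test_constant_rate_limit(self):
        series, _ = simulate_epi_dataset(_flat_config(), seed=0)
        deaths = series["deaths"].dropna().to_numpy(dtype=float)
        se = np.sqrt(50.0 / len(deaths))
        assert abs(deaths.mean() - 50.0) < 3 * se

    def test_expected_count_matches_hand_formula(self):
        dates = pd.date_range("2020-06-01", periods=5, freq="D")
        temps = np.array([18.0, 22.0, 25.0, 28.0, 24.0])
        series = pd.DataFrame({"date": dates, "tmean": temps})
        warm = np.random.default_rng(1).uniform(10, 30, 400)
        truth = calibrate_truth(warm, 1.2, 1.5, mmt_temp=16.0)
        cfg = _flat_config(rr90=1.2, rr99=1.5, mmt_temp=16.0,
                           seasonal_baseline_amplitude=0.0)
        mu = expected_deaths(series, truth, cfg)
        w = (0.4, 0.3, 0.2, 0.1)
        for t in (3, 4):
            hand = 50.0 * np.exp(sum(
                w[l] * truth.f(temps[t - l])[0] for l in range(4)))
            assert mu[t] == pytest.approx(hand, rel=1e-12)
        assert np.isnan(mu[:3]).all()

    def test_missing_temperature_propagates_not_imputed(self):
        dates = pd.date_range("2020-06-01", periods=10, freq="D")
        temps = np.linspace(18, 25, 10)
        temps[5] = np.nan
        series = pd.DataFrame({"date": dates, "tmean": temps})
        truth = calibrate_truth(np.random.default_rng(0).uniform(10, 30, 300),
                                1.2, 1.4, mmt_temp=15.0)
        out = simulate_deaths(series, truth, _flat_config(), seed=0)
        missing = out["deaths"].isna().to_numpy()
        # burn-in + the missing day and every day whose lag window touches it
        assert missing[:3].all() and missing[5:9].all()
        assert not missing[4] and not missing[9]

    def test_warsaw_profile_total_deaths_in_expectation(self):
        cfg = presets.warsaw_epi_config()
        series = simulate_temperature(cfg.temp, seed=3)
        warm_mask = pd.DatetimeIndex(series["date"]).month.isin([5, 6, 7, 8, 9])
        truth = calibrate_truth(series.loc[warm_mask, "tmean"], cfg.rr90, cfg.rr99,
                                cfg.cold_rr, cfg.mmt_temp)
        mu = expected_deaths(series, truth, cfg)
        total = np.nansum(np.where(warm_mask, mu, 0.0))
        assert abs(total / 121240 - 1) < 0.03

    def test_overdispersion_matches_negative_binomial_target(self):
        cfg = _flat_config(overdispersion=1.3,
                           temp=TempConfig(annual_mean=15, seasonal_amplitude=0,
                                           noise_sd=2.0, ar_coefficient=0.0,
                                           n_years=30, start_year=2000))
        series, _ = simulate_epi_dataset(cfg, seed=4)
        deaths = series["deaths"].dropna().to_numpy(dtype=float)
        assert deaths.var() / deaths.mean() == pytest.approx(1.3, abs=0.1)

    def test_seed_contract_end_to_end(self):
        cfg = _flat_config()
        a, _ = simulate_epi_dataset(cfg, seed=9)
        b, _ = simulate_epi_dataset(cfg, seed=9)
        c, _ = simulate_epi_dataset(cfg, seed=10)
        pd.testing.assert_frame_equal(a, b)
        assert not a["deaths"].equals(c["deaths"])


class TestSimulateSurvey:
    def test_degenerate_generator(self):
        cfg = presets.warsaw_survey_config()
        cfg = SurveySimConfig(n=50, beta={k: 0.0 for k in cfg.beta}, intercept=3.0,
                              residual_sd=0.0, covariate_model=cfg.covariate_model)
        raw = simulate_survey(cfg, seed=0)
        counts = raw[[f"symptom_{k:02d}" for k in range(1, 12)]].sum(axis=1)
        assert (counts == 3).all()

    def test_default_sizes(self):
        assert presets.warsaw_survey_config().n == 1050
        assert presets.madrid_survey_config().n == 1061

    def test_beta_without_covariate_rule_rejected(self):
        with pytest.raises(ValueError, match="nonexistent"):
            SurveySimConfig(n=10, beta={"nonexistent": 1.0}, intercept=0.0,
                            residual_sd=1.0, covariate_model={})

    def test_clipping_is_rare_under_default_model(self):
        cfg = presets.warsaw_survey_config(n=100_000)
        _, _, latent = simulate_survey(cfg, seed=2, return_design=True)
        assert ((latent < 0) | (latent > 11)).mean() < 0.02

    def test_weights_positive_and_mean_one(self):
        raw = simulate_survey(presets.warsaw_survey_config(), seed=3)
        assert (raw["weight"] > 0).all()
        assert raw["weight"].mean() == pytest.approx(1.0, abs=1e-12)

    def test_seed_contract(self):
        cfg = presets.warsaw_survey_config()
        pd.testing.assert_frame_equal(simulate_survey(cfg, seed=8),
                                      simulate_survey(cfg, seed=8))
        assert not simulate_survey(cfg, seed=8).equals(simulate_survey(cfg, seed=9))
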