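"""Order selection, replicate fitting, bagging, and the validation split."""

import numpy as np
import pandas as pd
import pytest
from scipy.signal import lfilter

from airshift import (
    OrderCaps,
    SarimaSpec,
    SimulationConfig,
    bag_forecasts,
    compute_deviations,
    fit_and_forecast,
    run_state,
    select_order,
    simulate_state_series,
    validation_run,
)

CAPS = OrderCaps()


def sarima_sim(n, phi=0.5, theta_seasonal=-0.4, m=12, rng=None, level=0.0):
    """Simulate from SARIMA(1,0,0)(0,1,1)_m: seasonal difference is ARMA."""
    rng = rng or np.random.default_rng(0)
    eps = rng.normal(0, 1, n + 3 * m)
    w = eps.copy()
    w[m:] += theta_seasonal * eps[:-m]
    z = lfilter([1.0], [1.0, -phi], w)
    y = np.zeros_like(z)
    y[:m] = z[:m]
    for t in range(m, len(z)):
        y[t] = y[t - m] + z[t]
    return level + y[-n:]


class TestSelectOrder:
    def test_white_noise_selects_parsimonious_models(self):
        """AICc penalises spurious terms: white noise yields p+q+P+Q <= 1 nearly always."""
        wins = 0
        reps = 25
        for rep in range(reps):
            rng = np.random.default_rng(100 + rep)
            y = rng.normal(10.0, 1.0, 300)
            spec = select_order(y, None, m=12, caps=CAPS)
            p, d, q = spec.order
            P, D, Q, _ = spec.seasonal_order
            if p + q + P + Q <= 1:
                wins += 1
        assert wins / reps >= 0.9

    def test_order_recovery_finds_seasonal_difference(self):
        """Data with a seasonal unit root: modal selection has d=0, D=1."""
        picks = []
        for rep in range(20):
            rng = np.random.default_rng(200 + rep)
            y = sarima_sim(300, rng=rng, level=50.0)
            spec = select_order(y, None, m=12, caps=CAPS)
            picks.append((spec.order[1], spec.seasonal_order[1]))
        modal = max(set(picks), key=picks.count)
        assert modal == (0, 1)

    def test_search_is_deterministic(self):
        rng = np.random.default_rng(5)
        y = 10 + np.sin(2 * np.pi * np.arange(120) / 12) + rng.normal(0, 1, 120)
        s1 = select_order(y, None, m=12, caps=CAPS)
        s2 = select_order(y, None, m=12, caps=CAPS)
        assert (s1.order, s1.seasonal_order, s1.aicc) == (s2.order, s2.seasonal_order, s2.aicc)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SarimaSpec(order=(1, 2, 0), seasonal_order=(0, 2, 0, 12), aicc=0.0)
        with pytest.raises(ValueError):
            SarimaSpec(order=(-1, 0, 0), seasonal_order=(0, 0, 0, 1), aicc=0.0)


class TestFitAndForecast:
    def test_constant_series_forecasts_the_constant(self):
        y = np.full(60, 7.0)
        spec = SarimaSpec(order=(0, 0, 0), seasonal_order=(0, 0, 0, 0), aicc=0.0, trend="c")
        fc, _ = fit_and_forecast(y, None, None, spec, horizon=8)
        np.testing.assert_allclose(fc, 7.0, atol=1e-6)

    def test_ar1_forecast_decays_monotonically_toward_the_mean(self):
        """Closed-form AR(1) geometry: forecasts from a high last value decay."""
        rng = np.random.default_rng(7)
        y = 10 + lfilter([1.0], [1.0, -0.8], rng.normal(0, 1, 350))[50:]
        y[-1] = y.mean() + 6 * y.std()  # far above the mean
        spec = SarimaSpec(order=(1, 0, 0), seasonal_order=(0, 0, 0, 0), aicc=0.0, trend="c")
        fc, _ = fit_and_forecast(y, None, None, spec, horizon=12)
        diffs = np.diff(fc)
        assert (diffs < 0).all()  # monotone decay from above
        assert (np.abs(diffs[1:]) < np.abs(diffs[:-1])).all()  # geometric shrinkage

    def test_known_weather_coefficient_recovered(self):
        """beta_temp = 0.5 in the generator lands within 2 SE in >= 90% of fits."""
        hits = 0
        reps = 50
        for rep in range(reps):
            rng = np.random.default_rng(300 + rep)
            n = 200
            temp = 15 + 10 * np.sin(2 * np.pi * np.arange(n) / 12) + rng.normal(0, 2, n)
            noise = lfilter([1.0], [1.0, -0.5], rng.normal(0, 1, n + 50))[50:]
            y = 20 + 0.5 * temp + noise
            spec = SarimaSpec(order=(1, 0, 0), seasonal_order=(0, 0, 0, 0),
                              aicc=0.0, trend="c")
            _, res = fit_and_forecast(y[:-8], temp[:-8, None], temp[-8:, None],
                                      spec, horizon=8)
            i = list(res.param_names).index("x1")
            beta, se = res.params[i], res.bse[i]
            hits += abs(beta - 0.5) <= 2 * se
        assert hits / reps >= 0.9

    def test_missing_future_covariates_rejected(self):
        spec = SarimaSpec(order=(0, 0, 0), seasonal_order=(0, 0, 0, 0), aicc=0.0, trend="c")
        with pytest.raises(ValueError, match="future covariate"):
            fit_and_forecast(np.ones(30), np.ones((30, 1)), np.ones((3, 1)), spec, horizon=8)


class TestBagForecasts:
    def test_identical_paths_collapse_the_bands(self):
        path = np.linspace(5, 8, 16)
        fc = bag_forecasts(np.tile(path, (40, 1)), c_obs=path)
        np.testing.assert_allclose(fc.lo95, fc.c_pred)
        np.testing.assert_allclose(fc.hi95, fc.c_pred)
        np.testing.assert_allclose(fc.c_pred, path)

    def test_two_path_mean(self):
        paths = np.vstack([np.zeros(16), np.full(16, 2.0)])
        fc = bag_forecasts(paths, c_obs=np.ones(16))
        np.testing.assert_allclose(fc.c_pred, 1.0)

    def test_mean_lies_within_bands(self, desk_forecast):
        assert (desk_forecast.lo95 <= desk_forecast.c_pred + 1e-12).all()
        assert (desk_forecast.c_pred <= desk_forecast.hi95 + 1e-12).all()

    def test_low_survival_aborts(self):
        paths = np.ones((3, 16))
        with pytest.raises(RuntimeError, match="converged"):
            bag_forecasts(paths, c_obs=np.ones(16), n_requested=10)

    def test_band_calibration_without_intervention(self):
        """Null data: observed weeks fall in the 95% band most of the time."""
        cfg = SimulationConfig(delta_true=0.0, master_seed=31)
        covered = total = 0
        for rep in range(6):
            series, _ = simulate_state_series(cfg, f"N{rep}")
            fc = run_state(series, B=40, m=12, seed=500 + rep)
            covered += int(((fc.c_obs >= fc.lo95) & (fc.c_obs <= fc.hi95)).sum())
            total += fc.horizon
        assert covered / total >= 0.85


class TestValidationRun:
    def test_split_excludes_validation_horizon(self, desk_series):
        series, _ = desk_series  # 60 training + 16 forecast weeks
        fc = validation_run(series, m=12, B=10, seed=3)
        assert fc.horizon == 16
        # validation observations are the pre-forecast-period weeks 44..59
        np.testing.assert_array_equal(fc.c_obs, series.values[44:60])
        assert (fc.week_start < series.forecast_week_start[0]).all()

    def test_overlapping_split_rejected(self, desk_series):
        series, _ = desk_series
        with pytest.raises(ValueError, match="overlap"):
            validation_run(series, m=12, split_index=50, B=5, seed=0)

    def test_insufficient_history_rejected(self, desk_series):
        series, _ = desk_series
        with pytest.raises(ValueError, match="training data"):
            validation_run(series, m=12, split_index=20, horizon=16, B=5, seed=0)

    def test_ape_comparable_across_no_intervention_years(self):
        """Without an intervention, the validation year and the final year are
        exchangeable: their |APE| distributions agree within Monte-Carlo error."""
        cfg = SimulationConfig(delta_true=0.0, n_years_history=6, master_seed=23)
        ape_main, ape_val = [], []
        for rep in range(5):
            series, _ = simulate_state_series(cfg, f"V{rep}")
            fc_main = run_state(series, B=20, m=12, seed=900 + rep)
            fc_val = validation_run(series, m=12, B=20, seed=950 + rep)
            ape_main.append(abs(np.mean(fc_main.c_obs - fc_main.c_pred)))
            ape_val.append(abs(np.mean(fc_val.c_obs - fc_val.c_pred)))
        k = len(ape_main)
        diff = np.mean(ape_main) - np.mean(ape_val)
        se = np.sqrt(np.var(ape_main, ddof=1) / k + np.var(ape_val, ddof=1) / k)
        assert abs(diff) <= 2.5 * se + 0.1  # small absolute floor for tiny samples


class TestRunState:
    def test_deterministic_under_seed(self, desk_series):
        series, _ = desk_series
        a = run_state(series, B=8, m=12, seed=99)
        b = run_state(series, B=8, m=12, seed=99)
        np.testing.assert_array_equal(a.replicate_paths, b.replicate_paths)

    def test_first_replicate_is_original_series_fit(self, desk_series):
        """With include_original and mean paths, replicate 0 is seed-independent:
        its path comes from the untouched training series."""
        series, _ = desk_series
        fc = run_state(series, B=4, m=12, seed=1, path_mode="mean")
        fc2 = run_state(series, B=4, m=12, seed=2, path_mode="mean")
        np.testing.assert_allclose(fc.replicate_paths[0], fc2.replicate_paths[0])

    def test_pre_intervention_deviations_center_on_zero(self, desk_forecast, desk_config):
        dev = compute_deviations(desk_forecast)
        pre = dev.delta[: desk_config.intervention_week - 1]
        assert abs(np.median(pre)) < 1.5  # Monte-Carlo slack at B=30
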