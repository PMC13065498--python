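"""Generator contracts: OU backbone, weather field, excursion model."""

import numpy as np
import pandas as pd
import pytest

from windforay import synthetic as syn
from windforay.weather import wind_from_uv


class TestOUProcess:
    def test_iid_limit_variance(self, rng):
        # dt >> tau: consecutive positions are independent N(mu, sigma^2)
        x = syn.ou_step(np.zeros(10_000), 0.0, dt_h=1000.0, tau_h=2.0,
                        sigma_km=3.0, rng=rng)
        assert np.var(x) == pytest.approx(9.0, rel=0.05)
        assert abs(np.corrcoef(x[:-1], x[1:])[0, 1]) < 0.05

    def test_zero_step_identity(self, rng):
        x0 = np.array([3.7, -1.2])
        x1 = syn.ou_step(x0, np.zeros(2), dt_h=0.0, tau_h=2.0, sigma_km=3.0, rng=rng)
        np.testing.assert_array_equal(x1, x0)

    def test_lag_one_autocorrelation_matches_closed_form(self, rng):
        # dt = tau: exact discretisation gives lag-1 ACF e^{-1}
        n = 10_000
        x = np.zeros(n)
        for i in range(1, n):
            x[i] = syn.ou_step(x[i - 1], 0.0, 2.0, 2.0, 3.0, rng)
        r = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert r == pytest.approx(np.exp(-1.0), abs=0.03)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            syn.SimConfig(ou_tau_h=-1.0)
        with pytest.raises(ValueError):
            syn.SimConfig(ou_sigma_km=0.0)
        with pytest.raises(ValueError):
            syn.SimConfig(interval_mix_weight=1.5)


class TestSamplingSchedule:
    def test_daytime_window_only(self, small_sim):
        hours = pd.DatetimeIndex(small_sim.fixes["timestamp"]).hour
        assert hours.min() >= 6 and hours.max() < 18

    def test_interval_mixture_is_bimodal(self, rng):
        cfg = syn.SimConfig(start_date="2021-01-01", end_date="2021-02-28")
        times = syn.sample_fix_times(cfg, rng)
        iv = np.diff(times.view("int64")) / 60e9
        iv = iv[iv < 200]  # drop overnight gaps
        short = ((iv > 45) & (iv < 75)).mean()
        long = ((iv > 105) & (iv < 130)).mean()
        assert short > 0.5 and long > 0.15


class TestWeatherField:
    def test_midnight_radiation_zero(self):
        w = syn.simulate_weather_field((-20, -20, 20, 20), ("2021-06-01", "2021-06-03"),
                                       10.0, 0)
        hours = pd.DatetimeIndex(w["time"].values).hour
        assert w["ssrd_flux"].values[hours == 0].max() == 0.0
        assert w["ssrd_flux"].values[hours == 3].max() == 0.0

    def test_clear_sky_noon_peak(self):
        w = syn.simulate_weather_field((-20, -20, 20, 20), ("2021-06-01", "2021-06-01"),
                                       10.0, 0, cloud_factor=1.0)
        hours = pd.DatetimeIndex(w["time"].values).hour
        noon = w["ssrd_flux"].values[hours == 12]
        assert noon.max() == pytest.approx(syn.WeatherParams().clear_sky_peak_wm2)

    def test_wind_direction_bimodal_at_regime_peaks(self):
        w = syn.simulate_weather_field((-20, -20, 20, 20), ("2021-01-01", "2021-12-31"),
                                       20.0, 7)
        _, psi = wind_from_uv(w["u100"].values.ravel(), w["v100"].values.ravel())
        # both prevailing regimes produce a mode within +-20 deg, and the
        # global maximum over each semicircle sits at one of the two modes
        def share(target):
            d = np.abs(((psi - target + 180) % 360) - 180)
            return (d <= 20).mean()

        uniform_share = 40.0 / 360.0
        assert share(315.0) > 2.0 * uniform_share
        assert share(135.0) > 2.0 * uniform_share
        hist, edges = np.histogram(psi, bins=72, range=(0, 360))
        centres = (edges[:-1] + edges[1:]) / 2
        for lo, hi, target in ((225, 360, 315.0), (45, 225, 135.0)):
            m = (centres >= lo) & (centres < hi)
            peak = centres[m][np.argmax(hist[m])]
            assert abs(((peak - target + 180) % 360) - 180) <= 20

    def test_empty_date_range_errors(self):
        with pytest.raises(ValueError):
            syn.simulate_weather_field((-20, -20, 20, 20), ("2021-06-02", "2021-05-01"), 10.0, 0)
        with pytest.raises(ValueError):
            syn.simulate_weather_field((20, -20, -20, 20), ("2021-06-01", "2021-06-02"), 10.0, 0)


class TestExcursionModel:
    def test_intercept_only_start_rate(self, rng):
        # a1=a2=a3=0 reduces the initiation model to logistic(a0)
        par = syn.ExcursionParams(a0=-3.0, a1=0.0, a2=0.0, a3=0.0)
        p = syn.start_probability(rng.uniform(0, 360, 100_000),
                                  rng.uniform(0, 60, 100_000),
                                  rng.uniform(0, 1, 100_000), par)
        expected = 1.0 / (1.0 + np.exp(3.0))
        np.testing.assert_allclose(p, expected)
        draws = rng.random(100_000) < p
        se = np.sqrt(expected * (1 - expected) / 100_000)
        assert abs(draws.mean() - expected) < 2.6 * se  # ~99% binomial CI

    def test_direction_effect_peaks_and_range(self):
        par = syn.ExcursionParams()
        g = syn.direction_effect(np.arange(0.0, 360.0), par)
        assert g.max() == pytest.approx(1.0, abs=1e-6)
        assert g.min() >= 0.0
        peaks = np.argsort(g)[-2:]
        assert {int(round(p / 5) * 5) % 360 for p in peaks} <= {315, 135, 310, 320, 130, 140}

    def test_speed_effect_collapses_above_cutoff(self):
        par = syn.ExcursionParams()
        h = syn.speed_effect(np.array([1.0, 11.0, 45.0, 55.0, 70.0]), par)
        assert h[0] > 0.8 and h[1] > 0.8 and h[2] > 0.5
        assert h[3] < 0.1 and h[4] < 0.01

    def test_lrm_duration_log_mean_slope(self, rng):
        # mean duration ratio between R_norm=1 and 0 equals e^{beta_r}
        par = syn.ExcursionParams(lrm_logit_intercept=50.0,  # force LRM class
                                  lrm_min_duration_h=0.0)
        durs = {r: [] for r in (0.0, 1.0)}
        for r_norm in durs:
            for _ in range(10_000):
                cls, dur, _ = syn.draw_excursion_plan(rng, r_norm, 315.0, par,
                                                      start_hour=9.0)
                assert cls == "LRM"
                durs[r_norm].append(dur)
        ratio = np.mean(durs[1.0]) / np.mean(durs[0.0])
        assert ratio == pytest.approx(np.exp(-0.5), rel=0.05)

    def test_evening_starts_never_long_range(self, rng):
        par = syn.ExcursionParams(lrm_logit_intercept=50.0)
        for _ in range(50):
            cls, _, _ = syn.draw_excursion_plan(rng, 0.2, 315.0, par, start_hour=16.0)
            assert cls == "MRM"


class TestGroundTruth:
    def test_labels_partition_fixes(self, small_sim):
        truth = small_sim.truth
        assert len(truth) == len(small_sim.fixes)
        assert set(truth["true_label"]) <= {"SRM", "MRM", "LRM"}
        counts = truth["true_label"].value_counts()
        assert counts.sum() == len(small_sim.fixes)

    def test_srm_dominates(self, small_sim):
        assert (small_sim.truth["true_label"] == "SRM").mean() > 0.85

    def test_excursion_fixes_outside_core(self, small_sim):
        cfg = small_sim.config
        merged = small_sim.fixes.copy()
        merged["true_label"] = small_sim.truth["true_label"].to_numpy()
        for k, (_, sub) in enumerate(merged.groupby("individual_id", sort=True)):
            colony = np.asarray(cfg.colony_centers[k % len(cfg.colony_centers)])
            exc = sub[sub["true_label"] != "SRM"]
            d = np.hypot(exc["x_km"] - colony[0], exc["y_km"] - colony[1])
            assert (d > 2.0 * cfg.ou_sigma_km).all()

    def test_fixed_seed_is_byte_identical(self):
        cfg = syn.SimConfig(n_individuals=2, start_date="2021-05-01",
                            end_date="2021-05-20", seed=9)
        a = syn.simulate_dataset(cfg)
        b = syn.simulate_dataset(cfg)
        pd.testing.assert_frame_equal(a.fixes, b.fixes)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        np.testing.assert_array_equal(a.weather["u100"].values,
                                      b.weather["u100"].values)


class TestOrdinalLabelDraws:
    def test_shares_and_columns(self):
        cfg = syn.SimConfig(seed=3, start_date="2021-01-01", end_date="2021-01-31")
        d = syn.simulate_ordinal_labels(cfg, n_per_individual=100)
        assert len(d) == 100 * cfg.n_individuals
        share = (d["label"] == "SRM").mean()
        assert share == pytest.approx(0.938, abs=0.02)
        assert {"wind_dir_deg", "wind_kmh", "radiation_wm2", "label"} <= set(d.columns)
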