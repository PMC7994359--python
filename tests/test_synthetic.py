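"""The scenario generator: closed forms, moments, and seed contracts."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import smokecast as sc
from smokecast.synthetic import (Episode, ScenarioConfig, make_scenario,
                                 simulate_dispensations, simulate_firework,
                                 simulate_geography, simulate_observations,
                                 simulate_smoke_fields)


class TestGeography:
    def test_cardinalities_and_population_range(self):
        cfg = ScenarioConfig(seed=0, n_hsdas=4, das_per_hsda=50)
        geo = simulate_geography(cfg)
        assert len(geo.das) == 200
        assert geo.das["population"].between(400, 700).all()
        assert len(geo.hsda_ids) == 4
        for h in geo.hsda_ids:
            assert len(geo.stations_in_hsda(h)) >= 1

    def test_hsda_population_is_da_sum(self):
        geo = simulate_geography(ScenarioConfig(seed=1))
        for area in geo.health_areas():
            das = geo.das[geo.das["hsda_id"] == area.hsda_id]
            assert area.population == das["population"].sum()

    def test_same_seed_identical_coordinates(self):
        cfg = ScenarioConfig(seed=5)
        a, b = simulate_geography(cfg), simulate_geography(cfg)
        pd.testing.assert_frame_equal(a.das, b.das)
        pd.testing.assert_frame_equal(a.stations, b.stations)

    def test_geometry_seed_scoping(self):
        """Different scenario seeds share geography when geometry_seed fixed,
        but differ in monitor noise."""
        a = make_scenario(ScenarioConfig(seed=1, geometry_seed=42,
                                         das_per_hsda=20))
        b = make_scenario(ScenarioConfig(seed=2, geometry_seed=42,
                                         das_per_hsda=20))
        pd.testing.assert_frame_equal(a.geography.das, b.geography.das)
        assert not a.observations["pm25"].equals(b.observations["pm25"])


class TestSmokeFields:
    def test_zero_episodes_is_pure_background(self):
        cfg = ScenarioConfig(seed=2, n_episodes=0)
        geo = simulate_geography(cfg)
        f = simulate_smoke_fields(cfg, geo)
        bg = f.background.reindex(f.truth_cells.index).to_numpy()
        assert np.allclose(f.truth_cells.to_numpy(), bg[:, None])

    def test_peak_day_centre_value_closed_form(self):
        ep = Episode(center=(50.0, 50.0), start=pd.Timestamp("2018-08-01"),
                     duration_days=10, peak=120.0)
        dates = pd.DatetimeIndex(["2018-08-06"])  # the triangular midpoint
        assert ep.temporal(dates)[0] == pytest.approx(1.0)
        assert ep.spatial(np.array([[50.0, 50.0]]), 30.0)[0] == 1.0
        # one decay length away the Gaussian footprint is exp(-1/2)
        assert ep.spatial(np.array([[80.0, 50.0]]), 30.0)[0] == pytest.approx(
            np.exp(-0.5))
        # a field carrying this single episode adds exactly `peak` on top of
        # the (noise-free) background at the centre on the peak day
        cfg = ScenarioConfig(seed=3, n_episodes=0, background_sd_log=0.0,
                             spatial_decay_km=30.0)
        geo = simulate_geography(cfg)
        f = dataclasses.replace(simulate_smoke_fields(cfg, geo),
                                episodes=[ep])
        val = f.truth_at(np.array([[50.0, 50.0]]), dates, cfg)[0, 0]
        assert val == pytest.approx(cfg.background_pm + 120.0)

    def test_plume_flags_match_bruteforce_recount(self):
        cfg = ScenarioConfig(seed=4)
        geo = simulate_geography(cfg)
        f = simulate_smoke_fields(cfg, geo)
        recount = int((f.truth_cells.to_numpy() > cfg.hms_threshold).sum())
        assert int(f.hms.to_numpy().sum()) == recount

    def test_monitor_noise_sd_recoverable(self):
        cfg = ScenarioConfig(seed=6)
        geo = simulate_geography(cfg)
        f = simulate_smoke_fields(cfg, geo)
        obs = simulate_observations(cfg, geo, f)
        wide = obs.pivot_table(index="date", columns="station_id",
                               values="pm25").sort_index(axis=1)
        truth = f.truth_at(geo.stations[["x_km", "y_km"]].to_numpy(),
                           wide.index, cfg)
        resid = wide.to_numpy() - truth
        assert np.std(resid) == pytest.approx(cfg.monitor_noise_sd, rel=0.10)


class TestFirework:
    def test_unbiased_noiseless_forecast_equals_truth(self):
        cfg = ScenarioConfig(seed=7, forecast_bias=1.0,
                             forecast_noise_sd_log=0.0)
        geo = simulate_geography(cfg)
        f = simulate_smoke_fields(cfg, geo)
        fw = simulate_firework(cfg, geo, f)
        issue = cfg.window(cfg.eval_year)[10]
        day0, day1 = sc.firework_daily(fw[issue])
        xy = geo.cells[["x_km", "y_km"]].to_numpy()
        t0 = f.truth_at(xy, pd.DatetimeIndex([issue]), cfg)[0]
        t1 = f.truth_at(xy, pd.DatetimeIndex([issue + pd.Timedelta(days=1)]),
                        cfg)[0]
        assert np.allclose(day0, t0) and np.allclose(day1, t1)

    def test_bias_scales_daily_mean_at_fire_cells(self):
        cfg = ScenarioConfig(seed=8, forecast_bias=3.0,
                             forecast_noise_sd_log=0.0)
        geo = simulate_geography(cfg)
        f = simulate_smoke_fields(cfg, geo)
        fw = simulate_firework(cfg, geo, f)
        ep = next(e for e in f.episodes
                  if e.start.year == cfg.eval_year)
        issue = ep.start + pd.Timedelta(days=ep.duration_days // 2)
        xy = geo.cells[["x_km", "y_km"]].to_numpy()
        day0, _ = sc.firework_daily(fw[issue])
        truth = f.truth_at(xy, pd.DatetimeIndex([issue]), cfg)[0]
        i = int(np.argmin(np.hypot(xy[:, 0] - ep.center[0],
                                   xy[:, 1] - ep.center[1])))
        # at the episode centre the bias factor is >= forecast_bias (other
        # active episodes can only push it higher), minus grid discretisation
        assert day0[i] / truth[i] >= 2.9

    def test_same_seed_identical_fields(self):
        cfg = ScenarioConfig(seed=9)
        geo = simulate_geography(cfg)
        f = simulate_smoke_fields(cfg, geo)
        fw1 = simulate_firework(cfg, geo, f)
        fw2 = simulate_firework(cfg, geo, f)
        for k in fw1:
            assert np.array_equal(fw1[k], fw2[k])


class TestDispensations:
    @staticmethod
    def flat_exposure(cfg, pm=4.0, n=400):
        idx = pd.date_range("2017-01-01", periods=n)
        return {"A": pd.Series(pm, index=idx)}

    def test_mean_matches_rate_when_beta_zero(self):
        cfg = ScenarioConfig(seed=10, beta_pm=0.0, dow_multipliers=(1.0,) * 7,
                             holidays="none")
        pops = {"A": 80_000}
        counts = simulate_dispensations(cfg, self.flat_exposure(cfg), pops,
                                        seed=10)["A"]
        lam = cfg.base_rate * pops["A"] / 1e4
        se = (lam / len(counts)) ** 0.5
        assert abs(counts.mean() - lam) < 3 * se

    def test_weekend_multiplier_shows_in_means(self):
        cfg = ScenarioConfig(seed=11, beta_pm=0.0, holidays="none",
                             dow_multipliers=(1, 1, 1, 1, 1, 1, 0.2))
        counts = simulate_dispensations(cfg, self.flat_exposure(cfg, n=1400),
                                        {"A": 80_000}, seed=11)["A"]
        sunday = counts[counts.index.dayofweek == 6].mean()
        weekday = counts[counts.index.dayofweek < 5].mean()
        assert sunday / weekday == pytest.approx(0.2, rel=0.15)

    def test_elevated_exposure_gives_calibrated_excess(self):
        """A +22 ug/m3 season carries ~30% excess dispensations (10 seeds)."""
        ratios = []
        for seed in range(10):
            cfg = ScenarioConfig(seed=seed)
            pops = {"A": 80_000}
            clean = simulate_dispensations(
                cfg, self.flat_exposure(cfg, pm=4.0), pops, seed=seed)["A"]
            smoky = simulate_dispensations(
                cfg, self.flat_exposure(cfg, pm=26.0), pops, seed=seed)["A"]
            ratios.append(smoky.sum() / clean.sum())
        assert np.mean(ratios) == pytest.approx(1.30, rel=0.05)

    def test_overdispersion_increases_variance(self):
        cfg0 = ScenarioConfig(seed=12, beta_pm=0.0, holidays="none",
                              dow_multipliers=(1.0,) * 7)
        cfg1 = dataclasses.replace(cfg0, overdispersion=0.3)
        exp = self.flat_exposure(cfg0, n=2000)
        v0 = simulate_dispensations(cfg0, exp, {"A": 80_000}, seed=1)["A"].var()
        v1 = simulate_dispensations(cfg1, exp, {"A": 80_000}, seed=1)["A"].var()
        assert v1 > 1.5 * v0

    def test_beta_recovery_from_log_counts(self, beta_recovery_estimates):
        """Regressing log(counts+1) on PM recovers beta_pm within 15%
        in a no-weekday, no-holiday world (20 replicates, 3x365 days)."""
        true = ScenarioConfig().beta_pm
        assert abs(np.mean(beta_recovery_estimates) - true) / true < 0.15
        assert all(abs(e - true) / true < 0.15
                   for e in beta_recovery_estimates)


class TestMakeScenario:
    def test_bundle_consistency(self, tiny_bundle):
        b = tiny_bundle
        cfg = b.cfg
        assert set(b.indicators) == set(b.geography.hsda_ids)
        for h, counts in b.indicators.items():
            assert (counts >= 0).all()
            assert counts.dtype.kind in "iu"
        # every evaluation-season issue date carries a 48-h forecast
        for d in cfg.window(cfg.eval_year):
            assert d in b.firework
            assert b.firework[d].shape == (len(b.geography.cells), 48)

    def test_observation_noise_is_exactly_additive(self, tiny_bundle):
        b = tiny_bundle
        wide = b.observations.pivot_table(index="date", columns="station_id",
                                          values="pm25").sort_index(axis=1)
        truth = b.fields.truth_at(
            b.geography.stations[["x_km", "y_km"]].to_numpy(), wide.index,
            b.cfg)
        resid = wide.to_numpy() - truth
        assert np.abs(resid).max() < 6 * b.cfg.monitor_noise_sd

    def test_two_seeds_differ(self):
        a = make_scenario(ScenarioConfig(seed=1, das_per_hsda=10))
        b = make_scenario(ScenarioConfig(seed=2, das_per_hsda=10))
        assert not a.observations["pm25"].equals(b.observations["pm25"])
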