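"""Shared fixtures.

The expensive artifacts — full season runs across replicate seeds, the
bias-variant blend runs — are session-scoped and shared between the module
property tests and the acceptance suite so each is computed once.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

import smokecast as sc
from smokecast import health as H
from smokecast import metrics as M
from smokecast import pipeline as P

PANEL_SEEDS = tuple(range(10))


def tiny_config(**overrides) -> sc.ScenarioConfig:
    """A minimal scenario for fast file/CLI round-trips: 2 HSDAs, 8x8 grid,
    21-day evaluation window, one history year."""
    base = dict(seed=7, n_hsdas=2, das_per_hsda=8, n_stations_per_hsda=3,
                n_vi_stations=3, extent_km=40.0, cell_km=5.0,
                years=(2017, 2018), season_start="08-01", season_end="08-21",
                indicator_warmup_days=182, n_episodes=2,
                episode_duration_days=(5, 10))
    base.update(overrides)
    return sc.ScenarioConfig(**base)


@pytest.fixture(scope="session")
def tiny_bundle() -> sc.ScenarioBundle:
    return sc.make_scenario(tiny_config())


@pytest.fixture(scope="session")
def default_run():
    """One full default-scenario season run (the generator's default seed)."""
    bundle = sc.make_scenario(sc.ScenarioConfig())
    return bundle, P.run_season(bundle)


def indicator_vs_baseline(bundle: sc.ScenarioBundle, results: P.SeasonResults):
    """Model vs trailing same-weekday-mean baseline, pooled over horizons.

    The baseline predicts every target date with its trailing 4-week
    same-weekday mean computed from counts observed before the issue date —
    the same information set the model has, minus all PM knowledge.
    """
    hols = bundle.holidays
    model_rmse, base_rmse, pops = {}, {}, {}
    for h, grp in results.indicator_forecasts.groupby("hsda_id"):
        obs = bundle.indicators[h]
        Ps, Os, Bs = [], [], []
        for rec in grp.itertuples():
            past = obs.loc[obs.index < rec.issue_date]
            for horizon, pred in ((0, rec.day0_count), (1, rec.day1_count)):
                d = rec.issue_date + pd.Timedelta(days=horizon)
                if d in obs.index:
                    Ps.append(pred)
                    Os.append(float(obs.loc[d]))
                    Bs.append(H.trailing_dow_mean(past, d, 4, hols))
        model_rmse[h] = M.rmse((Ps, Os))
        base_rmse[h] = M.rmse((Bs, Os))
        pops[h] = bundle.geography.hsda_population(h)
    return (M.pop_weighted_metric(model_rmse, pops),
            M.pop_weighted_metric(base_rmse, pops))


@pytest.fixture(scope="session")
def season_panel():
    """Full pipeline runs for 10 replicate seeds of the default scenario.

    Returns a list of per-seed records with the per-HSDA indicator IOA
    (horizons pooled) and the model/baseline population-weighted RMSE.
    """
    records = []
    for seed in PANEL_SEEDS:
        bundle = sc.make_scenario(sc.ScenarioConfig(seed=seed))
        results = P.run_season(bundle)
        ev = results.evaluation
        sub = ev[(ev["kind"] == "indicator")
                 & (ev["horizon"] == "both")].set_index("hsda_id")
        model_rmse, base_rmse = indicator_vs_baseline(bundle, results)
        records.append({
            "seed": seed,
            "ioa": sub["ioa"].to_dict(),
            "pm_in_range": bool(
                results.pm_forecasts[["day0_pm25", "day1_pm25"]]
                .stack().between(0, 150).all()),
            "model_rmse": model_rmse,
            "base_rmse": base_rmse,
        })
    return records


def blend_vs_raw_station_rmse(seed: int, bias: float) -> tuple[float, float]:
    """Blend and raw numerical-forecast RMSE against station monitors.

    Trains the blend on the history seasons of a scenario with near-fire
    multiplicative bias ``bias``, then compares day0 predictions at the
    62-station analogue locations over the evaluation season against the
    uncapped monitor observations.
    """
    from smokecast import pm_forecast as PM

    cfg = sc.ScenarioConfig(seed=seed, forecast_bias=bias)
    bundle = sc.make_scenario(cfg)
    model = P.train_blend(bundle, seed=seed)
    geo = bundle.geography
    obs_wide = bundle.observations.pivot_table(
        index="date", columns="station_id", values="pm25").sort_index(axis=1)
    st_xy = geo.stations[["x_km", "y_km"]].to_numpy()
    cell_idx = PM.nearest_index(st_xy, geo.cells[["x_km", "y_km"]].to_numpy())
    preds, raws, obs = [], [], []
    for date in cfg.window(cfg.eval_year):
        fw0, _ = PM.firework_daily(bundle.firework[date])
        X = PM.assemble_predictors(geo, bundle.fields, obs_wide, st_xy, date,
                                   fw0[cell_idx])
        preds.append(PM.predict_day0(model, X))
        raws.append(fw0[cell_idx])
        obs.append(obs_wide.loc[date].to_numpy())
    preds, raws, obs = (np.concatenate(preds), np.concatenate(raws),
                        np.concatenate(obs))
    return M.rmse((preds, obs)), M.rmse((raws, obs))


@pytest.fixture(scope="session")
def blend_bias_panel():
    """(blend RMSE, raw RMSE) per seed for near-fire bias factors 2 and 3."""
    return {b: [blend_vs_raw_station_rmse(seed, b) for seed in PANEL_SEEDS]
            for b in (2.0, 3.0)}


@pytest.fixture(scope="session")
def beta_recovery_estimates():
    """Estimated PM response per replicate in a no-weekday, no-holiday world.

    Each replicate simulates 3 x 365 days of exposure and counts and
    regresses log(counts + 1) on PM per health area (slopes averaged).
    """
    estimates = []
    for seed in range(20):
        cfg = sc.ScenarioConfig(seed=seed, dow_multipliers=(1.0,) * 7,
                                holidays="none", season_start="01-01",
                                season_end="12-31", n_episodes=10,
                                indicator_warmup_days=0)
        geo = sc.simulate_geography(cfg)
        fields = sc.simulate_smoke_fields(cfg, geo)
        exps = {h: geo.pop_weighted_exposure(fields.truth_cells, h).series
                for h in geo.hsda_ids}
        pops = {h: geo.hsda_population(h) for h in geo.hsda_ids}
        counts = sc.simulate_dispensations(cfg, exps, pops)
        slopes = [np.polyfit(exps[h].to_numpy(),
                             np.log(counts[h].to_numpy() + 1.0), 1)[0]
                  for h in geo.hsda_ids]
        estimates.append(float(np.mean(slopes)))
    return estimates


def scaled_forecast_bundle(bundle: sc.ScenarioBundle, factor: float):
    """A copy of a scenario with the numerical forecast scaled everywhere."""
    return dataclasses.replace(
        bundle, firework={k: v * factor for k, v in bundle.firework.items()})
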