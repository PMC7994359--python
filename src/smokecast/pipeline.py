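"""End-to-end season driver: train, forecast daily, verify.

The operational loop mirrors the morning routine of a smoke-season
surveillance system: each issue date, assemble yesterday's covariates and
today's numerical forecast, blend them into capped day0/day+1 PM2.5 fields,
extract the worst-case (maximum) value over each health area's populated
grid cells, and feed those into the dispensation forest together with
trailing day-of-week means computed from counts observed strictly before the
issue date.  Forecasts are then verified against station-based PM2.5
comparators and observed counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geo as G
from . import health as H
from . import metrics as M
from . import pm_forecast as PM
from .synthetic import ScenarioBundle

__all__ = [
    "SeasonResults",
    "train_blend",
    "train_health",
    "forecast_pm_issue",
    "forecast_pm_season",
    "forecast_health_season",
    "evaluate_season",
    "run_season",
]


@dataclass
class SeasonResults:
    cfg: object
    blend_model: PM.BlendModel
    health_model: H.HealthModel
    pm_forecasts: pd.DataFrame          # hsda_id, issue_date, day0/day1 blend + range + raw
    indicator_forecasts: pd.DataFrame   # hsda_id, issue_date, day0_count, day1_count
    evaluation: pd.DataFrame
    summary: dict
    comparators: dict = field(default_factory=dict)
    skipped: list = field(default_factory=list)


def _history_dates(cfg) -> pd.DatetimeIndex:
    return pd.DatetimeIndex(np.concatenate(
        [cfg.window(y).to_numpy() for y in cfg.years[:-1]]))


def train_blend(bundle: ScenarioBundle, seed: int) -> PM.BlendModel:
    """Fit the PM blend forest on the history seasons (all years but the last)."""
    cfg = bundle.cfg
    table = PM.build_blend_table(bundle.geography, bundle.fields,
                                 bundle.observations, bundle.firework,
                                 _history_dates(cfg))
    return PM.fit_blend_model(table, seed=seed)


def train_health(bundle: ScenarioBundle, seed: int,
                 low_sample_frac: float = 0.25) -> H.HealthModel:
    """Fit the dispensation forest on all data before the first issue date.

    The training set spans the history years plus the evaluation year's
    pre-season months — everything observed strictly before the first
    forecast is issued, so nothing the season's forecasts are verified
    against can leak into training.
    """
    cfg = bundle.cfg
    cutoff = cfg.window(cfg.eval_year)[0]
    hols = bundle.holidays
    tables = []
    for i, h in enumerate(bundle.geography.hsda_ids):
        ind = bundle.indicators[h]
        exp = bundle.exposures[h]
        tables.append(H.build_health_table(
            ind[ind.index < cutoff], exp[exp.index < cutoff], holidays=hols,
            low_sample_frac=low_sample_frac, seed=seed + i, hsda_id=h))
    rows = pd.concat(tables, ignore_index=True)
    model = H.fit_health_model(rows, seed=seed)
    model.low_sample_frac = low_sample_frac
    return model


def forecast_pm_issue(bundle: ScenarioBundle, model: PM.BlendModel,
                      issue_date: pd.Timestamp, obs_wide: pd.DataFrame | None = None
                      ) -> pd.DataFrame:
    """Blended day0/day+1 PM2.5 summaries per health area for one issue.

    Blending happens cell by cell over each HSDA's populated cells; the
    maximum (fed to the health model) and minimum (the report range) are
    extracted per HSDA, alongside the raw numerical forecast maxima for
    comparison.  Uses only observations dated before the issue date plus the
    morning's numerical forecast.
    """
    geo = bundle.geography
    cfg = bundle.cfg
    issue = pd.Timestamp(issue_date)
    if issue not in bundle.firework:
        raise KeyError(f"no numerical forecast issued {issue.date()}")
    if obs_wide is None:
        obs = bundle.observations
        obs = obs[obs["date"] < issue]
        obs_wide = obs.pivot_table(index="date", columns="station_id",
                                   values="pm25").sort_index(axis=1)
    fw0_cells, fw1_cells = PM.firework_daily(bundle.firework[issue])

    cells = geo.cells
    pop_mask = cells["populated"].to_numpy()
    pop_ids = cells["cell_id"].to_numpy()[pop_mask]
    X = PM.assemble_predictors(geo, bundle.fields, obs_wide,
                               cells[["x_km", "y_km"]].to_numpy()[pop_mask],
                               issue, fw0_cells[pop_mask])
    day0 = PM.predict_day0(model, X)
    day1 = PM.blend_day1(day0, fw1_cells[pop_mask])
    d0 = pd.Series(day0, index=pop_ids)
    d1 = pd.Series(day1, index=pop_ids)
    raw0 = pd.Series(fw0_cells[pop_mask], index=pop_ids)
    raw1 = pd.Series(fw1_cells[pop_mask], index=pop_ids)

    rows = []
    for h in geo.hsda_ids:
        ids = geo.populated_cells(h)
        rows.append({
            "hsda_id": h, "issue_date": issue,
            "day0_pm25": G.hsda_forecast_exposure(d0, ids),
            "day1_pm25": G.hsda_forecast_exposure(d1, ids),
            "day0_pm25_min": float(d0[ids].min()),
            "day1_pm25_min": float(d1[ids].min()),
            "raw_day0_pm25": G.hsda_forecast_exposure(raw0, ids),
            "raw_day1_pm25": G.hsda_forecast_exposure(raw1, ids),
        })
    return pd.DataFrame(rows)


def forecast_pm_season(bundle: ScenarioBundle, model: PM.BlendModel):
    """Blended PM summaries for every issue date of the evaluation season.

    Covariate assembly is per issue (day-1 data only), but all issues go
    through the forest in one batched prediction; results are identical to
    issuing :func:`forecast_pm_issue` date by date.  Issue dates with missing
    inputs are skipped with a warning and the run continues.
    """
    cfg = bundle.cfg
    geo = bundle.geography
    obs_all = bundle.observations.pivot_table(
        index="date", columns="station_id", values="pm25").sort_index(axis=1)
    pop_mask = geo.cells["populated"].to_numpy()
    pop_ids = geo.cells["cell_id"].to_numpy()[pop_mask]
    pop_xy = geo.cells[["x_km", "y_km"]].to_numpy()[pop_mask]

    blocks, fw1s, issues, skipped = [], [], [], []
    for issue in cfg.window(cfg.eval_year):
        lag = issue - pd.Timedelta(days=1)
        if issue not in bundle.firework or lag not in obs_all.index:
            skipped.append(issue)
            warnings.warn(f"inputs missing for {issue.date()}; issue skipped")
            continue
        fw0, fw1 = PM.firework_daily(bundle.firework[issue])
        blocks.append(PM.assemble_predictors(geo, bundle.fields,
                                             obs_all.loc[:lag], pop_xy, issue,
                                             fw0[pop_mask]))
        fw1s.append(fw1[pop_mask])
        issues.append(issue)
    if not blocks:
        raise ValueError("no issue date could be forecast")
    day0 = PM.predict_day0(model, pd.concat(blocks, ignore_index=True)
                           ).reshape(len(issues), -1)
    rows = []
    for i, issue in enumerate(issues):
        d0 = pd.Series(day0[i], index=pop_ids)
        d1 = pd.Series(PM.blend_day1(day0[i], fw1s[i]), index=pop_ids)
        fw0, _ = PM.firework_daily(bundle.firework[issue])
        raw0 = pd.Series(fw0[pop_mask], index=pop_ids)
        raw1 = pd.Series(fw1s[i], index=pop_ids)
        for h in geo.hsda_ids:
            ids = geo.populated_cells(h)
            rows.append({
                "hsda_id": h, "issue_date": issue,
                "day0_pm25": G.hsda_forecast_exposure(d0, ids),
                "day1_pm25": G.hsda_forecast_exposure(d1, ids),
                "day0_pm25_min": float(d0[ids].min()),
                "day1_pm25_min": float(d1[ids].min()),
                "raw_day0_pm25": G.hsda_forecast_exposure(raw0, ids),
                "raw_day1_pm25": G.hsda_forecast_exposure(raw1, ids),
            })
    return pd.DataFrame(rows), skipped


def forecast_health_season(bundle: ScenarioBundle, model: H.HealthModel,
                           pm_forecasts: pd.DataFrame) -> pd.DataFrame:
    """Dispensation forecasts for every (HSDA, issue) in ``pm_forecasts``.

    Feature rows are assembled exactly as :func:`health.forecast_indicator`
    does — counts strictly before the issue date, the day0/day+1 blend
    substitution — but the whole season is pushed through the forest in one
    batched prediction.
    """
    hols = bundle.holidays
    feats, keys = [], []
    for rec in pm_forecasts.itertuples():
        issue = rec.issue_date
        h = rec.hsda_id
        past = bundle.indicators[h].loc[bundle.indicators[h].index < issue]
        pm_obs_lag1 = float(bundle.exposures[h].loc[issue - pd.Timedelta(days=1)])
        feats.extend(H.substitution_features(
            past, rec.day0_pm25, rec.day1_pm25, pm_obs_lag1, issue, hols))
        keys.append((h, issue))
    X = pd.DataFrame(feats)[H.HEALTH_FEATURES].to_numpy(float)
    pred = np.clip(model.estimator.predict(X), 0.0, None).reshape(-1, 2)
    return pd.DataFrame([{"hsda_id": h, "issue_date": d,
                          "day0_count": float(p[0]), "day1_count": float(p[1])}
                         for (h, d), p in zip(keys, pred)])


def _pairs(fc: pd.DataFrame, obs: pd.Series, col0: str, col1: str, horizon: str):
    f = fc.set_index("issue_date")
    if horizon == "day0":
        P = f[col0]
        O = obs.reindex(P.index)
    elif horizon == "day1":
        P = f[col1].copy()
        P.index = P.index + pd.Timedelta(days=1)
        O = obs.reindex(P.index)
    else:
        raise ValueError("horizon must be 'day0' or 'day1'; pooling is the caller's")
    keep = O.notna()
    return P[keep].to_numpy(), O[keep].to_numpy()


def _summaries(fc: pd.DataFrame, obs_by_hsda: dict, col0: str, col1: str,
               pops: dict, kind: str) -> pd.DataFrame:
    rows = []
    for h, grp in fc.groupby("hsda_id"):
        obs = obs_by_hsda.get(h)
        if obs is None:
            continue
        parts = {hor: _pairs(grp, obs, col0, col1, hor)
                 for hor in ("day0", "day1")}
        parts["both"] = (np.concatenate([parts["day0"][0], parts["day1"][0]]),
                         np.concatenate([parts["day0"][1], parts["day1"][1]]))
        for hor, (P, O) in parts.items():
            if len(P) == 0:
                continue
            ps = M.PairedSeries(P, O)
            row = {"kind": kind, "hsda_id": h, "horizon": hor, "n": ps.n,
                   "rmse": M.rmse(ps), "ioa": M.ioa(ps),
                   "pct_within20": M.pct_within(ps), "population": pops[h]}
            if kind == "indicator":
                row["rmse_per_10k"] = M.rate_per_10k(row["rmse"], pops[h])
            rows.append(row)
    return pd.DataFrame(rows)


def evaluate_season(bundle: ScenarioBundle, pm_forecasts: pd.DataFrame,
                    indicator_forecasts: pd.DataFrame,
                    station_weighting: str = "population"):
    """Verification per HSDA and horizon, plus province-wide aggregates.

    PM2.5 blends are compared against the (uncapped) station comparator
    series; HSDAs without stations are excluded from the PM table only.
    Dispensation forecasts are compared against observed counts.  Aggregates
    are population-weighted means of the per-HSDA metrics, with Pearson
    correlations of each metric against HSDA population.
    """
    geo = bundle.geography
    pops = {h: geo.hsda_population(h) for h in geo.hsda_ids}

    comparators = {}
    for h in geo.hsda_ids:
        es = G.station_comparator_series(geo, h, bundle.observations,
                                         weighting=station_weighting)
        if es is not None:
            comparators[h] = es.series
    pm_eval = _summaries(pm_forecasts, comparators, "day0_pm25", "day1_pm25",
                         pops, "pm25")
    ind_eval = _summaries(indicator_forecasts,
                          {h: bundle.indicators[h] for h in geo.hsda_ids},
                          "day0_count", "day1_count", pops, "indicator")
    evaluation = pd.concat([pm_eval, ind_eval], ignore_index=True)

    summary = {}
    for kind in ("pm25", "indicator"):
        for hor in ("day0", "day1", "both"):
            sub = evaluation[(evaluation["kind"] == kind)
                             & (evaluation["horizon"] == hor)]
            if sub.empty:
                continue
            vals = sub.set_index("hsda_id")
            p = {h: pops[h] for h in vals.index}
            entry = {
                "n_hsdas": len(vals),
                "ioa_pop_weighted": M.pop_weighted_metric(vals["ioa"].to_dict(), p),
                "ioa_range": [float(vals["ioa"].min()), float(vals["ioa"].max())],
                "rmse_pop_weighted": M.pop_weighted_metric(vals["rmse"].to_dict(), p),
                "pct_within20_pop_weighted": M.pop_weighted_metric(
                    vals["pct_within20"].to_dict(), p),
            }
            if kind == "indicator":
                entry["rmse_per_10k_pop_weighted"] = M.pop_weighted_metric(
                    vals["rmse_per_10k"].to_dict(), p)
            if len(vals) >= 3:
                popv = [p[h] for h in vals.index]
                for met in ("ioa", "pct_within20", "rmse"):
                    try:
                        entry[f"pearson_population_{met}"] = M.pearson(
                            popv, vals[met].to_numpy())
                    except ValueError:
                        entry[f"pearson_population_{met}"] = None
            summary[f"{kind}_{hor}"] = entry
    return evaluation, summary, comparators


def run_season(bundle: ScenarioBundle, model_seed: int | None = None,
               low_sample_frac: float = 0.25,
               station_weighting: str = "population") -> SeasonResults:
    """Train both forests on the history seasons and run the evaluation season."""
    cfg = bundle.cfg
    seed = cfg.seed if model_seed is None else model_seed
    blend = train_blend(bundle, seed=seed)
    healthm = train_health(bundle, seed=seed, low_sample_frac=low_sample_frac)
    pm_fc, skipped = forecast_pm_season(bundle, blend)
    ind_fc = forecast_health_season(bundle, healthm, pm_fc)
    evaluation, summary, comparators = evaluate_season(
        bundle, pm_fc, ind_fc, station_weighting=station_weighting)
    return SeasonResults(cfg=cfg, blend_model=blend, health_model=healthm,
                         pm_forecasts=pm_fc, indicator_forecasts=ind_fc,
                         evaluation=evaluation, summary=summary,
                         comparators=comparators, skipped=skipped)
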