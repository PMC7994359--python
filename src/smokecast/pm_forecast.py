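"""Blended day0 / day+1 PM2.5 forecasts.

A single province-wide random forest regresses observed 24-h station PM2.5
(truncated at 150 ug/m3) on six covariates: yesterday's nearest-station
PM2.5, nearest aerosol optical depth within 50 km, mean fire radiative power
within 100 km, binary plume presence, the venting index, and today's
numerical smoke-forecast daily mean.  The ensemble uses 1,000 trees with 3
of the 6 variables sampled per split, and is scored with out-of-bag (OOB)
predictions: for each training row, the mean prediction of the trees that
did not sample it.

The day0 blended forecast is the capped ensemble prediction; the day+1
forecast averages the day0 blend with the numerical forecast's second-day
mean, then caps.  Blending exists to attenuate the numerical model's
near-fire overestimates while retaining its skill elsewhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .geo import PM_CAP, Geography, cap_pm, nearest_index

__all__ = [
    "FEATURES",
    "PredictorVector",
    "ForecastPair",
    "BlendModel",
    "firework_daily",
    "assemble_predictors",
    "build_blend_table",
    "fit_blend_model",
    "oob_metrics",
    "predict_day0",
    "blend_day1",
    "save_model",
    "load_model",
]

#: Covariate order offered to the forest.
FEATURES = ["pm25_lag1", "aod", "frp", "hms", "vi", "firework"]

AOD_RADIUS_KM = 50.0
FRP_RADIUS_KM = 100.0


@dataclass(frozen=True)
class PredictorVector:
    """The six blend-model covariates for one location-date.

    ``pm25_lag1``/``aod``/``frp``/``hms``/``vi`` are day-1 values;
    ``firework`` is the day0 daily-mean numerical forecast.  ``aod`` may be
    None (no retrieval within 50 km) and is median-imputed at prediction.
    """

    pm25_lag1: float
    aod: float | None
    frp: float
    hms: int
    vi: int
    firework: float

    def __post_init__(self):
        if self.hms not in (0, 1):
            raise ValueError("hms must be 0 or 1")
        if not 1 <= self.vi <= 100:
            raise ValueError("vi must be in [1, 100]")
        for name in ("pm25_lag1", "frp", "firework"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.aod is not None and self.aod < 0:
            raise ValueError("aod must be non-negative or None")

    def as_row(self) -> pd.DataFrame:
        return pd.DataFrame([{**{f: getattr(self, f) for f in FEATURES},
                              "aod": np.nan if self.aod is None else self.aod}])


@dataclass
class ForecastPair:
    """day0/day+1 predictions issued on one date for one health area."""

    hsda_id: str
    issue_date: pd.Timestamp
    day0: float
    day1: float
    kind: str  # "pm25" | "indicator"

    def __post_init__(self):
        if self.kind == "pm25" and not (0 <= self.day0 <= PM_CAP
                                        and 0 <= self.day1 <= PM_CAP):
            raise ValueError("pm25 forecasts must lie in [0, 150]")
        if self.kind == "indicator" and (self.day0 < 0 or self.day1 < 0):
            raise ValueError("indicator forecasts must be non-negative")


@dataclass
class BlendModel:
    """Fitted blend ensemble plus everything needed to reuse it."""

    estimator: RandomForestRegressor
    n_trees: int
    vars_per_split: int
    seed: int
    aod_median: float
    n_rows: int
    oob_pred: np.ndarray
    oob_rmse: float
    oob_pseudo_r2: float
    version: str = "1"


def firework_daily(hourly) -> tuple:
    """Collapse a 48-h hourly forecast to (day0, day1) daily means.

    day0 averages hours 1-24, day1 averages hours 25-48.  Accepts one
    48-vector or an (n, 48) array.
    """
    arr = np.asarray(hourly, dtype=float)
    if arr.shape[-1] != 48:
        raise ValueError("expected 48 hourly values")
    if (arr < 0).any():
        raise ValueError("hourly forecasts must be non-negative")
    day0 = arr[..., :24].mean(axis=-1)
    day1 = arr[..., 24:].mean(axis=-1)
    if arr.ndim == 1:
        return float(day0), float(day1)
    return day0, day1


def assemble_predictors(geo: Geography, fields, obs_wide: pd.DataFrame,
                        points_xy: np.ndarray, date: pd.Timestamp,
                        firework_day0: np.ndarray) -> pd.DataFrame:
    """Six-covariate matrix for arbitrary points on one date.

    ``obs_wide`` is the station observation table (index date, columns
    station_id in sorted order); ``firework_day0`` holds the day0 numerical
    daily mean already evaluated at each point.  Day-1 covariates are read
    from ``date - 1 day``.  AOD is left NaN when no retrieval lies within
    50 km.
    """
    lag = date - pd.Timedelta(days=1)
    pts = np.asarray(points_xy, float)
    n = len(pts)
    st_xy = geo.stations[["x_km", "y_km"]].to_numpy()
    obs_lag = obs_wide.loc[lag].to_numpy()
    pm25_lag1 = obs_lag[nearest_index(pts, st_xy)]

    aod_day = fields.aod[fields.aod["date"] == lag]
    aod = np.full(n, np.nan)
    if len(aod_day):
        axy = aod_day[["x_km", "y_km"]].to_numpy()
        idx = nearest_index(pts, axy)
        dist = np.hypot(*(pts - axy[idx]).T)
        vals = aod_day["aod"].to_numpy()[idx]
        aod = np.where(dist <= AOD_RADIUS_KM, vals, np.nan)

    frp_day = fields.frp[fields.frp["date"] == lag]
    frp = np.zeros(n)
    if len(frp_day):
        fxy = frp_day[["x_km", "y_km"]].to_numpy()
        d = np.hypot(pts[:, None, 0] - fxy[None, :, 0],
                     pts[:, None, 1] - fxy[None, :, 1])
        inside = d <= FRP_RADIUS_KM
        vals = frp_day["frp_mw"].to_numpy()
        cnt = inside.sum(axis=1)
        frp = np.where(cnt > 0, (inside * vals).sum(axis=1) / np.maximum(cnt, 1), 0.0)

    cell_xy = geo.cells[["x_km", "y_km"]].to_numpy()
    cell_idx = nearest_index(pts, cell_xy)
    hms = fields.hms.loc[lag].to_numpy()[cell_idx]

    vi_xy = fields.vi_stations[["x_km", "y_km"]].to_numpy()
    vi = fields.vi.loc[lag].to_numpy()[nearest_index(pts, vi_xy)]

    return pd.DataFrame({"pm25_lag1": pm25_lag1, "aod": aod, "frp": frp,
                         "hms": hms, "vi": vi,
                         "firework": np.asarray(firework_day0, float)})


def build_blend_table(geo: Geography, fields, observations: pd.DataFrame,
                      firework: dict, dates) -> pd.DataFrame:
    """One training row per station-date with a complete target.

    The target is the station's observed day0 24-h mean truncated at 150
    ug/m3.  Missing AOD values are imputed with the median AOD over all
    non-missing rows; the imputation value is recorded in the table's
    ``attrs['aod_median']`` and carried into the fitted model.
    """
    obs_wide = observations.pivot_table(index="date", columns="station_id",
                                        values="pm25").sort_index(axis=1)
    st_xy = geo.stations[["x_km", "y_km"]].to_numpy()
    cell_idx = nearest_index(st_xy, geo.cells[["x_km", "y_km"]].to_numpy())
    frames = []
    for date in pd.DatetimeIndex(dates):
        if date not in firework or (date - pd.Timedelta(days=1)) not in obs_wide.index:
            continue
        fw0, _ = firework_daily(firework[date])
        block = assemble_predictors(geo, fields, obs_wide, st_xy, date,
                                    fw0[cell_idx])
        block.insert(0, "date", date)
        block.insert(0, "station_id", geo.stations["station_id"].to_numpy())
        block["target"] = cap_pm(obs_wide.loc[date].to_numpy())
        frames.append(block)
    if not frames:
        raise ValueError("no training rows could be built")
    table = pd.concat(frames, ignore_index=True).dropna(
        subset=["pm25_lag1", "target"])
    median = float(np.nanmedian(table["aod"]))
    table["aod"] = table["aod"].fillna(median)
    table.attrs["aod_median"] = median
    return table


def _oob_from_estimator(est: RandomForestRegressor, y: np.ndarray):
    oob = est.oob_prediction_
    ok = ~np.isnan(oob)
    if not ok.all():
        warnings.warn(f"{(~ok).sum()} rows never out-of-bag; excluded from OOB metrics")
    err = oob[ok] - y[ok]
    rmse = float(np.sqrt(np.mean(err**2)))
    pseudo_r2 = float(1.0 - np.mean(err**2) / np.var(y[ok]))
    return oob, rmse, pseudo_r2


def fit_blend_model(rows: pd.DataFrame, n_trees: int = 1000,
                    vars_per_split: int = 3, seed: int = 0) -> BlendModel:
    """Fit the blend forest and score it out-of-bag.

    ``rows`` must carry the six FEATURES columns plus ``target``.  Requires
    at least 50 rows and a non-constant target; reproducible given the seed.
    """
    if len(rows) < 50:
        raise ValueError("need at least 50 training rows")
    y = rows["target"].to_numpy(float)
    if np.ptp(y) == 0:
        raise ValueError("degenerate constant target")
    if len(rows) < 5 * n_trees // 100:
        warnings.warn("very few rows relative to forest size")
    X = rows[FEATURES].to_numpy(float)
    if np.isnan(X).any():
        raise ValueError("predictor matrix contains missing values; impute first")
    est = RandomForestRegressor(n_estimators=n_trees, max_features=vars_per_split,
                                oob_score=True, random_state=int(seed), n_jobs=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        est.fit(X, y)
    oob, rmse, pr2 = _oob_from_estimator(est, y)
    return BlendModel(estimator=est, n_trees=n_trees, vars_per_split=vars_per_split,
                      seed=int(seed), aod_median=float(rows.attrs.get(
                          "aod_median", np.nanmedian(rows["aod"]))),
                      n_rows=len(rows), oob_pred=oob, oob_rmse=rmse,
                      oob_pseudo_r2=pr2)


def oob_metrics(model: BlendModel, rows: pd.DataFrame) -> tuple[float, float]:
    """(RMSE, pseudo-R2) of the stored per-row OOB predictions.

    RMSE is sqrt(sum (P_i - O_i)^2 / n) with P_i the mean OOB prediction for
    observation O_i; pseudo-R2 is one minus the mean squared OOB error over
    the population variance of the targets.
    """
    y = rows["target"].to_numpy(float)
    if len(y) != len(model.oob_pred):
        raise ValueError("rows do not match the model's training set")
    ok = ~np.isnan(model.oob_pred)
    if not ok.all():
        warnings.warn(f"{(~ok).sum()} rows never out-of-bag; excluded")
    err = model.oob_pred[ok] - y[ok]
    return (float(np.sqrt(np.mean(err**2))),
            float(1.0 - np.mean(err**2) / np.var(y[ok])))


def predict_day0(model: BlendModel, pv) -> float | np.ndarray:
    """Capped ensemble day0 prediction for one PredictorVector or a matrix."""
    if isinstance(pv, PredictorVector):
        X = pv.as_row()
        scalar = True
    else:
        X = pv[FEATURES].copy() if isinstance(pv, pd.DataFrame) else pd.DataFrame(
            np.asarray(pv, float), columns=FEATURES)
        scalar = False
    if X["firework"].isna().any():
        raise ValueError("missing numerical forecast covariate")
    X["aod"] = X["aod"].fillna(model.aod_median)
    if X.isna().any().any():
        raise ValueError("predictor matrix incomplete after AOD imputation")
    pred = np.clip(model.estimator.predict(X.to_numpy(float)), 0.0, PM_CAP)
    return float(pred[0]) if scalar else pred


def blend_day1(day0_blend, firework_day1):
    """day+1 blend: average the day0 blend with the day+1 numerical mean, cap.

    The average is taken before capping (the cap is a reporting constraint on
    outputs, not on intermediate arithmetic).
    """
    d0 = np.asarray(day0_blend, float)
    d1 = np.asarray(firework_day1, float)
    if (d0 < 0).any() or (d1 < 0).any():
        raise ValueError("inputs must be non-negative")
    out = np.minimum((d0 + d1) / 2.0, PM_CAP)
    return float(out) if out.ndim == 0 else out


def save_model(model, path) -> None:
    """Persist a fitted model bundle (opaque, versioned)."""
    payload = {"format_version": "smokecast-model-1", "model": model}
    joblib.dump(payload, path)


def load_model(path):
    payload = joblib.load(path)
    if payload.get("format_version") != "smokecast-model-1":
        raise ValueError("unrecognised model bundle format")
    return payload["model"]
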