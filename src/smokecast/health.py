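"""Daily inhaler-dispensation forecasts per health area.

A random forest predicts the daily count of reliever-inhaler (salbutamol)
dispensations from five covariates: (1) today's population-weighted PM2.5,
(2) yesterday's, (3) the mean count on the same day-of-week over the past 12
weeks, (4) the same over the past 4 weeks, and (5) the ISO week of year.
The trailing day-of-week means skip statutory holidays — pharmacies largely
close on holidays, so a holiday count would bias the weekday trend — and
extend the lookback (to at most twice the window) until enough qualifying
days are found.

Training uses every date with exposure above 15 ug/m3 plus a seeded random
sample of cleaner dates, so smoky days are never diluted away.  At forecast
time covariate (1) is replaced by the blended day0 PM2.5 forecast (day+1:
covariates (1) and (2) replaced by the day+1 and day0 blends); all other
covariates come from data observed strictly before the issue date.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .pm_forecast import ForecastPair

__all__ = [
    "HEALTH_FEATURES",
    "IndicatorSeries",
    "HealthModel",
    "trailing_dow_mean",
    "week_of_year",
    "build_health_table",
    "fit_health_model",
    "substitution_features",
    "forecast_indicator",
]

HEALTH_FEATURES = ["pm_day0", "pm_lag1", "dow12", "dow4", "week_of_year"]

PM_THRESHOLD = 15.0  # ug/m3; training keeps all days above this


@dataclass
class IndicatorSeries:
    """Daily dispensation counts for one health area."""

    hsda_id: str
    series: pd.Series  # index: dates; values: non-negative integer counts

    def __post_init__(self):
        if (self.series < 0).any():
            raise ValueError("counts must be non-negative")


@dataclass
class HealthModel:
    estimator: RandomForestRegressor
    n_trees: int
    vars_per_split: int
    seed: int
    n_rows: int
    threshold: float
    low_sample_frac: float
    oob_pred: np.ndarray
    oob_rmse: float
    oob_pseudo_r2: float
    version: str = "1"


def _as_date(d) -> dt.date:
    return d.date() if hasattr(d, "date") else d


def _trailing(series: pd.Series, date: pd.Timestamp, k: int,
              holidays) -> tuple[float, int]:
    hols = {_as_date(h) for h in (holidays or ())}
    if _as_date(date) in hols:
        # closure-regime reference for a holiday target: recent Sundays
        anchor = date - pd.Timedelta(days=(date.dayofweek - 6) % 7 or 7)
    else:
        anchor = date - pd.Timedelta(weeks=1)
    found = []
    for j in range(2 * k):
        d = anchor - pd.Timedelta(weeks=j)
        if _as_date(d) in hols:
            continue
        if d in series.index:
            found.append(float(series.loc[d]))
        if len(found) == k:
            break
    return (float(np.mean(found)) if found else np.nan), len(found)


def trailing_dow_mean(series: pd.Series, date, k_weeks: int, holidays=()) -> float:
    """Mean count on the same weekday over the past ``k_weeks`` weeks.

    Considers dates strictly before ``date`` in weekly steps, skipping
    holidays and extending the lookback to at most 2*k_weeks weeks until
    ``k_weeks`` qualifying dates are found.  Fewer qualifying dates give the
    mean of those available with a warning; none at all is an error.

    Holiday awareness is two-sided: holidays never enter a lookback (their
    depressed counts would bias the weekday trend down), and when ``date``
    itself is a holiday the mean is taken over the most recent Sundays
    instead — pharmacies close on holidays as they do on Sundays, so recent
    Sundays are the comparable closure regime.
    """
    date = pd.Timestamp(date)
    mean, n = _trailing(series, date, k_weeks, holidays)
    if n == 0:
        raise ValueError(f"no qualifying same-weekday history before {date.date()}")
    if n < k_weeks:
        warnings.warn(f"only {n}/{k_weeks} qualifying weeks before {date.date()}")
    return mean


def week_of_year(date) -> int:
    """ISO-8601 week number (1-53)."""
    return int(pd.Timestamp(date).isocalendar().week)


def build_health_table(indicator: pd.Series, exposure: pd.Series,
                       holidays=(), threshold: float = PM_THRESHOLD,
                       low_sample_frac: float = 0.25, seed: int = 0,
                       hsda_id: str | None = None) -> pd.DataFrame:
    """Training rows for one health area.

    Every date whose exposure exceeds ``threshold`` is included; remaining
    dates enter via a seeded uniform sample of fraction ``low_sample_frac``.
    A date qualifies only when its trailing 12- and 4-week day-of-week means
    are fully available (no shortened lookback) and yesterday's exposure
    exists.
    """
    rng = np.random.default_rng(seed)
    rows = []
    dates = sorted(set(indicator.index) & set(exposure.index))
    keep_draw = rng.random(len(dates))
    for i, d in enumerate(dates):
        lag = d - pd.Timedelta(days=1)
        if lag not in exposure.index:
            continue
        smoky = exposure.loc[d] > threshold
        if not smoky and keep_draw[i] >= low_sample_frac:
            continue
        m12, n12 = _trailing(indicator, d, 12, holidays)
        m4, n4 = _trailing(indicator, d, 4, holidays)
        if n12 < 12 or n4 < 4:
            continue
        rows.append({"hsda_id": hsda_id, "date": d,
                     "pm_day0": float(exposure.loc[d]),
                     "pm_lag1": float(exposure.loc[lag]),
                     "dow12": m12, "dow4": m4,
                     "week_of_year": week_of_year(d),
                     "target": float(indicator.loc[d])})
    if not rows:
        raise ValueError("no usable training dates")
    return pd.DataFrame(rows)


def fit_health_model(rows: pd.DataFrame, n_trees: int = 1000,
                     vars_per_split: int = 2, seed: int = 0) -> HealthModel:
    """Fit the dispensation forest with out-of-bag scoring (as the PM blend)."""
    if len(rows) < 50:
        raise ValueError("need at least 50 training rows")
    y = rows["target"].to_numpy(float)
    if np.ptp(y) == 0:
        raise ValueError("degenerate constant target")
    X = rows[HEALTH_FEATURES].to_numpy(float)
    est = RandomForestRegressor(n_estimators=n_trees, max_features=vars_per_split,
                                oob_score=True, random_state=int(seed), n_jobs=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        est.fit(X, y)
    oob = est.oob_prediction_
    ok = ~np.isnan(oob)
    if not ok.all():
        warnings.warn(f"{(~ok).sum()} rows never out-of-bag; excluded from OOB metrics")
    err = oob[ok] - y[ok]
    return HealthModel(estimator=est, n_trees=n_trees,
                       vars_per_split=vars_per_split, seed=int(seed),
                       n_rows=len(rows), threshold=PM_THRESHOLD,
                       low_sample_frac=float("nan"), oob_pred=oob,
                       oob_rmse=float(np.sqrt(np.mean(err**2))),
                       oob_pseudo_r2=float(1 - np.mean(err**2) / np.var(y[ok])))


def substitution_features(past: pd.Series, pm_day0: float, pm_day1: float,
                          pm_obs_lag1: float, issue: pd.Timestamp,
                          holidays=()) -> list[dict]:
    """The two feature rows (day0, day+1) for one issue, after substitution.

    day0 takes (blended day0 PM, observed day-1 PM); day+1 takes (blended
    day+1 PM, blended day0 PM); trailing day-of-week means and the week
    number are evaluated at the issue date and the following day, from
    counts observed strictly before the issue date.
    """
    issue = pd.Timestamp(issue)
    day1 = issue + pd.Timedelta(days=1)
    return [
        {"pm_day0": pm_day0, "pm_lag1": pm_obs_lag1,
         "dow12": trailing_dow_mean(past, issue, 12, holidays),
         "dow4": trailing_dow_mean(past, issue, 4, holidays),
         "week_of_year": week_of_year(issue)},
        {"pm_day0": pm_day1, "pm_lag1": pm_day0,
         "dow12": trailing_dow_mean(past, day1, 12, holidays),
         "dow4": trailing_dow_mean(past, day1, 4, holidays),
         "week_of_year": week_of_year(day1)},
    ]


def forecast_indicator(model: HealthModel, history: pd.Series,
                       pm_fc: ForecastPair, pm_obs_lag1: float,
                       issue_date, holidays=(), hsda_id: str | None = None
                       ) -> ForecastPair:
    """Dispensation ForecastPair for one issue date.

    day0 covariates: (blended day0 PM, observed day-1 PM, trailing means and
    week at the issue date).  day+1 covariates: (blended day+1 PM, blended
    day0 PM, trailing means and week at issue date + 1).  Counts dated on or
    after the issue date are discarded from ``history`` so nothing unobserved
    at issue time can leak in.
    """
    if pm_fc.kind != "pm25":
        raise ValueError("pm_fc must be a PM2.5 forecast pair")
    issue = pd.Timestamp(issue_date)
    past = history.loc[history.index < issue]
    X = pd.DataFrame(substitution_features(past, pm_fc.day0, pm_fc.day1,
                                           pm_obs_lag1, issue, holidays))
    pred = np.clip(model.estimator.predict(X[HEALTH_FEATURES].to_numpy(float)),
                   0.0, None)
    return ForecastPair(hsda_id=hsda_id or pm_fc.hsda_id, issue_date=issue,
                        day0=float(pred[0]), day1=float(pred[1]),
                        kind="indicator")
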