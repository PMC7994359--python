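"""Daily surveillance reports.

Each report pairs the last 21 days of observed-vs-forecast history (PM2.5
comparator and dispensation counts) with the two-day outlook: the range of
blended PM2.5 forecasts over the health area's populated grid cells (the top
of the range is exactly the value fed to the health model) and the
dispensation forecast pair.  Reports serialise to plain JSON for downstream
rendering; styling is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pm_forecast import ForecastPair

__all__ = ["DailyReport", "build_daily_report"]

HISTORY_DAYS = 21


@dataclass
class DailyReport:
    hsda_id: str
    issue_date: pd.Timestamp
    history: pd.DataFrame  # date, pm_obs, pm_fc, count_obs, count_fc
    pm_range_day0: tuple[float, float]
    pm_range_day1: tuple[float, float]
    indicator: ForecastPair
    short_history: bool

    def to_dict(self) -> dict:
        hist = self.history.copy()
        hist["date"] = hist["date"].dt.strftime("%Y-%m-%d")
        return {
            "hsda_id": self.hsda_id,
            "issue_date": self.issue_date.strftime("%Y-%m-%d"),
            "history": hist.round(1).replace({np.nan: None}).to_dict("records"),
            "today": {"pm25_min": round(self.pm_range_day0[0], 1),
                      "pm25_max": round(self.pm_range_day0[1], 1),
                      "indicator": round(self.indicator.day0, 1)},
            "tomorrow": {"pm25_min": round(self.pm_range_day1[0], 1),
                         "pm25_max": round(self.pm_range_day1[1], 1),
                         "indicator": round(self.indicator.day1, 1)},
            "short_history": self.short_history,
        }


def build_daily_report(bundle, results, hsda_id, issue_date) -> DailyReport:
    """Assemble the report for one health area and issue date.

    ``results`` is a SeasonResults; forecasts must exist for the issue date.
    The history window is the 21 dates preceding the issue date (shorter at
    season start, flagged via ``short_history``).
    """
    issue = pd.Timestamp(issue_date)
    pm = results.pm_forecasts
    ind = results.indicator_forecasts
    row = pm[(pm["hsda_id"] == hsda_id) & (pm["issue_date"] == issue)]
    irow = ind[(ind["hsda_id"] == hsda_id) & (ind["issue_date"] == issue)]
    if row.empty or irow.empty:
        raise ValueError(f"no forecasts issued {issue.date()} for {hsda_id!r}")
    row, irow = row.iloc[0], irow.iloc[0]

    season_start = bundle.cfg.window(bundle.cfg.eval_year)[0]
    start = max(issue - pd.Timedelta(days=HISTORY_DAYS), season_start)
    dates = pd.date_range(start, issue - pd.Timedelta(days=1))
    comp = results.comparators.get(hsda_id)
    pm_hist = pm[pm["hsda_id"] == hsda_id].set_index("issue_date")
    ind_hist = ind[ind["hsda_id"] == hsda_id].set_index("issue_date")
    history = pd.DataFrame({
        "date": dates,
        "pm_obs": (comp.reindex(dates).to_numpy() if comp is not None
                   else np.full(len(dates), np.nan)),
        "pm_fc": pm_hist["day0_pm25"].reindex(dates).to_numpy(),
        "count_obs": bundle.indicators[hsda_id].reindex(dates).to_numpy(float),
        "count_fc": ind_hist["day0_count"].reindex(dates).to_numpy(),
    })
    return DailyReport(
        hsda_id=hsda_id, issue_date=issue, history=history,
        pm_range_day0=(float(row["day0_pm25_min"]), float(row["day0_pm25"])),
        pm_range_day1=(float(row["day1_pm25_min"]), float(row["day1_pm25"])),
        indicator=ForecastPair(hsda_id, issue, float(irow["day0_count"]),
                               float(irow["day1_count"]), "indicator"),
        short_history=len(dates) < HISTORY_DAYS,
    )
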