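"""Health forecasting: trailing features, training rules, substitution."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

import smokecast as sc
from smokecast import health as H
from smokecast import metrics as M
from smokecast import pipeline as P
from smokecast.calendars import bc_holidays
from smokecast.pm_forecast import ForecastPair


def series_from(values, start="2018-01-01"):
    return pd.Series(values, index=pd.date_range(start, periods=len(values)))


class TestTrailingDowMean:
    def test_constant_series(self):
        s = series_from([7.0] * 120)
        for k in (4, 12):
            assert H.trailing_dow_mean(s, s.index[100], k) == 7.0

    def test_hand_mean_of_four_weeks(self):
        target = pd.Timestamp("2018-03-05")  # a Monday
        idx = [target - pd.Timedelta(weeks=j) for j in (4, 3, 2, 1)]
        s = pd.Series([10.0, 20.0, 30.0, 40.0], index=pd.DatetimeIndex(idx))
        assert H.trailing_dow_mean(s, target, 4) == 25.0

    def test_holiday_in_lookback_skipped_and_lookback_extended(self):
        target = pd.Timestamp("2018-03-05")
        idx = [target - pd.Timedelta(weeks=j) for j in (5, 4, 3, 2, 1)]
        s = pd.Series([10.0, 20.0, 30.0, 40.0, 50.0],
                      index=pd.DatetimeIndex(idx))
        hols = {(target - pd.Timedelta(weeks=1)).date()}  # drops the 50
        assert H.trailing_dow_mean(s, target, 4, hols) == 25.0

    def test_holiday_target_uses_recent_sundays(self):
        # counts: Sundays 5, everything else 50
        idx = pd.date_range("2018-05-01", "2018-09-01")
        s = pd.Series(np.where(idx.dayofweek == 6, 5.0, 50.0), index=idx)
        labour_day = pd.Timestamp("2018-09-03")  # Monday holiday
        assert H.trailing_dow_mean(s, labour_day, 4,
                                   bc_holidays(2018)) == pytest.approx(5.0)

    def test_insufficient_history_warns_then_errors(self):
        s = series_from([3.0] * 15)
        with pytest.warns(UserWarning, match="qualifying"):
            assert H.trailing_dow_mean(s, s.index[-1] + pd.Timedelta(days=1),
                                       4) == 3.0
        with pytest.raises(ValueError):
            H.trailing_dow_mean(s, s.index[0], 4)


class TestWeekOfYear:
    @pytest.mark.parametrize("date,week", [
        ("2018-01-01", 1), ("2018-12-31", 1),  # ISO week of the next year
        ("2018-08-15", 33),
    ])
    def test_iso_weeks(self, date, week):
        assert H.week_of_year(date) == week

    def test_seven_days_apart_differ_by_one_within_year(self):
        for d in pd.date_range("2018-02-01", "2018-11-01", freq="17D"):
            assert (H.week_of_year(d + pd.Timedelta(weeks=1))
                    - H.week_of_year(d)) == 1


class TestBuildHealthTable:
    @staticmethod
    def make_inputs(n=250, seed=0):
        rng = np.random.default_rng(seed)
        idx = pd.date_range("2018-01-01", periods=n)
        exposure = pd.Series(rng.uniform(2, 10, n), index=idx)
        counts = pd.Series(rng.poisson(40, n).astype(float), index=idx)
        return counts, exposure

    def test_threshold_filter_keeps_all_smoky_dates(self):
        counts, exposure = self.make_inputs()
        smoky = exposure.index[180:190]
        exposure[smoky] = 60.0
        table = H.build_health_table(counts, exposure, low_sample_frac=0.0)
        assert set(table["date"]) == set(smoky)

    def test_sample_frac_one_keeps_every_eligible_date(self):
        counts, exposure = self.make_inputs()
        t0 = H.build_health_table(counts, exposure, low_sample_frac=1.0)
        # eligible dates: those with a full 12-week same-weekday lookback
        # (the 84-day head); every such date also has a day-1 exposure
        assert len(t0) == len(counts) - 12 * 7

    def test_same_seed_reproduces_row_set(self):
        counts, exposure = self.make_inputs()
        t1 = H.build_health_table(counts, exposure, low_sample_frac=0.3, seed=4)
        t2 = H.build_health_table(counts, exposure, low_sample_frac=0.3, seed=4)
        pd.testing.assert_frame_equal(t1, t2)
        t3 = H.build_health_table(counts, exposure, low_sample_frac=0.3, seed=5)
        assert not t1["date"].equals(t3["date"])


def feature_rows(n, seed, signal="dow4"):
    rng = np.random.default_rng(seed)
    rows = pd.DataFrame({
        "pm_day0": rng.uniform(0, 100, n),
        "pm_lag1": rng.uniform(0, 100, n),
        "dow12": rng.uniform(5, 60, n),
        "dow4": rng.uniform(5, 60, n),
        "week_of_year": rng.integers(1, 54, n).astype(float),
    })
    rows["target"] = rows[signal]
    return rows


class TestFitHealthModel:
    def test_perfect_signal(self):
        m = H.fit_health_model(feature_rows(1500, 0), n_trees=300, seed=0)
        assert m.oob_pseudo_r2 >= 0.95

    def test_permuted_target(self):
        rows = feature_rows(800, 1)
        rows["target"] = rows["target"].sample(frac=1, random_state=3).to_numpy()
        m = H.fit_health_model(rows, n_trees=300, seed=0)
        assert m.oob_pseudo_r2 <= 0.1

    def test_determinism(self):
        rows = feature_rows(200, 2)
        assert (H.fit_health_model(rows, n_trees=150, seed=8).oob_rmse
                == H.fit_health_model(rows, n_trees=150, seed=8).oob_rmse)


@pytest.fixture(scope="module")
def weekday_world():
    """Counts driven purely by day-of-week; PM is irrelevant noise."""
    rng = np.random.default_rng(3)
    idx = pd.date_range("2017-06-01", "2018-08-14")
    weekly = np.array([40.0, 40, 40, 40, 38, 12, 8])
    counts = pd.Series(weekly[idx.dayofweek], index=idx)
    exposure = pd.Series(rng.uniform(2, 40, len(idx)), index=idx)
    table = H.build_health_table(counts, exposure, low_sample_frac=1.0,
                                 seed=0)
    model = H.fit_health_model(table, n_trees=300, seed=0)
    return model, counts


class TestForecastIndicator:

    def test_day0_tracks_weekday_mean(self, weekday_world):
        model, counts = weekday_world
        issue = pd.Timestamp("2018-08-15")  # a Wednesday
        fc = H.forecast_indicator(
            model, counts, ForecastPair("X", issue, 20.0, 20.0, "pm25"),
            pm_obs_lag1=15.0, issue_date=issue, hsda_id="X")
        expected = H.trailing_dow_mean(counts[counts.index < issue], issue, 4)
        assert abs(fc.day0 - expected) <= 0.1 * expected

    def test_constant_world_day0_equals_day1(self, weekday_world):
        model, _ = weekday_world
        counts = series_from([30.0] * 400, start="2017-07-01")
        issue = pd.Timestamp("2018-07-20")
        fc = H.forecast_indicator(
            model, counts, ForecastPair("X", issue, 20.0, 20.0, "pm25"),
            pm_obs_lag1=20.0, issue_date=issue, hsda_id="X")
        assert fc.day0 == pytest.approx(fc.day1, rel=0.05)
        assert fc.day0 >= 0 and fc.day1 >= 0

    def test_substitution_scheme_feature_structure(self):
        """Between day0 and day1 rows only the two PM covariates and the
        date-derived features of issue+1 may differ."""
        counts = series_from(list(np.tile([40, 40, 40, 40, 38, 12, 8], 60)),
                             start="2017-06-05")
        issue = pd.Timestamp("2018-06-20")
        rows = H.substitution_features(counts[counts.index < issue],
                                       pm_day0=33.0, pm_day1=44.0,
                                       pm_obs_lag1=11.0, issue=issue)
        d0, d1 = rows
        assert (d0["pm_day0"], d0["pm_lag1"]) == (33.0, 11.0)
        assert (d1["pm_day0"], d1["pm_lag1"]) == (44.0, 33.0)
        nxt = issue + pd.Timedelta(days=1)
        past = counts[counts.index < issue]
        assert d1["dow12"] == H.trailing_dow_mean(past, nxt, 12)
        assert d1["dow4"] == H.trailing_dow_mean(past, nxt, 4)
        assert d1["week_of_year"] == H.week_of_year(nxt)


class TestSmokeResponseRecovery:
    """Behavioural recovery of the generating exposure-response."""

    N_REPLICATES = 20

    @staticmethod
    def smoky_minus_clean(seed: int, beta: float) -> float:
        """Mean forecast difference between smoky days and matched clean
        same-weekday days of the evaluation season (exposure fed directly,
        isolating the health model from the PM blend)."""
        cfg = sc.ScenarioConfig(seed=seed, beta_pm=beta)
        bundle = sc.make_scenario(cfg)
        model = P.train_health(bundle, seed=seed)
        hols = bundle.holidays
        rows = []
        for h in bundle.geography.hsda_ids:
            exp = bundle.exposures[h]
            counts = bundle.indicators[h]
            window = cfg.window(cfg.eval_year)
            smoky = [d for d in window if exp[d] > 30 and d.date() not in hols]
            clean = {d.dayofweek: d for d in window
                     if exp[d] < 10 and d.date() not in hols}
            for d in smoky:
                if d.dayofweek not in clean:
                    continue
                for day in (d, clean[d.dayofweek]):
                    past = counts[counts.index < day]
                    pm = float(min(exp[day], 150))
                    rows.append(H.substitution_features(
                        past, pm, pm,
                        float(exp[day - pd.Timedelta(days=1)]), day, hols)[0])
        X = pd.DataFrame(rows)[H.HEALTH_FEATURES].to_numpy(float)
        pred = model.estimator.predict(X)
        return float(np.mean(pred[0::2] - pred[1::2]))

    def test_fitted_model_responds_to_smoke(self):
        from scipy import stats

        beta = sc.ScenarioConfig().beta_pm
        deltas = [self.smoky_minus_clean(seed, beta)
                  for seed in range(self.N_REPLICATES)]
        t = stats.ttest_1samp(deltas, 0.0, alternative="greater")
        assert t.pvalue < 0.01, deltas

    def test_no_response_when_generator_has_none(self):
        from scipy import stats

        deltas = [self.smoky_minus_clean(seed, 0.0)
                  for seed in range(self.N_REPLICATES)]
        t = stats.ttest_1samp(deltas, 0.0)
        assert t.pvalue > 0.01, deltas
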