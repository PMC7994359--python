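"""Seeded synthetic smoke seasons.

Generates complete, internally consistent inputs for the whole pipeline with
no external data: a planar geography (health areas, dissemination areas,
grid, monitors), episodic gridded smoke fields with satellite-style
covariates, noisy monitor observations, a biased numerical 48-h smoke
forecast, and Poisson dispensation counts with a log-linear PM2.5 response
and strong day-of-week structure.

Every generator is a pure function of (config, seed).  The statistical truth
is recoverable by construction: monitor observations are the closed-form
truth field at the station location plus additive Gaussian noise, and counts
are drawn from the stated rate model, so tests can check each stage of the
pipeline against known parameters.

The default configuration emulates an extreme smoke season over a
desk-scale province: 4 health areas on a 100 x 100 km domain, a 5 km grid,
a 63-day mid-July to mid-September evaluation season preceded by two
equally smoky training seasons, and a dispensation response calibrated so
that a season averaging ~22 ug/m3 above background carries ~30% excess
dispensations.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calendars import resolve_holidays
from .geo import Geography

__all__ = [
    "ScenarioConfig",
    "ScenarioBundle",
    "simulate_geography",
    "simulate_smoke_fields",
    "simulate_firework",
    "simulate_dispensations",
    "make_scenario",
]

_SUBSTREAMS = ("geometry", "episodes", "background", "monitor", "aod", "vi",
               "firework", "counts")


@dataclass
class ScenarioConfig:
    """Full parameterisation of a synthetic smoke scenario."""

    seed: int = 0
    geometry_seed: int | None = None  # defaults to seed; fix to share geography

    # geography
    n_hsdas: int = 4
    das_per_hsda: int = 150  # ~82k residents/HSDA, the smallest real BC HSDA
    da_population_range: tuple[int, int] = (400, 700)
    n_stations_per_hsda: int = 3
    n_vi_stations: int = 8
    extent_km: float = 100.0
    cell_km: float = 5.0

    # calendar: last year is the evaluation season, earlier years are history
    years: tuple[int, ...] = (2016, 2017, 2018)
    season_start: str = "07-15"  # month-day
    season_end: str = "09-15"
    indicator_warmup_days: int = 182

    # smoke episodes (per season window)
    n_episodes: int = 4
    episode_duration_days: tuple[int, int] = (10, 21)
    episode_peak_range: tuple[float, float] = (60.0, 150.0)
    spatial_decay_km: float = 35.0

    # background and measurement
    background_pm: float = 4.0
    background_sd_log: float = 0.25
    monitor_noise_sd: float = 1.5

    # satellite-style covariates
    aod_scale: float = 0.02     # AOD per ug/m3
    aod_noise_sd: float = 0.03
    aod_availability: float = 0.7
    frp_per_peak: float = 10.0  # MW of fire radiative power per ug/m3 of episode peak
    hms_threshold: float = 20.0

    # numerical smoke forecast emulation
    forecast_bias: float = 2.0       # multiplicative, near episode centres
    forecast_noise_sd_log: float = 0.3

    # dispensation model
    dow_multipliers: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 0.95, 0.45, 0.30)
    holidays: object = "bc"
    holiday_multiplier: float = 0.35
    base_rate: float = 4.5           # dispensations per 10,000 per weekday
    beta_pm: float = math.log(1.3) / 22.0  # log count increase per ug/m3
    overdispersion: float = 0.0      # gamma mixing variance; 0 = pure Poisson

    def __post_init__(self) -> None:
        if self.extent_km <= 0 or self.cell_km <= 0:
            raise ValueError("extent and cell size must be positive")
        if self.extent_km / self.cell_km != int(self.extent_km / self.cell_km):
            raise ValueError("extent_km must be a multiple of cell_km")
        if any(m <= 0 for m in self.dow_multipliers) or len(self.dow_multipliers) != 7:
            raise ValueError("dow_multipliers must be 7 positive values")
        if self.base_rate < 0 or self.holiday_multiplier < 0:
            raise ValueError("rates must be non-negative")

    @property
    def eval_year(self) -> int:
        return self.years[-1]

    def window(self, year: int) -> pd.DatetimeIndex:
        return pd.date_range(f"{year}-{self.season_start}", f"{year}-{self.season_end}")

    def field_dates(self, year: int) -> pd.DatetimeIndex:
        """Dates with gridded fields: season window padded one day each side.

        The pad supplies day-1 predictors for the first issue and day+1
        verification for the last issue.
        """
        w = self.window(year)
        return pd.date_range(w[0] - pd.Timedelta(days=1), w[-1] + pd.Timedelta(days=1))

    def indicator_dates(self, year: int) -> pd.DatetimeIndex:
        w = self.window(year)
        return pd.date_range(w[0] - pd.Timedelta(days=self.indicator_warmup_days),
                             w[-1] + pd.Timedelta(days=1))

    def holiday_set(self) -> set[dt.date]:
        return resolve_holidays(self.holidays, self.years)

    def substream(self, name: str) -> np.random.Generator:
        """Independent, named random substream so components decouple.

        Geometry honours ``geometry_seed`` so two scenarios can share a
        geography while differing in everything stochastic.
        """
        if name not in _SUBSTREAMS:
            raise KeyError(name)
        base = self.geometry_seed if (name == "geometry" and self.geometry_seed
                                      is not None) else self.seed
        return np.random.default_rng(
            np.random.SeedSequence(entropy=int(base),
                                   spawn_key=(_SUBSTREAMS.index(name),)))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        for k in ("da_population_range", "years", "episode_duration_days",
                  "episode_peak_range", "dow_multipliers"):
            if k in d and isinstance(d[k], list):
                d[k] = tuple(d[k])
        if isinstance(d.get("holidays"), list):
            d["holidays"] = list(d["holidays"])
        return cls(**d)


@dataclass
class Episode:
    center: tuple[float, float]
    start: pd.Timestamp
    duration_days: int
    peak: float  # ug/m3 added at the centre on the peak day

    def temporal(self, dates: pd.DatetimeIndex) -> np.ndarray:
        """Triangular profile: 0 at start and end, 1 at the midpoint."""
        mid = (self.start + pd.Timedelta(days=self.duration_days / 2)).to_numpy()
        half = self.duration_days / 2
        offs = (dates.to_numpy() - mid) / np.timedelta64(1, "D")
        return np.clip(1.0 - np.abs(offs) / half, 0.0, None)

    def spatial(self, xy: np.ndarray, decay_km: float) -> np.ndarray:
        d2 = ((np.asarray(xy, float) - np.asarray(self.center)) ** 2).sum(axis=1)
        return np.exp(-d2 / (2.0 * decay_km**2))


@dataclass
class SmokeFields:
    """Daily truth and covariate fields on the grid, all years concatenated."""

    truth_cells: pd.DataFrame      # index date, columns cell_id; uncapped truth
    background: pd.Series          # index date (indicator range), ug/m3
    episodes: list[Episode]
    hms: pd.DataFrame              # same shape as truth_cells, {0,1}
    aod: pd.DataFrame              # columns: date, x_km, y_km, aod
    frp: pd.DataFrame              # columns: date, x_km, y_km, frp_mw
    vi_stations: pd.DataFrame      # columns: vi_id, x_km, y_km
    vi: pd.DataFrame               # index date, columns vi_id; integers 1-100

    def truth_at(self, xy: np.ndarray, dates: pd.DatetimeIndex,
                 cfg: "ScenarioConfig") -> np.ndarray:
        """Closed-form truth field at arbitrary points, shape (n_dates, n_pts)."""
        out = np.repeat(self.background.reindex(dates).to_numpy()[:, None],
                        len(xy), axis=1)
        for ep in self.episodes:
            out += np.outer(ep.temporal(dates), ep.spatial(xy, cfg.spatial_decay_km)
                            ) * ep.peak
        return out


@dataclass
class ScenarioBundle:
    """Everything one synthetic scenario produced, ready for the pipeline."""

    cfg: ScenarioConfig
    geography: Geography
    fields: SmokeFields
    observations: pd.DataFrame              # station_id, date, pm25 (uncapped)
    firework: dict                          # issue_date -> (n_cells, 48) hourly
    exposures: dict                         # hsda -> pd.Series pop-weighted truth
    indicators: dict                        # hsda -> pd.Series integer counts

    @property
    def holidays(self) -> set[dt.date]:
        return self.cfg.holiday_set()

    def truth_capped(self, cap: float = 150.0) -> pd.DataFrame:
        """The historic exposure-model view of the field: truth capped at
        the reporting limit, as an observation-based gridded product would
        deliver it."""
        return self.fields.truth_cells.clip(upper=cap)


def simulate_geography(cfg: ScenarioConfig, seed: int | None = None) -> Geography:
    """Planar geography: clustered DAs per HSDA quadrant, monitors at towns.

    HSDAs tile the domain as equal vertical bands split into two rows when
    even; DAs cluster around a few town centres per HSDA; each HSDA receives
    at least one monitoring station, placed at (jittered) DA locations so
    stations sit where people live.
    """
    rng = (np.random.default_rng(seed) if seed is not None
           else cfg.substream("geometry"))
    n_side = int(round(cfg.extent_km / cfg.cell_km))
    xs = (np.arange(n_side) + 0.5) * cfg.cell_km
    gx, gy = np.meshgrid(xs, xs)
    cells = pd.DataFrame({
        "cell_id": [f"C{i:04d}" for i in range(n_side * n_side)],
        "x_km": gx.ravel(), "y_km": gy.ravel(),
    })

    # equal rectangular blocks for the HSDAs
    ncol = int(math.ceil(math.sqrt(cfg.n_hsdas)))
    nrow = int(math.ceil(cfg.n_hsdas / ncol))
    bw, bh = cfg.extent_km / ncol, cfg.extent_km / nrow
    das, stations = [], []
    lo, hi = cfg.da_population_range
    for h in range(cfg.n_hsdas):
        hsda_id = f"H{h + 1:02d}"
        r, c = divmod(h, ncol)
        x0, y0 = c * bw, r * bh
        n_towns = max(1, rng.integers(2, 5))
        towns = np.column_stack([rng.uniform(x0 + 5, x0 + bw - 5, n_towns),
                                 rng.uniform(y0 + 5, y0 + bh - 5, n_towns)])
        which = rng.integers(0, n_towns, cfg.das_per_hsda)
        xy = towns[which] + rng.normal(0, 4.0, (cfg.das_per_hsda, 2))
        xy = np.clip(xy, 0.5, cfg.extent_km - 0.5)
        for j in range(cfg.das_per_hsda):
            das.append((f"DA{h + 1:02d}{j:03d}", xy[j, 0], xy[j, 1],
                        int(rng.integers(lo, hi + 1)), hsda_id))
        picks = rng.choice(cfg.das_per_hsda, size=min(cfg.n_stations_per_hsda,
                                                      cfg.das_per_hsda),
                           replace=False)
        for k, j in enumerate(sorted(picks)):
            sxy = np.clip(xy[j] + rng.normal(0, 1.0, 2), 0.5, cfg.extent_km - 0.5)
            stations.append((f"S{h + 1:02d}{k:02d}", sxy[0], sxy[1]))

    return Geography(
        das=pd.DataFrame(das, columns=["da_id", "x_km", "y_km", "population",
                                       "hsda_id"]),
        cells=cells,
        stations=pd.DataFrame(stations, columns=["station_id", "x_km", "y_km"]),
    )


def _union_dates(indexes) -> pd.DatetimeIndex:
    out = None
    for ix in indexes:
        out = ix if out is None else out.union(ix)
    return pd.DatetimeIndex(out.unique().sort_values())


def _draw_episodes(cfg: ScenarioConfig, rng: np.random.Generator) -> list[Episode]:
    eps = []
    for year in cfg.years:
        w = cfg.window(year)
        for _ in range(cfg.n_episodes):
            dur = int(rng.integers(cfg.episode_duration_days[0],
                                   cfg.episode_duration_days[1] + 1))
            start_off = int(rng.integers(0, max(1, len(w) - dur)))
            eps.append(Episode(
                center=(float(rng.uniform(0, cfg.extent_km)),
                        float(rng.uniform(0, cfg.extent_km))),
                start=w[start_off],
                duration_days=dur,
                peak=float(rng.uniform(*cfg.episode_peak_range)),
            ))
    return eps


def simulate_smoke_fields(cfg: ScenarioConfig, geo: Geography,
                          seed: int | None = None) -> SmokeFields:
    """Daily gridded truth plus the satellite-style covariates.

    Truth is background (day-varying, log-normal around ``background_pm``)
    plus a sum of episode plumes, each Gaussian in space and triangular in
    time.  AOD is proportional to truth with noise and partial availability;
    FRP points sit at active episode centres; the plume flag marks cells with
    truth above ``hms_threshold``; the venting index is lower on smoky days.
    """
    ep_rng = np.random.default_rng(seed) if seed is not None else cfg.substream("episodes")
    bg_rng = cfg.substream("background")
    aod_rng = cfg.substream("aod")
    vi_rng = cfg.substream("vi")

    episodes = _draw_episodes(cfg, ep_rng)

    f_dates = _union_dates(cfg.field_dates(y) for y in cfg.years)
    bg_dates = _union_dates([f_dates] + [cfg.indicator_dates(y)
                                         for y in cfg.years])
    background = pd.Series(
        cfg.background_pm * np.exp(bg_rng.normal(0.0, cfg.background_sd_log,
                                                 len(bg_dates))),
        index=bg_dates, name="background")
    cell_xy = geo.cells[["x_km", "y_km"]].to_numpy()
    truth = np.repeat(background.reindex(f_dates).to_numpy()[:, None],
                      len(cell_xy), axis=1)
    for ep in episodes:
        truth += np.outer(ep.temporal(f_dates),
                          ep.spatial(cell_xy, cfg.spatial_decay_km)) * ep.peak
    truth_cells = pd.DataFrame(truth, index=f_dates,
                               columns=geo.cells["cell_id"].to_list())

    hms = (truth_cells > cfg.hms_threshold).astype(int)

    # AOD: per cell-day, available with probability aod_availability
    avail = aod_rng.random(truth.shape) < cfg.aod_availability
    aod_vals = np.clip(cfg.aod_scale * truth
                       + aod_rng.normal(0, cfg.aod_noise_sd, truth.shape), 0, None)
    di, ci = np.nonzero(avail)
    aod = pd.DataFrame({
        "date": f_dates[di], "x_km": cell_xy[ci, 0], "y_km": cell_xy[ci, 1],
        "aod": aod_vals[di, ci],
    })

    # FRP points at active episode centres, power tracking the plume profile
    frp_rows = []
    for ep in episodes:
        t = ep.temporal(f_dates)
        for d, w in zip(f_dates[t > 0], t[t > 0]):
            frp_rows.append((d, ep.center[0], ep.center[1],
                             cfg.frp_per_peak * ep.peak * w))
    frp = pd.DataFrame(frp_rows, columns=["date", "x_km", "y_km", "frp_mw"])

    # venting index: low when the domain is smoky (stagnant air)
    vi_xy = vi_rng.uniform(0, cfg.extent_km, (cfg.n_vi_stations, 2))
    vi_stations = pd.DataFrame({
        "vi_id": [f"V{i:02d}" for i in range(cfg.n_vi_stations)],
        "x_km": vi_xy[:, 0], "y_km": vi_xy[:, 1],
    })
    smoke_level = (truth_cells.mean(axis=1) - background.reindex(f_dates)).to_numpy()
    vi_raw = (70.0 - 1.5 * smoke_level[:, None]
              + vi_rng.normal(0, 12.0, (len(f_dates), cfg.n_vi_stations)))
    vi = pd.DataFrame(np.clip(np.round(vi_raw), 1, 100).astype(int),
                      index=f_dates, columns=vi_stations["vi_id"].to_list())

    return SmokeFields(truth_cells=truth_cells, background=background,
                       episodes=episodes, hms=hms, aod=aod, frp=frp,
                       vi_stations=vi_stations, vi=vi)


def simulate_observations(cfg: ScenarioConfig, geo: Geography,
                          fields: SmokeFields) -> pd.DataFrame:
    """Monitor records: truth at the station location plus Gaussian noise.

    Observations are never capped; negative draws (possible only on the very
    cleanest days) are floored at zero.
    """
    rng = cfg.substream("monitor")
    st_xy = geo.stations[["x_km", "y_km"]].to_numpy()
    dates = fields.truth_cells.index
    truth = fields.truth_at(st_xy, dates, cfg)
    obs = np.maximum(truth + rng.normal(0, cfg.monitor_noise_sd, truth.shape), 0.0)
    long = pd.DataFrame(obs, index=dates, columns=geo.stations["station_id"]
                        ).rename_axis("date").reset_index().melt(
        id_vars="date", var_name="station_id", value_name="pm25")
    return long.sort_values(["station_id", "date"]).reset_index(drop=True)


def simulate_firework(cfg: ScenarioConfig, geo: Geography, fields: SmokeFields,
                      seed: int | None = None) -> dict:
    """Hourly 48-h numerical smoke forecasts for every issue date.

    For each issue date and horizon the target daily mean is the truth field
    times a multiplicative bias (``forecast_bias`` at episode centres,
    decaying to 1 with distance, active only while the episode burns) times
    log-normal error; the 24 hourly values follow a sinusoidal diurnal shape
    whose mean is exactly that daily target.  Issue dates are all season-window
    days of every year.

    The log-normal error is drawn once per issue and horizon, shared across
    the grid: dispersion-model errors are spatially coherent (a mis-forecast
    plume is wrong everywhere at once), and independent per-cell error would
    make any maximum-over-cells extraction inflate with grid size, an
    artifact the emulated forecast system does not have.
    """
    rng = np.random.default_rng(seed) if seed is not None else cfg.substream("firework")
    cell_xy = geo.cells[["x_km", "y_km"]].to_numpy()
    diurnal = 1.0 + 0.3 * np.sin(2 * np.pi * (np.arange(1, 25) - 0.5) / 24.0)

    out = {}
    for year in cfg.years:
        dates = cfg.field_dates(year)
        truth = fields.truth_at(cell_xy, dates, cfg)
        bias = np.ones_like(truth)
        for ep in fields.episodes:
            active = (ep.temporal(dates) > 0).astype(float)
            bias += np.outer(active, ep.spatial(cell_xy, cfg.spatial_decay_km)
                             ) * (cfg.forecast_bias - 1.0)
        daily = truth * bias
        pos = {d: i for i, d in enumerate(dates)}
        for d in cfg.window(year):
            m0 = daily[pos[d]] * np.exp(
                rng.normal(0, cfg.forecast_noise_sd_log))
            m1 = daily[pos[d + pd.Timedelta(days=1)]] * np.exp(
                rng.normal(0, cfg.forecast_noise_sd_log))
            hourly = np.empty((len(cell_xy), 48))
            hourly[:, :24] = m0[:, None] * diurnal
            hourly[:, 24:] = m1[:, None] * diurnal
            out[d] = hourly
    return out


def simulate_dispensations(cfg: ScenarioConfig, exposures: dict,
                           populations: dict, seed: int | None = None) -> dict:
    """Daily dispensation counts per health area.

    count(h, d) ~ Poisson(lambda) with
    lambda = base_rate * pop/10,000 * dow(weekday) * holiday(d)
             * exp(beta_pm * PM(h, d)).
    With ``overdispersion`` v > 0, lambda is gamma-mixed (shape 1/v) giving a
    negative-binomial marginal.
    """
    rng = np.random.default_rng(seed) if seed is not None else cfg.substream("counts")
    hols = cfg.holiday_set()
    dow = np.asarray(cfg.dow_multipliers, float)
    out = {}
    for h in sorted(exposures):
        pm = exposures[h]
        lam = (cfg.base_rate * populations[h] / 1e4
               * dow[pm.index.dayofweek]
               * np.where([d.date() in hols for d in pm.index],
                          cfg.holiday_multiplier, 1.0)
               * np.exp(cfg.beta_pm * pm.to_numpy()))
        if np.any(lam > 1e9):
            raise ValueError("dispensation rate overflow; check beta_pm/exposures")
        if cfg.overdispersion > 0:
            shape = 1.0 / cfg.overdispersion
            lam = rng.gamma(shape, lam / shape)
        out[h] = pd.Series(rng.poisson(lam), index=pm.index, name="count")
    return out


def make_scenario(cfg: ScenarioConfig) -> ScenarioBundle:
    """Compose all simulators into a complete scenario bundle."""
    geo = simulate_geography(cfg)
    fields = simulate_smoke_fields(cfg, geo)
    observations = simulate_observations(cfg, geo, fields)
    firework = simulate_firework(cfg, geo, fields)

    # population-weighted truth exposure per HSDA over the full indicator
    # range; outside the gridded window every cell equals background, so the
    # weighted mean is the background itself.
    exposures = {}
    ind_dates = _union_dates(cfg.indicator_dates(y) for y in cfg.years)
    for h in geo.hsda_ids:
        series = fields.background.reindex(ind_dates).copy()
        es = geo.pop_weighted_exposure(fields.truth_cells, h)
        common = es.series.index.intersection(ind_dates)
        series.loc[common] = es.series.loc[common]
        exposures[h] = series.rename("pm25")

    populations = {h: geo.hsda_population(h) for h in geo.hsda_ids}
    indicators = simulate_dispensations(cfg, exposures, populations)
    return ScenarioBundle(cfg=cfg, geography=geo, fields=fields,
                          observations=observations, firework=firework,
                          exposures=exposures, indicators=indicators)
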