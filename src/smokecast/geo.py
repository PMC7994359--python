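"""Geography, nearest-neighbour predictor assembly and exposure aggregation.

The spatial world is planar: coordinates are kilometres on an arbitrary
origin and distances are Euclidean.  Projecting real geography onto such a
plane is the caller's responsibility; the built-in synthetic scenarios are
generated directly in planar coordinates.

Administrative structure follows the British Columbia pattern: dissemination
areas (DAs, census units of roughly 400-700 residents) nest inside Health
Service Delivery Areas (HSDAs), the geographic unit of forecasting.  Gridded
PM2.5 fields live on a 5 x 5 km grid; a DA takes the value of the grid cell
whose centroid is nearest its own centroid, and a cell is "populated" when at
least one DA centroid maps to it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "PM_CAP",
    "Station",
    "GridCell",
    "DisseminationArea",
    "HealthArea",
    "ExposureSeries",
    "Geography",
    "nearest_value",
    "nearest_index",
    "radius_mean",
    "pop_weighted_mean",
    "hsda_forecast_exposure",
    "cap_pm",
    "station_comparator_series",
]

#: Reporting cap on modelled/blended PM2.5 concentrations (ug/m3).
PM_CAP = 150.0


@dataclass(frozen=True)
class Station:
    station_id: str
    x_km: float
    y_km: float


@dataclass(frozen=True)
class GridCell:
    cell_id: str
    x_km: float
    y_km: float
    populated: bool


@dataclass(frozen=True)
class DisseminationArea:
    da_id: str
    x_km: float
    y_km: float
    population: int
    hsda_id: str


@dataclass(frozen=True)
class HealthArea:
    hsda_id: str
    name: str
    population: int


@dataclass
class ExposureSeries:
    """Daily PM2.5 exposure for one health area.

    ``kind`` distinguishes the population-weighted mean over DAs, the maximum
    over populated grid cells (the worst-case value fed to health forecasts),
    and the monitoring-station comparator used for verification.
    """

    hsda_id: str
    series: pd.Series  # index: dates, values: ug/m3
    kind: str  # "population_weighted" | "hsda_max" | "station_comparator"


def _sorted_points(points):
    """Normalise (id, (x, y), value) triples sorted by identifier.

    Sorting by identifier makes every argmin-style lookup break exact
    distance ties toward the lowest identifier.
    """
    pts = sorted(points, key=lambda p: p[0])
    ids = [p[0] for p in pts]
    xy = np.array([p[1] for p in pts], dtype=float).reshape(-1, 2)
    vals = np.array([p[2] for p in pts], dtype=float)
    return ids, xy, vals


def nearest_value(location, points, max_radius: float | None = None):
    """Value of the point nearest to ``location``; None outside ``max_radius``.

    ``points`` is an iterable of (identifier, (x, y), value); ties in distance
    are broken by the lowest identifier.  Returns None when no point
    qualifies.
    """
    if max_radius is not None and max_radius < 0:
        raise ValueError("max_radius must be non-negative")
    points = list(points)
    if not points:
        return None
    _, xy, vals = _sorted_points(points)
    d = np.hypot(*(xy - np.asarray(location, dtype=float)).T)
    i = int(np.argmin(d))
    if max_radius is not None and d[i] > max_radius:
        return None
    return float(vals[i])


def nearest_index(query_xy: np.ndarray, ref_xy: np.ndarray) -> np.ndarray:
    """Index of the nearest reference point for each query point (KD-tree).

    Callers must pass ``ref_xy`` sorted by identifier when the lowest-id tie
    rule matters; the KD-tree returns the smallest index among exact ties.
    """
    tree = cKDTree(np.asarray(ref_xy, dtype=float))
    return tree.query(np.asarray(query_xy, dtype=float))[1]


def radius_mean(location, points, radius: float) -> float:
    """Mean value of points within ``radius`` km (boundary inclusive); 0 if none.

    Used for fire radiative power, where the absence of any fire within range
    genuinely means zero radiative power.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    points = list(points)
    if not points:
        return 0.0
    _, xy, vals = _sorted_points(points)
    d = np.hypot(*(xy - np.asarray(location, dtype=float)).T)
    inside = d <= radius
    if not inside.any():
        return 0.0
    return float(vals[inside].mean())


def pop_weighted_mean(values: dict, populations: dict) -> float:
    """Population-weighted mean: sum(value * pop) / sum(pop) over shared keys."""
    if not values:
        raise ValueError("no values to weight")
    if set(values) != set(populations):
        raise ValueError("values and populations must share the same keys")
    keys = list(values)
    v = np.array([values[k] for k in keys], dtype=float)
    w = np.array([populations[k] for k in keys], dtype=float)
    if (w <= 0).any():
        raise ValueError("populations must be positive")
    return float(np.sum(v * w) / np.sum(w))


def hsda_forecast_exposure(cell_values: dict, populated_cells) -> float:
    """Maximum forecast value over the populated grid cells of one HSDA.

    The maximum (rather than the population-weighted mean) is used so that
    health forecasts reflect the worst-case exposure in the area.
    """
    ids = [c.cell_id if isinstance(c, GridCell) else c for c in populated_cells]
    if not ids:
        raise ValueError("HSDA has no populated cells")
    return float(max(cell_values[i] for i in ids))


def cap_pm(value, cap: float = PM_CAP):
    """Cap modelled PM2.5 at ``cap`` (default 150 ug/m3); rejects negatives.

    Accepts scalars or arrays.
    """
    arr = np.asarray(value, dtype=float)
    if (arr < 0).any():
        raise ValueError("PM2.5 must be non-negative")
    out = np.minimum(arr, cap)
    return float(out) if np.isscalar(value) or arr.ndim == 0 else out


@dataclass
class Geography:
    """Study geography: DA centroids, grid cells, monitors, health areas.

    ``das``      columns: da_id, x_km, y_km, population, hsda_id
    ``cells``    columns: cell_id, x_km, y_km (plus derived: populated, da count)
    ``stations`` columns: station_id, x_km, y_km
    """

    das: pd.DataFrame
    cells: pd.DataFrame
    stations: pd.DataFrame
    hsda_names: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.das = self.das.sort_values("da_id").reset_index(drop=True)
        self.cells = self.cells.sort_values("cell_id").reset_index(drop=True)
        self.stations = self.stations.sort_values("station_id").reset_index(drop=True)
        if self.das["da_id"].duplicated().any():
            raise ValueError("duplicate da_id")
        if self.cells["cell_id"].duplicated().any():
            raise ValueError("duplicate cell_id")
        if (self.das["population"] <= 0).any():
            raise ValueError("DA populations must be positive")
        # nearest-centroid assignment of DAs to grid cells
        self.das["cell_id"] = self.cells["cell_id"].to_numpy()[
            nearest_index(self.das[["x_km", "y_km"]].to_numpy(),
                          self.cells[["x_km", "y_km"]].to_numpy())
        ]
        self.cells["populated"] = self.cells["cell_id"].isin(self.das["cell_id"]).to_numpy()

    @property
    def hsda_ids(self) -> list:
        return sorted(self.das["hsda_id"].unique())

    def hsda_population(self, hsda_id) -> int:
        pop = int(self.das.loc[self.das["hsda_id"] == hsda_id, "population"].sum())
        if pop == 0:
            raise KeyError(f"unknown hsda_id {hsda_id!r}")
        return pop

    def health_areas(self) -> list[HealthArea]:
        return [
            HealthArea(h, self.hsda_names.get(h, str(h)), self.hsda_population(h))
            for h in self.hsda_ids
        ]

    def populated_cells(self, hsda_id) -> list:
        """Populated cells of one HSDA: cells claimed by at least one of its DAs."""
        ids = sorted(self.das.loc[self.das["hsda_id"] == hsda_id, "cell_id"].unique())
        if not ids:
            raise ValueError(f"HSDA {hsda_id!r} has no populated cells")
        return ids

    def stations_in_hsda(self, hsda_id) -> pd.DataFrame:
        """Stations assigned to an HSDA: those nearest to one of its DAs.

        With point geography there are no HSDA polygons; a station belongs to
        the HSDA whose DA centroid is nearest to it.
        """
        if self.stations.empty:
            return self.stations
        idx = nearest_index(self.stations[["x_km", "y_km"]].to_numpy(),
                            self.das[["x_km", "y_km"]].to_numpy())
        owner = self.das["hsda_id"].to_numpy()[idx]
        return self.stations[owner == hsda_id].reset_index(drop=True)

    def pop_weighted_exposure(self, cell_values: pd.DataFrame, hsda_id) -> ExposureSeries:
        """Population-weighted daily exposure of one HSDA from a gridded field.

        ``cell_values``: DataFrame indexed by date with one column per cell_id.
        Each DA contributes its assigned cell's value weighted by population.
        """
        das = self.das[self.das["hsda_id"] == hsda_id]
        if das.empty:
            raise KeyError(f"unknown hsda_id {hsda_id!r}")
        w = das.groupby("cell_id")["population"].sum()
        vals = cell_values[w.index.to_list()]
        series = vals.mul(w.to_numpy(), axis=1).sum(axis=1) / w.sum()
        return ExposureSeries(hsda_id, series.rename("pm25"), "population_weighted")


def station_comparator_series(
    geo: Geography,
    hsda_id,
    observations: pd.DataFrame,
    weighting: str = "population",
) -> ExposureSeries | None:
    """Daily station-based exposure comparator for one HSDA.

    ``observations`` columns: station_id, date, pm25 (raw 24-h means, never
    capped).  With ``weighting="population"`` each station is weighted by the
    total population of the HSDA's DAs for which it is the nearest station;
    ``weighting="simple"`` averages stations equally.  Returns None (with a
    warning) for an HSDA without stations, which is then excluded from PM
    verification rather than aborting the run.
    """
    if weighting not in ("population", "simple"):
        raise ValueError("weighting must be 'population' or 'simple'")
    stations = geo.stations_in_hsda(hsda_id)
    if stations.empty:
        warnings.warn(f"HSDA {hsda_id!r} has no stations; excluded from PM verification")
        return None
    das = geo.das[geo.das["hsda_id"] == hsda_id]
    if weighting == "population":
        assigned = stations["station_id"].to_numpy()[
            nearest_index(das[["x_km", "y_km"]].to_numpy(),
                          stations[["x_km", "y_km"]].to_numpy())
        ]
        weights = (
            pd.Series(das["population"].to_numpy(), index=assigned)
            .groupby(level=0).sum()
            .reindex(stations["station_id"], fill_value=0).astype(float)
        )
    else:
        weights = pd.Series(1.0, index=stations["station_id"])
    obs = observations[observations["station_id"].isin(stations["station_id"])]
    wide = obs.pivot_table(index="date", columns="station_id", values="pm25")
    w = weights.reindex(wide.columns).to_numpy()
    mask = wide.notna().to_numpy()
    wsum = (mask * w).sum(axis=1)
    with np.errstate(invalid="ignore"):
        series = pd.Series(
            np.nansum(wide.to_numpy() * w, axis=1) / np.where(wsum > 0, wsum, np.nan),
            index=wide.index, name="pm25",
        ).dropna()
    return ExposureSeries(hsda_id, series, "station_comparator")
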