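"""File interfaces: scenario CSV bundles, configs, and stamped outputs.

All on-disk formats are plain text: delimited CSV for tabular data (ISO-8601
dates, concentrations in ug/m3), YAML for configuration, JSON for summaries
and reports.  Output files written by the pipeline carry a header comment
with the tool version, a hash of the generating configuration, and the
seeds, so any artifact can be traced back to its exact run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geo import Geography
from .synthetic import ScenarioBundle, ScenarioConfig, SmokeFields

__all__ = [
    "config_hash",
    "file_header",
    "write_csv",
    "read_csv",
    "write_json",
    "load_config",
    "write_scenario",
    "read_scenario",
]


def config_hash(cfg: ScenarioConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def file_header(cfg: ScenarioConfig) -> str:
    return (f"# smokecast v{__version__} | config sha256:{config_hash(cfg)}"
            f" | seed={cfg.seed} geometry_seed={cfg.geometry_seed}\n")


def write_csv(df: pd.DataFrame, path, cfg: ScenarioConfig) -> None:
    path = Path(path)
    with path.open("w") as f:
        f.write(file_header(cfg))
        # %.17g guarantees float64 round-trips bit-exactly through the file
        df.to_csv(f, index=False, float_format="%.17g")


def read_csv(path, **kw) -> pd.DataFrame:
    # round_trip parsing so written float64 values come back bit-exact
    return pd.read_csv(path, comment="#", float_precision="round_trip", **kw)


def write_json(obj: dict, path, cfg: ScenarioConfig) -> None:
    payload = {"meta": {"tool": f"smokecast v{__version__}",
                        "config_sha256": config_hash(cfg),
                        "seed": cfg.seed, "geometry_seed": cfg.geometry_seed},
               **obj}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True,
                                     default=str) + "\n")


def load_config(path) -> tuple[ScenarioConfig, dict]:
    """Read config.yaml: a ``scenario`` section plus run parameters."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = ScenarioConfig.from_dict(raw.get("scenario", {}))
    run = raw.get("run", {})
    return cfg, run


def _dates(col: pd.Series) -> pd.DatetimeIndex:
    return pd.DatetimeIndex(pd.to_datetime(col))


def write_scenario(bundle: ScenarioBundle, outdir) -> None:
    """Write every scenario input file (the formats the pipeline consumes)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg, geo, f = bundle.cfg, bundle.geography, bundle.fields
    W = lambda df, name: write_csv(df, out / name, cfg)

    W(geo.stations, "stations.csv")
    W(geo.das[["da_id", "x_km", "y_km", "population", "hsda_id"]], "das.csv")
    W(geo.cells[["cell_id", "x_km", "y_km"]], "cells.csv")
    W(bundle.observations.assign(date=bundle.observations["date"].dt.strftime(
        "%Y-%m-%d")), "observations.csv")

    grid = f.truth_cells.rename_axis("date").reset_index().melt(
        id_vars="date", var_name="cell_id", value_name="pm25")
    grid["date"] = grid["date"].dt.strftime("%Y-%m-%d")
    W(grid, "grid_pm25.csv")
    hms = f.hms.rename_axis("date").reset_index().melt(
        id_vars="date", var_name="cell_id", value_name="flag")
    hms["date"] = hms["date"].dt.strftime("%Y-%m-%d")
    W(hms, "hms.csv")
    W(f.aod.assign(date=f.aod["date"].dt.strftime("%Y-%m-%d")), "aod.csv")
    W(f.frp.assign(date=f.frp["date"].dt.strftime("%Y-%m-%d")), "frp.csv")
    W(f.vi_stations, "vi_stations.csv")
    vi = f.vi.rename_axis("date").reset_index().melt(
        id_vars="date", var_name="vi_id", value_name="vi")
    vi["date"] = vi["date"].dt.strftime("%Y-%m-%d")
    W(vi, "vi.csv")

    fw_rows = []
    for issue in sorted(bundle.firework):
        arr = bundle.firework[issue]
        n_cells, _ = arr.shape
        fw_rows.append(pd.DataFrame({
            "cell_id": np.repeat(geo.cells["cell_id"].to_numpy(), 48),
            "issue_date": issue.strftime("%Y-%m-%d"),
            "hour": np.tile(np.arange(1, 49), n_cells),
            "pm25": arr.ravel(),
        }))
    W(pd.concat(fw_rows, ignore_index=True), "firework.csv")

    ind = pd.concat([s.rename("count").rename_axis("date").reset_index()
                     .assign(hsda_id=h) for h, s in bundle.indicators.items()])
    ind["date"] = ind["date"].dt.strftime("%Y-%m-%d")
    W(ind[["hsda_id", "date", "count"]], "indicators.csv")
    exp = pd.concat([s.rename("pm25").rename_axis("date").reset_index()
                     .assign(hsda_id=h) for h, s in bundle.exposures.items()])
    exp["date"] = exp["date"].dt.strftime("%Y-%m-%d")
    W(exp[["hsda_id", "date", "pm25"]], "exposures.csv")

    hols = sorted(bundle.holidays)
    W(pd.DataFrame({"date": [h.isoformat() for h in hols],
                    "name": ["holiday"] * len(hols)}), "holidays.csv")
    (out / "scenario.yaml").write_text(
        yaml.safe_dump({"scenario": cfg.to_dict()}, sort_keys=True))


def read_scenario(outdir) -> ScenarioBundle:
    """Reconstruct a scenario bundle from its file set.

    Generator internals (episode objects, the background series) are not
    stored on disk; the returned bundle carries everything the forecasting
    and evaluation stages consume.
    """
    out = Path(outdir)
    cfg = ScenarioConfig.from_dict(
        yaml.safe_load((out / "scenario.yaml").read_text())["scenario"])
    geo = Geography(
        das=read_csv(out / "das.csv"),
        cells=read_csv(out / "cells.csv"),
        stations=read_csv(out / "stations.csv"),
    )
    obs = read_csv(out / "observations.csv", parse_dates=["date"])

    def wide(name, value, column):
        df = read_csv(out / name, parse_dates=["date"])
        return df.pivot_table(index="date", columns=column, values=value,
                              sort=True)

    truth = wide("grid_pm25.csv", "pm25", "cell_id")
    fields = SmokeFields(
        truth_cells=truth,
        background=pd.Series(dtype=float),
        episodes=[],
        hms=wide("hms.csv", "flag", "cell_id").astype(int),
        aod=read_csv(out / "aod.csv", parse_dates=["date"]),
        frp=read_csv(out / "frp.csv", parse_dates=["date"]),
        vi_stations=read_csv(out / "vi_stations.csv"),
        vi=wide("vi.csv", "vi", "vi_id").astype(int),
    )
    fw = read_csv(out / "firework.csv", parse_dates=["issue_date"])
    cell_order = {c: i for i, c in enumerate(geo.cells["cell_id"])}
    firework = {}
    for issue, grp in fw.groupby("issue_date"):
        arr = np.empty((len(cell_order), 48))
        g = grp.sort_values(["cell_id", "hour"])
        arr[[cell_order[c] for c in g["cell_id"].to_numpy()[::48]], :] = (
            g["pm25"].to_numpy().reshape(-1, 48))
        firework[issue] = arr
    ind = read_csv(out / "indicators.csv", parse_dates=["date"])
    indicators = {h: g.set_index("date")["count"].sort_index()
                  for h, g in ind.groupby("hsda_id")}
    exp = read_csv(out / "exposures.csv", parse_dates=["date"])
    exposures = {h: g.set_index("date")["pm25"].sort_index()
                 for h, g in exp.groupby("hsda_id")}
    return ScenarioBundle(cfg=cfg, geography=geo, fields=fields,
                          observations=obs, firework=firework,
                          exposures=exposures, indicators=indicators)
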