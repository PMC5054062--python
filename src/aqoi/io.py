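"""Readers and writers for the text/NetCDF formats the tool chains together.

Observation and station tables are plain CSV; gridded fields are
self-describing NetCDF rasters (dims ``lat``, ``lon``; one variable per
pollutant; attributes ``units``, ``valid_time``, ``dx_km``) with a CSV
raster dump as a test-friendly alternative; error statistics, bias regions
and run configuration are YAML.  All times are UTC.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .bias import BiasRegion
from .errstats import ErrorStatistics
from .grids import GridField, POLLUTANT_UNITS

log = logging.getLogger(__name__)

OBS_COLUMNS = ["station_id", "lat", "lon", "land_use", "pollutant",
               "time_utc", "value"]


def read_observations(path: Union[str, Path]) -> pd.DataFrame:
    """Read an observation table, rejecting malformed rows with their line
    numbers (header is line 1)."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in OBS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    bad_lines = []
    for col in ("lat", "lon", "value"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        bad_lines += [(i + 2, col) for i in df.index[bad]]
        df[col] = coerced
    bad_lines += [(i + 2, "value") for i in df.index[df["value"].isna()]]
    times = pd.to_datetime(df["time_utc"], errors="coerce", utc=True)
    bad_time = times.isna()
    bad_lines += [(i + 2, "time_utc") for i in df.index[bad_time]]
    df["time_utc"] = times
    drop = df["lat"].isna() | df["lon"].isna() | df["value"].isna() | bad_time
    for line, col in sorted(set(bad_lines)):
        log.warning("%s line %d: malformed %s; row rejected", path, line, col)
    df = df[~drop].reset_index(drop=True)
    df["station_id"] = df["station_id"].astype(str)
    return df


def write_observations(df: pd.DataFrame, path: Union[str, Path]) -> None:
    cols = [c for c in OBS_COLUMNS if c in df.columns]
    cols += [c for c in ("qc_flags", "accepted") if c in df.columns]
    out = df[cols].copy()
    out["time_utc"] = pd.to_datetime(out["time_utc"], utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False)


def _grid_attrs(field: GridField, extra: Optional[dict] = None) -> dict:
    attrs = {"units": field.units, "dx_km": field.dx_km}
    if field.valid_time is not None:
        attrs["valid_time"] = field.valid_time.strftime("%Y-%m-%dT%H:%M:%SZ")
    if extra:
        attrs.update(extra)
    return attrs


def write_grid(field: GridField, path: Union[str, Path],
               attrs: Optional[dict] = None) -> None:
    """Write one field as a NetCDF raster (or CSV if the suffix is .csv)."""
    path = Path(path)
    if path.suffix == ".csv":
        _write_grid_csv(field, path)
        return
    ds = xr.Dataset(
        {field.pollutant: (("lat", "lon"), field.values,
                           _grid_attrs(field, attrs))},
        coords={"lat": field.lats, "lon": field.lons},
    )
    ds.to_netcdf(path, engine="scipy")


def read_grid(path: Union[str, Path],
              pollutant: Optional[str] = None) -> GridField:
    path = Path(path)
    if path.suffix == ".csv":
        return _read_grid_csv(path)
    with xr.open_dataset(path, engine="scipy") as ds:
        names = [v for v in ds.data_vars if v in POLLUTANT_UNITS]
        if pollutant is not None:
            if pollutant not in ds.data_vars:
                raise ValueError(f"{path}: no variable {pollutant!r}")
            name = pollutant
        elif len(names) == 1:
            name = names[0]
        else:
            raise ValueError(
                f"{path}: expected exactly one pollutant variable, "
                f"found {list(ds.data_vars)}"
            )
        var = ds[name]
        units = var.attrs.get("units")
        if units != POLLUTANT_UNITS[name]:
            raise ValueError(
                f"{path}: variable {name} has units {units!r}, "
                f"expected {POLLUTANT_UNITS[name]!r}"
            )
        valid_time = var.attrs.get("valid_time")
        return GridField(
            lats=var["lat"].values.copy(),
            lons=var["lon"].values.copy(),
            values=var.values.copy(),
            pollutant=name,
            valid_time=pd.Timestamp(valid_time) if valid_time else None,
            dx_km=float(var.attrs.get("dx_km", 10.0)),
        )


def _write_grid_csv(field: GridField, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# pollutant: {field.pollutant}\n")
        fh.write(f"# units: {field.units}\n")
        fh.write(f"# dx_km: {field.dx_km}\n")
        if field.valid_time is not None:
            fh.write(f"# valid_time: "
                     f"{field.valid_time.strftime('%Y-%m-%dT%H:%M:%SZ')}\n")
        pd.DataFrame(field.values, index=field.lats,
                     columns=field.lons).to_csv(fh)


def _read_grid_csv(path: Path) -> GridField:
    meta = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
    if "pollutant" not in meta:
        raise ValueError(f"{path}: missing '# pollutant:' header")
    pollutant = meta["pollutant"]
    units = meta.get("units")
    if units != POLLUTANT_UNITS.get(pollutant):
        raise ValueError(
            f"{path}: units {units!r} do not match pollutant {pollutant}"
        )
    body = pd.read_csv(path, skiprows=skip, index_col=0)
    return GridField(
        lats=body.index.to_numpy(dtype=float),
        lons=body.columns.to_numpy(dtype=float),
        values=body.to_numpy(dtype=float),
        pollutant=pollutant,
        valid_time=pd.Timestamp(meta["valid_time"]) if "valid_time" in meta
        else None,
        dx_km=float(meta.get("dx_km", 10.0)),
    )


def write_stats(stats: ErrorStatistics, path: Union[str, Path]) -> None:
    doc = {
        "pollutant": stats.pollutant,
        "stratum": stats.stratum,
        "sigma_b2": float(stats.sigma_b2),
        "lc_km": float(stats.lc_km),
        "source": stats.source,
    }
    for key in ("sigma_b2_by_station", "sigma_o2_by_station",
                "sigma_o2_by_land_use"):
        value = getattr(stats, key)
        if value:
            doc[key] = {str(k): float(v) for k, v in value.items()}
    if stats.sigma_o2_default is not None:
        doc["sigma_o2_default"] = float(stats.sigma_o2_default)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_stats(path: Union[str, Path]) -> ErrorStatistics:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or "sigma_b2" not in doc:
        raise ValueError(f"{path}: not a valid statistics file")
    return ErrorStatistics(
        pollutant=doc["pollutant"],
        stratum=doc.get("stratum", "all"),
        sigma_b2=float(doc["sigma_b2"]),
        lc_km=float(doc["lc_km"]),
        sigma_b2_by_station=doc.get("sigma_b2_by_station"),
        sigma_o2_by_station=doc.get("sigma_o2_by_station"),
        sigma_o2_by_land_use=doc.get("sigma_o2_by_land_use"),
        sigma_o2_default=doc.get("sigma_o2_default"),
        source=doc.get("source", "prescribed"),
    )


def read_regions(path: Union[str, Path]) -> list[BiasRegion]:
    doc = yaml.safe_load(Path(path).read_text())
    regions = []
    for entry in doc:
        regions.append(BiasRegion(
            name=entry["name"],
            vertices=[(float(a), float(b)) for a, b in entry["vertices"]],
            decay_km=float(entry.get("decay_km", 100.0)),
        ))
    return regions


def read_config(path: Union[str, Path]) -> dict:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return doc


def config_hash(path: Union[str, Path]) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_report(report: pd.DataFrame, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for key, value in report.attrs.items():
            fh.write(f"# {key}: {value}\n")
        report.to_csv(fh, index=False)


def four_panel_export(product, out_dir: Union[str, Path],
                      prefix: str = "", quicklook: bool = False,
                      attrs: Optional[dict] = None) -> dict:
    """Write the four panels of an analysis product.

    Forecast, analysis and increment rasters plus the table of observations
    that were ingested; optionally a quick-look PNG of the four panels.
    Returns the paths written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    p = f"{prefix}_" if prefix else ""
    paths = {}
    for name, field in (("forecast", product.forecast),
                        ("analysis", product.analysis),
                        ("increment", product.increment)):
        paths[name] = out_dir / f"{p}{name}.nc"
        write_grid(field, paths[name], attrs=attrs)
    innov = product.innovations
    obs_df = pd.DataFrame({
        "station_id": [s.id for s in innov.stations],
        "lat": [s.lat for s in innov.stations],
        "lon": [s.lon for s in innov.stations],
        "land_use": [s.land_use for s in innov.stations],
        "pollutant": innov.pollutant,
        "time_utc": innov.valid_time,
        "value": innov.y_o,
    })
    paths["observations"] = out_dir / f"{p}observations.csv"
    write_observations(obs_df, paths["observations"])
    if quicklook:
        paths["quicklook"] = out_dir / f"{p}quicklook.png"
        _quicklook(product, paths["quicklook"])
    return paths


def _quicklook(product, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(10, 8), constrained_layout=True)
    innov = product.innovations
    extent = [product.forecast.lons[0], product.forecast.lons[-1],
              product.forecast.lats[0], product.forecast.lats[-1]]
    panels = [("forecast", product.forecast.values),
              ("analysis", product.analysis.values),
              ("increment", product.increment.values)]
    for ax, (title, values) in zip(axes.ravel(), panels):
        im = ax.imshow(values, origin="lower", extent=extent, aspect="auto")
        ax.set_title(title)
        fig.colorbar(im, ax=ax)
    ax = axes.ravel()[3]
    sc = ax.scatter([s.lon for s in innov.stations],
                    [s.lat for s in innov.stations],
                    c=innov.y_o, s=12)
    ax.set_xlim(extent[0], extent[1])
    ax.set_ylim(extent[2], extent[3])
    ax.set_title("observations")
    fig.colorbar(sc, ax=ax)
    fig.suptitle(f"{product.forecast.pollutant} "
                 f"{product.forecast.valid_time or ''}")
    fig.savefig(path, dpi=100)
    plt.close(fig)
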