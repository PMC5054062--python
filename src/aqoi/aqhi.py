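"""Air Quality Health Index (AQHI).

The Canadian AQHI combines NO2, O3 (ppbv) and PM2.5 (µg/m³) into a single
health-risk number:

    AQHI = (10/10.4) · 100 · [(e^(0.000871·NO2) − 1)
                              + (e^(0.000537·O3) − 1)
                              + (e^(0.000487·PM2.5) − 1)]

computed on 3-h running mean concentrations and reported in integer risk
categories (Low 1–3, Moderate 4–6, High 7–10, Extreme > 10).  Because the
exponents are small at ambient levels, the index is nearly the linear
combination (0.871·NO2 + 0.537·O3 + 0.487·PM2.5)/10.4; for mixtures in
which the three pollutants contribute equally and the index stays at or
below 10, the linearization undershoots by less than 2 %.

Gridded AQHI is produced as a *pseudo* objective analysis: the exact formula
is applied cellwise to the three pollutant analyses rather than assimilating
AQHI observations directly.
"""

from __future__ import annotations

from typing import Mapping, Optional

import numpy as np
import pandas as pd
import xarray as xr

from .grids import GridField

#: Risk coefficients per unit concentration.
C_NO2 = 0.000871   # per ppbv
C_O3 = 0.000537    # per ppbv
C_PM25 = 0.000487  # per µg/m³
SCALE = 10.0 / 10.4
AMPLIFICATION = 100.0

CATEGORY_BOUNDS = {"Low": (1, 3), "Moderate": (4, 6), "High": (7, 10)}


def _check_nonneg(*arrays) -> None:
    for a in arrays:
        if np.any(np.asarray(a, dtype=float) < 0):
            raise ValueError("concentrations must be non-negative")


def aqhi_exact(no2, o3, pm25):
    """Exact (exponential) AQHI; strictly increasing in each pollutant."""
    _check_nonneg(no2, o3, pm25)
    no2, o3, pm25 = (np.asarray(a, dtype=float) for a in (no2, o3, pm25))
    total = (
        np.expm1(C_NO2 * no2) + np.expm1(C_O3 * o3) + np.expm1(C_PM25 * pm25)
    )
    out = SCALE * AMPLIFICATION * total
    return out if out.ndim else float(out)


def aqhi_linear(no2, o3, pm25):
    """Linearized AQHI: (0.871·NO2 + 0.537·O3 + 0.487·PM2.5)/10.4."""
    _check_nonneg(no2, o3, pm25)
    no2, o3, pm25 = (np.asarray(a, dtype=float) for a in (no2, o3, pm25))
    out = (0.871 * no2 + 0.537 * o3 + 0.487 * pm25) / 10.4
    return out if out.ndim else float(out)


def categorize(aqhi_value: float) -> str:
    """Health-risk category of an AQHI value.

    The value is rounded half-up to the nearest integer with a floor of 1
    (the reporting convention), then banded: 1–3 Low, 4–6 Moderate,
    7–10 High, above 10 Extreme.
    """
    if aqhi_value < 0:
        raise ValueError("AQHI must be non-negative")
    rounded = max(int(np.floor(aqhi_value + 0.5)), 1)
    for label, (lo, hi) in CATEGORY_BOUNDS.items():
        if lo <= rounded <= hi:
            return label
    return "Extreme"


def rolling_3h(series: pd.Series) -> pd.Series:
    """Trailing 3-h running mean (current hour and the two previous).

    The series must be indexed by UTC timestamps.  Windows touching a
    missing hour yield NaN — a partial window is not a 3-h average.
    """
    series = series.sort_index()
    full = pd.date_range(series.index[0], series.index[-1], freq="1h",
                         tz=series.index.tz)
    regular = series.reindex(full)
    return regular.rolling(window=3, min_periods=3).mean()


def aqhi_map(
    analysis_no2: GridField,
    analysis_o3: GridField,
    analysis_pm25: GridField,
) -> tuple[GridField, GridField]:
    """Pseudo objective analysis of AQHI from three co-registered analyses.

    Returns the exact-formula AQHI grid and the residual grid
    (exact − linear), the latter showing where the linearization matters.
    """
    for f, want in ((analysis_no2, "NO2"), (analysis_o3, "O3"),
                    (analysis_pm25, "PM2.5")):
        if f.pollutant != want:
            raise ValueError(f"expected {want} analysis, got {f.pollutant}")
    if not (analysis_no2.same_grid(analysis_o3)
            and analysis_no2.same_grid(analysis_pm25)):
        raise ValueError("the three analyses must share one grid")
    times = {f.valid_time for f in (analysis_no2, analysis_o3, analysis_pm25)}
    if len(times) > 1:
        raise ValueError(f"the three analyses must share one valid time, got {times}")
    # concentrations can go slightly negative near strong negative increments;
    # clip at zero before applying the index
    no2 = np.clip(analysis_no2.values, 0.0, None)
    o3 = np.clip(analysis_o3.values, 0.0, None)
    pm25 = np.clip(analysis_pm25.values, 0.0, None)
    exact = aqhi_exact(no2, o3, pm25)
    residual = exact - aqhi_linear(no2, o3, pm25)
    meta = dict(lats=analysis_no2.lats, lons=analysis_no2.lons,
                pollutant="AQHI", valid_time=analysis_no2.valid_time,
                dx_km=analysis_no2.dx_km)
    return GridField(values=exact, **meta), GridField(values=residual, **meta)


SEASONS = ("DJF", "MAM", "JJA", "SON")


def exceedance_climatology(
    aqhi_grids: xr.DataArray,
    threshold: float = 3.0,
    below_percent: float = 1.0,
) -> xr.Dataset:
    """Percent of hours with AQHI strictly above ``threshold``, per season.

    ``aqhi_grids`` has dims (time, lat, lon) with hourly UTC timestamps.
    Returns a Dataset with ``percent`` (season, lat, lon) and a boolean
    ``below`` marking cells under ``below_percent`` % — the map convention
    for effectively unpolluted areas.
    """
    if "time" not in aqhi_grids.dims or aqhi_grids.sizes.get("time", 0) == 0:
        raise ValueError("need a non-empty time dimension")
    exceed = (aqhi_grids > threshold)
    valid = aqhi_grids.notnull()
    season = aqhi_grids["time"].dt.season
    pct = (
        100.0 * exceed.groupby(season).sum("time")
        / valid.groupby(season).sum("time")
    )
    pct = pct.reindex(season=[s for s in SEASONS if s in pct["season"].values])
    if pct.sizes["season"] == 0:
        raise ValueError("no season has any valid hours")
    return xr.Dataset({"percent": pct, "below": pct < below_percent})
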