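"""Core spatial containers: regular lat/lon rasters and monitoring stations."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: Units per pollutant. Gas concentrations are mixing ratios (ppbv),
#: particulate matter is a mass density (µg/m³), AQHI is dimensionless.
POLLUTANT_UNITS = {
    "O3": "ppbv",
    "NO2": "ppbv",
    "PM2.5": "ug/m3",
    "PM10": "ug/m3",
    "AQHI": "1",
}

LAND_USE_CLASSES = ("rural", "suburban", "urban")


def _check_pollutant(pollutant: str) -> str:
    if pollutant not in POLLUTANT_UNITS:
        raise ValueError(
            f"unknown pollutant {pollutant!r}; expected one of {sorted(POLLUTANT_UNITS)}"
        )
    return pollutant


@dataclass
class GridField:
    """One pollutant field at one valid time on a regular lat/lon grid.

    Coordinates are cell centers in degrees, strictly increasing.  Missing
    cells are NaN.  ``dx_km`` is the nominal horizontal resolution of the
    model that produced (or is emulated by) the field; it enters the
    representativeness error model through the effective resolution n·Δx.
    """

    lats: np.ndarray
    lons: np.ndarray
    values: np.ndarray
    pollutant: str
    valid_time: Optional[pd.Timestamp] = None
    dx_km: float = 10.0

    def __post_init__(self) -> None:
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        _check_pollutant(self.pollutant)
        if self.lats.ndim != 1 or self.lons.ndim != 1:
            raise ValueError("lats and lons must be one-dimensional")
        if np.any(np.diff(self.lats) <= 0) or np.any(np.diff(self.lons) <= 0):
            raise ValueError("grid coordinates must be strictly increasing")
        if self.values.shape != (self.lats.size, self.lons.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"(len(lats), len(lons)) = {(self.lats.size, self.lons.size)}"
            )
        if not self.dx_km > 0:
            raise ValueError("dx_km must be positive")
        if self.valid_time is not None:
            self.valid_time = pd.Timestamp(self.valid_time)
            if self.valid_time.tzinfo is None:
                self.valid_time = self.valid_time.tz_localize("UTC")

    @property
    def units(self) -> str:
        return POLLUTANT_UNITS[self.pollutant]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def with_values(self, values: np.ndarray) -> "GridField":
        """Same grid and metadata, different payload."""
        return replace(self, values=np.asarray(values, dtype=float))

    def same_grid(self, other: "GridField", atol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.lats, other.lats, atol=atol)
            and np.allclose(self.lons, other.lons, atol=atol)
        )


@dataclass(frozen=True)
class Station:
    """A ground monitoring site with its land-use (representativeness) class."""

    id: str
    lat: float
    lon: float
    land_use: str = "rural"
    region: Optional[str] = None

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"station {self.id}: latitude {self.lat} out of range")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"station {self.id}: longitude {self.lon} out of range")
        if self.land_use not in LAND_USE_CLASSES:
            raise ValueError(
                f"station {self.id}: land_use {self.land_use!r} not in {LAND_USE_CLASSES}"
            )


def stations_to_frame(stations: Sequence[Station]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "station_id": [s.id for s in stations],
            "lat": [s.lat for s in stations],
            "lon": [s.lon for s in stations],
            "land_use": [s.land_use for s in stations],
        }
    )


def stations_from_frame(df: pd.DataFrame) -> list[Station]:
    return [
        Station(
            id=str(r.station_id),
            lat=float(r.lat),
            lon=float(r.lon),
            land_use=str(getattr(r, "land_use", "rural")),
        )
        for r in df.itertuples(index=False)
    ]
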