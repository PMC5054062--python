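"""Regional forecast bias correction.

Systematic model offsets are estimated as the spatial mean innovation over
the stations inside a user-defined region and added to the forecast there.
Outside the region the correction decays exponentially with distance to the
boundary, so the corrected field stays continuous with no abrupt edges.
When regions overlap or compete, the nearest region wins — corrections are
never double-added.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import Point, Polygon

from .geo import great_circle_km
from .grids import GridField
from .oi import InnovationVector

log = logging.getLogger(__name__)

#: Maximum spacing (km) of the sampled boundary points used for
#: distance-to-boundary computations.
BOUNDARY_SAMPLE_KM = 5.0

KM_PER_DEGREE = 111.195  # mean meridional degree on the 6371-km sphere


@dataclass
class BiasRegion:
    """A closed lat/lon polygon with an e-folding decay scale outside it."""

    name: str
    vertices: Sequence[tuple[float, float]]  # (lat, lon) pairs
    decay_km: float = 100.0

    def __post_init__(self) -> None:
        if not self.decay_km > 0:
            raise ValueError("decay_km must be positive")
        self._polygon = Polygon([(lon, lat) for lat, lon in self.vertices])
        if not self._polygon.is_valid:
            raise ValueError(f"region {self.name}: polygon is self-intersecting")
        # boundary sampled finely enough that the nearest sample is within
        # BOUNDARY_SAMPLE_KM of the true nearest boundary point
        ring = self._polygon.exterior
        n = max(int(np.ceil(ring.length * KM_PER_DEGREE / BOUNDARY_SAMPLE_KM)), 8)
        pts = [ring.interpolate(i / n, normalized=True) for i in range(n)]
        self._boundary_lats = np.array([p.y for p in pts])
        self._boundary_lons = np.array([p.x for p in pts])

    def contains(self, lat, lon) -> np.ndarray:
        """Point-in-polygon (boundary counts as inside)."""
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        return np.array([
            self._polygon.covers(Point(x, y)) for y, x in zip(lat, lon)
        ])

    def distance_km(self, lat, lon) -> np.ndarray:
        """Great-circle distance to the region: 0 inside, else distance to
        the nearest sampled boundary point."""
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        d = great_circle_km(
            lat[:, None], lon[:, None],
            self._boundary_lats[None, :], self._boundary_lons[None, :],
        ).min(axis=1)
        d[self.contains(lat, lon)] = 0.0
        return d


def estimate_regional_bias(
    innov: InnovationVector,
    region: BiasRegion,
    min_stations: int = 5,
) -> Optional[float]:
    """Mean innovation (O − P) over QC-accepted stations inside the region.

    Returns None (with a log line) when fewer than ``min_stations`` stations
    fall inside — too few to trust a regional mean.
    """
    if len(innov) == 0:
        return None
    lats = np.array([s.lat for s in innov.stations])
    lons = np.array([s.lon for s in innov.stations])
    inside = region.contains(lats, lons)
    if inside.sum() < min_stations:
        log.warning("region %s: only %d station(s) inside (min %d); "
                    "no bias correction", region.name, int(inside.sum()),
                    min_stations)
        return None
    return float(innov.d[inside].mean())


def apply_bias_field(
    forecast: GridField,
    region_biases: Sequence[tuple[BiasRegion, float]],
) -> GridField:
    """Add the regional bias corrections to the forecast.

    Inside a region the full bias b = mean(O − P) is added (driving the mean
    innovation toward zero); outside, b·exp(−d/decay_km) with d the distance
    to the nearest boundary point.  With several regions, each grid point
    takes the correction of its nearest region only.
    """
    if not region_biases:
        return forecast
    glat, glon = np.meshgrid(forecast.lats, forecast.lons, indexing="ij")
    flat_lat, flat_lon = glat.ravel(), glon.ravel()
    dists = np.stack([
        region.distance_km(flat_lat, flat_lon) for region, _ in region_biases
    ])
    nearest = np.argmin(dists, axis=0)
    d_near = dists[nearest, np.arange(flat_lat.size)]
    biases = np.array([b for _, b in region_biases])
    decays = np.array([r.decay_km for r, _ in region_biases])
    correction = biases[nearest] * np.exp(-d_near / decays[nearest])
    return forecast.with_values(
        forecast.values + correction.reshape(forecast.shape)
    )
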