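"""Great-circle geometry on the sphere used for all station/grid distances."""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0


def great_circle_km(lat1, lon1, lat2, lon2):
    """Haversine distance in km between points given in degrees.

    Broadcasts over array inputs. Coordinates outside [-90, 90] x [-180, 180]
    are rejected.
    """
    lat1, lon1, lat2, lon2 = (np.asarray(a, dtype=float) for a in (lat1, lon1, lat2, lon2))
    for lat in (lat1, lat2):
        if np.any(np.abs(lat) > 90.0):
            raise ValueError("latitude out of range [-90, 90]")
    for lon in (lon1, lon2):
        if np.any(np.abs(lon) > 180.0):
            raise ValueError("longitude out of range [-180, 180]")
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2) - np.radians(lon1)
    h = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    # clip guards against round-off slightly above 1 for antipodal points
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    return d if d.ndim else float(d)


def pairwise_distances_km(lats, lons, lats2=None, lons2=None):
    """Distance matrix (n, m) between two point sets (or one set with itself)."""
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    if lats2 is None:
        lats2, lons2 = lats, lons
    lats2 = np.asarray(lats2, dtype=float)
    lons2 = np.asarray(lons2, dtype=float)
    return great_circle_km(
        lats[:, None], lons[:, None], lats2[None, :], lons2[None, :]
    )
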