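"""Optimal-interpolation analysis update.

The analysis is x^a = x^f + K(y^o − H x^f) with the gain applied in
observation space: the station-space innovation (covariance) matrix
A = H(HB)ᵀ + R is built from a homogeneous isotropic exponential background
error correlation and a diagonal observation error covariance, factorized
once by Cholesky, and the resulting weights are spread back to the grid
through the same exponential covariance.  Error statistics are stationary
within an hourly stratum but may differ between hours and seasons, which is
what lets the analysis follow the diurnal cycle of surface pollution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .errstats import ErrorStatistics
from .geo import great_circle_km, pairwise_distances_km
from .grids import GridField, Station

log = logging.getLogger(__name__)

#: Stations closer than this are merged into one pseudo-station before the
#: innovation matrix is built, to protect positive definiteness.
COLOCATION_KM = 1.0


@dataclass
class InnovationVector:
    """QC-accepted observations and the forecast at their locations."""

    stations: list[Station]
    y_o: np.ndarray
    h_xf: np.ndarray
    pollutant: str
    valid_time: Optional[pd.Timestamp] = None

    def __post_init__(self) -> None:
        self.y_o = np.asarray(self.y_o, dtype=float)
        self.h_xf = np.asarray(self.h_xf, dtype=float)
        if not (len(self.stations) == self.y_o.size == self.h_xf.size):
            raise ValueError("stations, y_o and h_xf must have equal length")

    @property
    def d(self) -> np.ndarray:
        """Innovations y^o − H x^f (OmP)."""
        return self.y_o - self.h_xf

    def __len__(self) -> int:
        return len(self.stations)


@dataclass
class AnalysisProduct:
    """Forecast, analysis and increment on one grid, plus the observations
    used — the four panels of the standard analysis product."""

    forecast: GridField
    analysis: GridField
    increment: GridField
    innovations: InnovationVector
    qc_counts: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)


def interpolate_to_stations(
    field: GridField, stations: Sequence[Station]
) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear interpolation of a grid field to station locations.

    Returns (values, inside) where ``inside`` marks stations within the grid
    hull; values outside are NaN and the exclusions are logged, never
    extrapolated.
    """
    lats = np.array([s.lat for s in stations], dtype=float)
    lons = np.array([s.lon for s in stations], dtype=float)
    glat, glon = field.lats, field.lons
    inside = (
        (lats >= glat[0]) & (lats <= glat[-1])
        & (lons >= glon[0]) & (lons <= glon[-1])
    )
    values = np.full(lats.shape, np.nan)
    if inside.any():
        iy = np.clip(np.searchsorted(glat, lats[inside], side="right") - 1,
                     0, glat.size - 2)
        ix = np.clip(np.searchsorted(glon, lons[inside], side="right") - 1,
                     0, glon.size - 2)
        ty = (lats[inside] - glat[iy]) / (glat[iy + 1] - glat[iy])
        tx = (lons[inside] - glon[ix]) / (glon[ix + 1] - glon[ix])
        v = field.values
        values[inside] = (
            v[iy, ix] * (1 - ty) * (1 - tx)
            + v[iy + 1, ix] * ty * (1 - tx)
            + v[iy, ix + 1] * (1 - ty) * tx
            + v[iy + 1, ix + 1] * ty * tx
        )
    for s, ok in zip(stations, inside):
        if not ok:
            log.info("station %s at (%.3f, %.3f) outside grid; excluded",
                     s.id, s.lat, s.lon)
    return values, inside


def merge_colocated(
    innov: InnovationVector, min_km: float = COLOCATION_KM
) -> InnovationVector:
    """Average observations of stations closer than ``min_km`` into one
    pseudo-station (keeps the innovation matrix positive definite)."""
    n = len(innov)
    if n < 2:
        return innov
    lats = np.array([s.lat for s in innov.stations])
    lons = np.array([s.lon for s in innov.stations])
    dist = pairwise_distances_km(lats, lons)
    group = np.arange(n)
    for i in range(n):
        for j in range(i + 1, n):
            if dist[i, j] < min_km:
                group[group == group[j]] = group[i]
    if len(np.unique(group)) == n:
        return innov
    stations, y_o, h_xf = [], [], []
    for g in np.unique(group):
        members = np.flatnonzero(group == g)
        k = members[0]
        s = innov.stations[k]
        if members.size > 1:
            merged_ids = "+".join(innov.stations[m].id for m in members)
            log.info("merging co-located stations %s", merged_ids)
            s = Station(id=merged_ids, lat=s.lat, lon=s.lon,
                        land_use=s.land_use, region=s.region)
        stations.append(s)
        y_o.append(innov.y_o[members].mean())
        h_xf.append(innov.h_xf[members].mean())
    return InnovationVector(
        stations=stations, y_o=np.array(y_o), h_xf=np.array(h_xf),
        pollutant=innov.pollutant, valid_time=innov.valid_time,
    )


def build_innovation_matrix(
    innov: InnovationVector, stats: ErrorStatistics
) -> np.ndarray:
    """Station-space covariance A = H(HB)ᵀ + R.

    Off-diagonal: σf(k1)·σf(k2)·exp(−d/Lc); diagonal adds the observation
    error variance.  Verified symmetric positive definite by a trial
    Cholesky, with one jitter retry before failing loudly.
    """
    stations = innov.stations
    n = len(stations)
    sf = np.array([stats.sigma_f_station(s) for s in stations])
    so2 = np.array([stats.sigma_o2_station(s) for s in stations])
    if np.any(sf <= 0) or np.any(so2 <= 0):
        raise ValueError("all error std devs/variances must be positive")
    lats = np.array([s.lat for s in stations])
    lons = np.array([s.lon for s in stations])
    dist = pairwise_distances_km(lats, lons)
    A = np.outer(sf, sf) * np.exp(-dist / stats.lc_km)
    A[np.diag_indices(n)] = sf ** 2 + so2
    try:
        np.linalg.cholesky(A)
    except np.linalg.LinAlgError:
        jitter = 1e-8 * np.trace(A) / n
        A_j = A + jitter * np.eye(n)
        try:
            np.linalg.cholesky(A_j)
            log.warning("innovation matrix needed diagonal jitter %.3g", jitter)
            return A_j
        except np.linalg.LinAlgError:
            off = dist + np.diag(np.full(n, np.inf))
            i, j = np.unravel_index(np.argmin(off), off.shape)
            raise np.linalg.LinAlgError(
                "innovation matrix not positive definite even after jitter; "
                f"closest station pair: {stations[i].id} and {stations[j].id} "
                f"({off[i, j]:.3f} km apart)"
            )
    return A


def solve_weights(A: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Solve A·w = d by Cholesky factorization."""
    d = np.asarray(d, dtype=float)
    c, low = cho_factor(A)
    w = cho_solve((c, low), d)
    resid = np.linalg.norm(A @ w - d)
    if resid > 1e-8 * max(np.linalg.norm(d), 1e-30):
        raise np.linalg.LinAlgError(
            f"Cholesky solve residual {resid:.3e} exceeds tolerance"
        )
    return w


def apply_gain(
    forecast: GridField,
    innov: InnovationVector,
    w: np.ndarray,
    stats: ErrorStatistics,
) -> AnalysisProduct:
    """Spread the solved weights back to the grid.

    increment(i,j) = Σ_k σf_grid · σf(k) · exp(−d((i,j),k)/Lc) · w_k, with
    the grid-side σf homogeneous (the domain mean) and the station-side σf
    local.  Far from all stations the increment decays to zero and the
    analysis relaxes to the forecast.
    """
    if innov.pollutant != forecast.pollutant:
        raise ValueError(
            f"pollutant mismatch: grid {forecast.pollutant}, "
            f"observations {innov.pollutant}"
        )
    if (innov.valid_time is not None and forecast.valid_time is not None
            and innov.valid_time != forecast.valid_time):
        raise ValueError(
            f"valid time mismatch: grid {forecast.valid_time}, "
            f"observations {innov.valid_time}"
        )
    w = np.asarray(w, dtype=float)
    sf_grid = float(np.sqrt(stats.sigma_b2))
    if len(innov) == 0:
        increment = np.zeros(forecast.shape)
    else:
        sf_k = np.array([stats.sigma_f_station(s) for s in innov.stations])
        slat = np.array([s.lat for s in innov.stations])
        slon = np.array([s.lon for s in innov.stations])
        glat2, glon2 = np.meshgrid(forecast.lats, forecast.lons, indexing="ij")
        dist = great_circle_km(
            glat2.ravel()[:, None], glon2.ravel()[:, None],
            slat[None, :], slon[None, :],
        )
        hb = sf_grid * sf_k[None, :] * np.exp(-dist / stats.lc_km)
        increment = (hb @ w).reshape(forecast.shape)
    analysis = forecast.with_values(forecast.values + increment)
    inc_field = GridField(
        lats=forecast.lats, lons=forecast.lons, values=increment,
        pollutant=forecast.pollutant, valid_time=forecast.valid_time,
        dx_km=forecast.dx_km,
    )
    return AnalysisProduct(
        forecast=forecast, analysis=analysis, increment=inc_field,
        innovations=innov,
    )


def increment_at_points(
    lats: np.ndarray,
    lons: np.ndarray,
    innov: InnovationVector,
    w: np.ndarray,
    stats: ErrorStatistics,
) -> np.ndarray:
    """Analysis increment evaluated directly at arbitrary points.

    Used for holdout-station verification without paying for a full-grid
    gain application.
    """
    lats = np.atleast_1d(np.asarray(lats, dtype=float))
    lons = np.atleast_1d(np.asarray(lons, dtype=float))
    if len(innov) == 0:
        return np.zeros(lats.shape)
    sf_grid = float(np.sqrt(stats.sigma_b2))
    sf_k = np.array([stats.sigma_f_station(s) for s in innov.stations])
    slat = np.array([s.lat for s in innov.stations])
    slon = np.array([s.lon for s in innov.stations])
    dist = great_circle_km(lats[:, None], lons[:, None],
                           slat[None, :], slon[None, :])
    hb = sf_grid * sf_k[None, :] * np.exp(-dist / stats.lc_km)
    return hb @ np.asarray(w, dtype=float)


def analyze(
    forecast: GridField,
    observations: pd.DataFrame,
    stats: ErrorStatistics,
    qc_config: Optional["QCConfig"] = None,
    bias_regions: Optional[Sequence["BiasRegion"]] = None,
) -> AnalysisProduct:
    """Full single-hour, single-pollutant analysis pipeline.

    QC → optional regional bias correction of the forecast → innovations →
    innovation-matrix build and Cholesky solve → gain application.  The
    observation table may span several hours (the hourly-jump check needs
    history); only records matching the forecast's pollutant and valid time
    enter the analysis.  With zero accepted observations the analysis equals
    the (bias-corrected) forecast and a warning is emitted.
    """
    from .qc import QCConfig, apply_qc
    from .bias import apply_bias_field, estimate_regional_bias

    if qc_config is None:
        qc_config = QCConfig()
    obs = observations[observations["pollutant"] == forecast.pollutant].copy()
    if obs.empty:
        raise ValueError(f"no observations for pollutant {forecast.pollutant}")
    obs["time_utc"] = pd.to_datetime(obs["time_utc"], utc=True)

    stations = {}
    for r in obs[["station_id", "lat", "lon", "land_use"]].drop_duplicates(
            "station_id").itertuples(index=False):
        stations[str(r.station_id)] = Station(
            id=str(r.station_id), lat=float(r.lat), lon=float(r.lon),
            land_use=str(r.land_use),
        )

    # forecast at stations for the background check, this hour only
    station_list = list(stations.values())
    h_all, inside = interpolate_to_stations(forecast, station_list)
    fcst_at = {s.id: v for s, v, ok in zip(station_list, h_all, inside) if ok}
    n_outside = int((~inside).sum())

    qc_obs, qc_counts = apply_qc(obs, qc_config, stats=stats,
                                 forecast_at_station=fcst_at,
                                 forecast_time=forecast.valid_time)
    qc_counts["outside_grid"] = n_outside

    hour = qc_obs[
        (qc_obs["time_utc"] == forecast.valid_time) & qc_obs["accepted"]
    ]
    hour = hour[hour["station_id"].astype(str).isin(fcst_at)]

    notes = []
    accepted_stations = [stations[str(i)] for i in hour["station_id"]]
    y_o = hour["value"].to_numpy(dtype=float)

    corrected = forecast
    if bias_regions:
        # first-pass innovations on the raw forecast drive the bias estimate
        h0 = np.array([fcst_at[s.id] for s in accepted_stations])
        innov0 = InnovationVector(accepted_stations, y_o, h0,
                                  forecast.pollutant, forecast.valid_time)
        region_biases = []
        for region in bias_regions:
            b = estimate_regional_bias(innov0, region)
            if b is not None:
                region_biases.append((region, b))
            else:
                notes.append(f"bias region {region.name}: too few stations")
        if region_biases:
            corrected = apply_bias_field(forecast, region_biases)
            h_corr, _ = interpolate_to_stations(corrected, station_list)
            fcst_at = {s.id: v for s, v, ok
                       in zip(station_list, h_corr, inside) if ok}

    h_xf = np.array([fcst_at[s.id] for s in accepted_stations])
    innov = InnovationVector(accepted_stations, y_o, h_xf,
                             forecast.pollutant, forecast.valid_time)
    innov = merge_colocated(innov)

    if len(innov) == 0:
        warnings.warn(
            "no QC-accepted observations; analysis equals the forecast",
            stacklevel=2,
        )
        product = apply_gain(corrected, innov, np.zeros(0), stats)
    else:
        A = build_innovation_matrix(innov, stats)
        w = solve_weights(A, innov.d)
        product = apply_gain(corrected, innov, w, stats)
    product.forecast = forecast  # keep the uncorrected trial field in the product
    product.increment = product.analysis.with_values(
        product.analysis.values - forecast.values
    )
    product.qc_counts = qc_counts
    product.notes = notes
    return product
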