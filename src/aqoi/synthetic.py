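"""Synthetic scenes with the statistical structure the analysis assumes.

Truth fields are Gaussian random fields with exponential spatial covariance;
the forecast is truth plus a spatially correlated background error of known
variance (and optional regional constant offsets); observations are the
truth bilinearly interpolated to stations plus white noise whose variance
follows the land-use representativeness model.  Because every error source
is drawn from exactly the model the optimal interpolation and the variogram
estimator assume, recovery of the generating parameters is a sharp test of
the whole chain.

Random fields are sampled by dense Cholesky factorization of the cell-to-
cell covariance — exact, and entirely adequate at test-scale grids (a few
thousand cells); the factor is cached so a multi-hour scene pays for it
once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errstats import obs_error_s14
from .geo import pairwise_distances_km
from .grids import GridField, Station, stations_to_frame

MAX_DENSE_CELLS = 5000


@dataclass
class SyntheticConfig:
    """Study conditions for a synthetic scene.

    Defaults describe a ~400 km square mid-latitude domain at 10-km nominal
    resolution with 200 stations — dense enough for variogram estimation —
    and error magnitudes typical of PM2.5: background error variance
    25 (µg/m³)² with a 60-km correlation length, instrument error variance
    4 (µg/m³)² (so a rural site carries σ_o² = 8 at Δx = 10 km).
    """

    lat_min: float = 43.0
    lat_max: float = 47.0
    lon_min: float = -79.0
    lon_max: float = -73.0
    n_lat: int = 40
    n_lon: int = 40
    dx_km: float = 10.0
    pollutant: str = "PM2.5"
    n_stations: int = 200
    land_use_mix: tuple[float, float, float] = (1.0, 0.0, 0.0)
    placement: str = "uniform"  # or "clustered"
    n_clusters: int = 5
    truth_mean: float = 20.0
    truth_variance: float = 25.0
    truth_lc_km: float = 120.0
    sigma_b2: float = 25.0
    lc_bg_km: float = 60.0
    bias_offsets: Sequence[tuple["BiasRegion", float]] = ()
    sigma_instr2: float = 4.0
    n_hours: int = 24
    start_time: str = "2013-07-01T00:00"
    seed: int = 0

    def grid_lats(self) -> np.ndarray:
        return np.linspace(self.lat_min, self.lat_max, self.n_lat)

    def grid_lons(self) -> np.ndarray:
        return np.linspace(self.lon_min, self.lon_max, self.n_lon)

    def times(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_time, periods=self.n_hours,
                             freq="1h", tz="UTC")


class GaussianFieldSampler:
    """Draws mean-zero Gaussian random fields with covariance
    variance·exp(−d/lc_km) between the given points (e.g. grid cell
    centers).  The Cholesky factor is computed once and reused."""

    def __init__(self, lats: np.ndarray, lons: np.ndarray,
                 variance: float, lc_km: float):
        lats = np.asarray(lats, dtype=float)
        lons = np.asarray(lons, dtype=float)
        if lats.size > MAX_DENSE_CELLS:
            raise ValueError(
                f"{lats.size} points exceeds the dense-factorization limit "
                f"({MAX_DENSE_CELLS}); use a coarser grid"
            )
        if variance < 0 or lc_km <= 0:
            raise ValueError("variance must be >= 0 and lc_km positive")
        self.n = lats.size
        self.variance = variance
        if variance == 0.0:
            self._chol = None
            return
        dist = pairwise_distances_km(lats, lons)
        cov = variance * np.exp(-dist / lc_km)
        jitter = 1e-10 * variance
        try:
            self._chol = np.linalg.cholesky(cov + jitter * np.eye(self.n))
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "covariance not positive definite even after jitter"
            ) from exc

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        if self._chol is None:
            return np.zeros(self.n)
        return self._chol @ rng.standard_normal(self.n)


def make_station_network(config: SyntheticConfig,
                         rng: Optional[np.random.Generator] = None
                         ) -> list[Station]:
    """Random station placement inside the grid with a configured land-use
    mix; uniform by default, or clustered around a few random centers to
    mimic the urban-concentrated density of real networks."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_stations
    if n < 1:
        raise ValueError("need at least one station")
    if config.placement == "clustered":
        centers_lat = rng.uniform(config.lat_min, config.lat_max,
                                  config.n_clusters)
        centers_lon = rng.uniform(config.lon_min, config.lon_max,
                                  config.n_clusters)
        which = rng.integers(0, config.n_clusters, n)
        spread_lat = 0.05 * (config.lat_max - config.lat_min)
        spread_lon = 0.05 * (config.lon_max - config.lon_min)
        lats = np.clip(centers_lat[which] + spread_lat * rng.standard_normal(n),
                       config.lat_min, config.lat_max)
        lons = np.clip(centers_lon[which] + spread_lon * rng.standard_normal(n),
                       config.lon_min, config.lon_max)
    else:
        lats = rng.uniform(config.lat_min, config.lat_max, n)
        lons = rng.uniform(config.lon_min, config.lon_max, n)
    mix = np.asarray(config.land_use_mix, dtype=float)
    if mix.min() < 0 or not np.isclose(mix.sum(), 1.0):
        raise ValueError("land_use_mix fractions must be >= 0 and sum to 1")
    classes = rng.choice(["rural", "suburban", "urban"], size=n, p=mix)
    return [
        Station(id=f"S{i:04d}", lat=float(lats[i]), lon=float(lons[i]),
                land_use=str(classes[i]))
        for i in range(n)
    ]


def simulate_truth(config: SyntheticConfig,
                   rng: Optional[np.random.Generator] = None,
                   sampler: Optional[GaussianFieldSampler] = None,
                   valid_time=None) -> GridField:
    """One truth field: configured mean plus a correlated anomaly."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lats, lons = config.grid_lats(), config.grid_lons()
    if sampler is None:
        glat, glon = np.meshgrid(lats, lons, indexing="ij")
        sampler = GaussianFieldSampler(glat.ravel(), glon.ravel(),
                                       config.truth_variance,
                                       config.truth_lc_km)
    values = config.truth_mean + sampler.sample(rng).reshape(
        config.n_lat, config.n_lon)
    return GridField(lats=lats, lons=lons, values=values,
                     pollutant=config.pollutant, valid_time=valid_time,
                     dx_km=config.dx_km)


def simulate_forecast(truth: GridField, config: SyntheticConfig,
                      rng: Optional[np.random.Generator] = None,
                      sampler: Optional[GaussianFieldSampler] = None
                      ) -> GridField:
    """Forecast = truth + correlated background error + regional offsets."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if sampler is None:
        glat, glon = np.meshgrid(truth.lats, truth.lons, indexing="ij")
        sampler = GaussianFieldSampler(glat.ravel(), glon.ravel(),
                                       config.sigma_b2, config.lc_bg_km)
    values = truth.values + sampler.sample(rng).reshape(truth.shape)
    if config.bias_offsets:
        glat, glon = np.meshgrid(truth.lats, truth.lons, indexing="ij")
        for region, offset in config.bias_offsets:
            inside = region.contains(glat.ravel(), glon.ravel())
            values = values + offset * inside.reshape(truth.shape)
    return truth.with_values(values)


def simulate_observations(truth: GridField, stations: Sequence[Station],
                          config: SyntheticConfig,
                          rng: Optional[np.random.Generator] = None
                          ) -> pd.DataFrame:
    """Observations = truth at the station + white noise of the land-use
    dependent representativeness variance, one record per station."""
    from .oi import interpolate_to_stations

    if rng is None:
        rng = np.random.default_rng(config.seed)
    values, inside = interpolate_to_stations(truth, stations)
    if not inside.all():
        raise ValueError("all stations must lie inside the grid")
    sigma_o = np.array([
        np.sqrt(obs_error_s14(config.sigma_instr2, config.dx_km, s.land_use))
        for s in stations
    ])
    obs_values = values + sigma_o * rng.standard_normal(len(stations))
    df = stations_to_frame(stations)
    df["pollutant"] = truth.pollutant
    df["time_utc"] = truth.valid_time
    df["value"] = obs_values
    return df


@dataclass
class Scene:
    """A complete multi-hour synthetic experiment with known truth."""

    config: SyntheticConfig
    stations: list[Station]
    truth: dict
    forecast: dict
    observations: pd.DataFrame
    truth_at_stations: pd.DataFrame = None


def simulate_scene(config: SyntheticConfig) -> Scene:
    """Generate stations, hourly truth/forecast fields and observations.

    Fields at different hours are drawn independently (the generator models
    spatial, not temporal, error correlation — consistent with the
    time-white observation error the analysis assumes).  Deterministic under
    ``config.seed``.
    """
    from .oi import interpolate_to_stations

    rng = np.random.default_rng(config.seed)
    stations = make_station_network(config, rng)
    lats, lons = config.grid_lats(), config.grid_lons()
    glat, glon = np.meshgrid(lats, lons, indexing="ij")
    truth_sampler = GaussianFieldSampler(glat.ravel(), glon.ravel(),
                                         config.truth_variance,
                                         config.truth_lc_km)
    bg_sampler = GaussianFieldSampler(glat.ravel(), glon.ravel(),
                                      config.sigma_b2, config.lc_bg_km)
    truth, forecast, obs_frames, truth_rows = {}, {}, [], []
    for t in config.times():
        tr = simulate_truth(config, rng, truth_sampler, valid_time=t)
        fc = simulate_forecast(tr, config, rng, bg_sampler)
        ob = simulate_observations(tr, stations, config, rng)
        truth[t] = tr
        forecast[t] = fc
        obs_frames.append(ob)
        tv, _ = interpolate_to_stations(tr, stations)
        truth_rows.append(pd.DataFrame({
            "station_id": [s.id for s in stations],
            "time_utc": t, "truth": tv,
        }))
    return Scene(
        config=config,
        stations=stations,
        truth=truth,
        forecast=forecast,
        observations=pd.concat(obs_frames, ignore_index=True),
        truth_at_stations=pd.concat(truth_rows, ignore_index=True),
    )


def omp_table(observations: pd.DataFrame,
              forecasts: Mapping) -> pd.DataFrame:
    """Pair an observation table with forecasts interpolated to stations.

    Returns the tidy table (station_id, time_utc, obs, fcst) consumed by the
    error-statistics estimators.
    """
    from .oi import interpolate_to_stations
    from .grids import stations_from_frame

    rows = []
    for t, grp in observations.groupby("time_utc"):
        if t not in forecasts:
            continue
        stations = stations_from_frame(
            grp[["station_id", "lat", "lon", "land_use"]])
        values, inside = interpolate_to_stations(forecasts[t], stations)
        rows.append(pd.DataFrame({
            "station_id": grp["station_id"].to_numpy(),
            "time_utc": t,
            "obs": grp["value"].to_numpy(),
            "fcst": values,
        })[inside])
    if not rows:
        raise ValueError("no observation times match the forecast times")
    return pd.concat(rows, ignore_index=True)
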