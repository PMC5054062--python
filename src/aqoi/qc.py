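"""Three-stage observation quality control.

Range check (physical plausibility bounds per pollutant), hourly-jump check
(instrument spikes and telemetry glitches), and background check (gross
departure from the forecast relative to the combined error budget).  All
thresholds are configurable defaults; every check only flags — values are
never modified — and any flag rejects the record.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .errstats import ErrorStatistics

DEFAULT_RANGE_LIMITS = {
    "O3": (0.0, 250.0),
    "NO2": (0.0, 200.0),
    "PM2.5": (0.0, 500.0),
    "PM10": (0.0, 1000.0),
}

DEFAULT_JUMP_LIMITS = {
    "O3": 50.0,
    "NO2": 60.0,
    "PM2.5": 100.0,
    "PM10": 200.0,
}


@dataclass
class QCConfig:
    """Thresholds for the three QC stages.

    ``k_bgck`` scales the background-check gate
    |O − P| > k·sqrt(σ_B² + σ_o²).  Boundary convention everywhere: strict
    inequality flags, equality passes.
    """

    range_limits: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RANGE_LIMITS))
    jump_limits: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_JUMP_LIMITS))
    k_bgck: float = 4.0
    enable_range: bool = True
    enable_jump: bool = True
    enable_background: bool = True


def range_check(values: np.ndarray, pollutant: str,
                limits: Mapping[str, tuple[float, float]]) -> np.ndarray:
    """True where the value lies outside the configured [min, max]."""
    if pollutant not in limits:
        raise ValueError(f"no range limits configured for pollutant {pollutant!r}")
    lo, hi = limits[pollutant]
    values = np.asarray(values, dtype=float)
    return (values < lo) | (values > hi)


def jump_check(series: pd.Series, max_jump: float) -> pd.Series:
    """Flag records whose change from the previous valid hour exceeds
    ``max_jump`` (strictly).

    ``series`` is indexed by UTC time, one station, one pollutant.  The first
    record is never flagged and the check is not applied across gaps in the
    hourly sequence.
    """
    series = series.sort_index()
    flags = pd.Series(False, index=series.index)
    if len(series) < 2:
        return flags
    dt = series.index.to_series().diff()
    dv = series.diff().abs()
    contiguous = dt == pd.Timedelta(hours=1)
    flags[:] = contiguous.to_numpy() & (dv > max_jump).to_numpy()
    return flags


def background_check(values: np.ndarray, forecast_at_station: np.ndarray,
                     sigma_b2: float, sigma_o2: float, k: float = 4.0
                     ) -> np.ndarray:
    """True where |O − P| strictly exceeds k·sqrt(σ_B² + σ_o²)."""
    values = np.asarray(values, dtype=float)
    forecast_at_station = np.asarray(forecast_at_station, dtype=float)
    gate = k * np.sqrt(sigma_b2 + sigma_o2)
    return np.abs(values - forecast_at_station) > gate


def apply_qc(
    obs: pd.DataFrame,
    config: Optional[QCConfig] = None,
    stats: Optional[ErrorStatistics] = None,
    forecast_at_station: Optional[Mapping[str, float]] = None,
    forecast_time: Optional[pd.Timestamp] = None,
) -> tuple[pd.DataFrame, dict]:
    """Run the full QC chain on an observation table.

    Adds ``qc_flags`` (comma-joined stage names) and ``accepted`` columns and
    returns per-stage rejection counts.  All three stages are evaluated for
    every record (no short-circuiting of the reporting), and any flag
    rejects.  The background check needs error statistics and the forecast
    interpolated to each station; when either is missing it is skipped with
    a warning rather than silently passed.
    """
    if config is None:
        config = QCConfig()
    obs = obs.reset_index(drop=True)
    obs["time_utc"] = pd.to_datetime(obs["time_utc"], utc=True)
    n = len(obs)
    flag_range = np.zeros(n, dtype=bool)
    flag_jump = np.zeros(n, dtype=bool)
    flag_bgck = np.zeros(n, dtype=bool)

    if config.enable_range:
        for pollutant, grp in obs.groupby("pollutant"):
            flag_range[grp.index.to_numpy()] = range_check(
                grp["value"].to_numpy(), str(pollutant), config.range_limits
            )

    if config.enable_jump:
        obs_sorted = obs.reset_index().set_index("time_utc")
        for (sid, pollutant), grp in obs_sorted.groupby(
                ["station_id", "pollutant"]):
            limit = config.jump_limits.get(str(pollutant))
            if limit is None:
                continue
            f = jump_check(grp["value"], limit)
            flag_jump[grp.loc[f.to_numpy(), "index"].to_numpy()] = True

    if config.enable_background:
        if stats is None or forecast_at_station is None:
            warnings.warn("background check skipped: error statistics or "
                          "forecast at stations unavailable", stacklevel=2)
        else:
            sel = obs["time_utc"] == forecast_time if forecast_time is not None \
                else np.ones(n, dtype=bool)
            from .grids import Station
            for idx, row in obs[sel].iterrows():
                sid = str(row["station_id"])
                if sid not in forecast_at_station:
                    continue
                st = Station(id=sid, lat=float(row["lat"]),
                             lon=float(row["lon"]),
                             land_use=str(row.get("land_use", "rural")))
                so2 = stats.sigma_o2_station(st)
                sb2 = stats.sigma_b2_by_station.get(sid, stats.sigma_b2) \
                    if stats.sigma_b2_by_station else stats.sigma_b2
                flag_bgck[idx] = bool(background_check(
                    row["value"], forecast_at_station[sid], sb2, so2,
                    k=config.k_bgck,
                ))

    flags = []
    for fr, fj, fb in zip(flag_range, flag_jump, flag_bgck):
        parts = [name for name, f in
                 (("RANGE", fr), ("JUMP", fj), ("BGCK", fb)) if f]
        flags.append(",".join(parts))
    obs["qc_flags"] = flags
    obs["accepted"] = ~(flag_range | flag_jump | flag_bgck)
    counts = {
        "total": n,
        "range": int(flag_range.sum()),
        "jump": int(flag_jump.sum()),
        "background": int(flag_bgck.sum()),
        "accepted": int(obs["accepted"].sum()),
        "rejected": int((~obs["accepted"]).sum()),
    }
    return obs, counts
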