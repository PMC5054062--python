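"""Internal and cross (holdout) validation of analyses.

Three complementary metrics: mean bias (mean of O − P or O − A), the
standard deviation of the residuals (random error / RMSE after bias
removal), and FC2 — the fraction of predictions within a factor of two of
the observation, a reliability measure robust to outliers and compensating
errors.  Cross-validation withholds a random subset of *stations* from the
analysis and verifies at those unseen sites; three independent replicates
are pooled into a single test for statistical power, and per-UTC-hour t and
F tests flag where the analysis beats the forecast significantly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errstats import ErrorStatistics
from .grids import Station
from .oi import analyze, interpolate_to_stations

P_SIGNIFICANT = 0.05


def metrics(observed: np.ndarray, predicted: np.ndarray,
            floor: float = 1.0) -> dict:
    """Mean bias, residual standard deviation and FC2 for paired values.

    FC2 counts pairs with 0.5 <= P/O <= 2 (inclusive) among pairs whose
    observed value is at least ``floor`` — ratios against near-zero
    observations are meaningless.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    ok = np.isfinite(observed) & np.isfinite(predicted)
    if not ok.any():
        raise ValueError("no valid observation/prediction pairs")
    o, p = observed[ok], predicted[ok]
    resid = o - p
    fc2_sel = o >= floor
    if fc2_sel.any():
        ratio = p[fc2_sel] / o[fc2_sel]
        fc2 = float(np.mean((ratio >= 0.5) & (ratio <= 2.0)))
    else:
        fc2 = np.nan
    return {
        "bias": float(resid.mean()),
        "std": float(resid.std(ddof=1)) if resid.size > 1 else 0.0,
        "fc2": fc2,
        "n": int(o.size),
    }


@dataclass(frozen=True)
class CrossValSplit:
    """One station-level analysis/holdout partition."""

    analysis_stations: tuple[str, ...]
    holdout_stations: tuple[str, ...]
    fraction: float
    replicate_index: int
    seed: int


def make_splits(stations: Sequence[Station], fraction: float = 0.9,
                n_replicates: int = 3, seed: int = 0) -> list[CrossValSplit]:
    """Random station splits, one per replicate, disjoint within each split.

    Splitting is by station, not by record, so holdout time series are
    wholly unseen by the analysis.
    """
    ids = np.array([s.id for s in stations])
    n_hold = int(round((1.0 - fraction) * ids.size))
    if n_hold < 1 or n_hold >= ids.size:
        raise ValueError(
            f"fraction {fraction} leaves an empty analysis or holdout set "
            f"for {ids.size} stations"
        )
    splits = []
    for rep in range(1, n_replicates + 1):
        rng = np.random.default_rng(seed + rep)
        holdout = rng.choice(ids, size=n_hold, replace=False)
        hold_set = set(holdout)
        splits.append(CrossValSplit(
            analysis_stations=tuple(i for i in ids if i not in hold_set),
            holdout_stations=tuple(sorted(hold_set)),
            fraction=fraction,
            replicate_index=rep,
            seed=seed + rep,
        ))
    return splits


def regional_partition(stations: Sequence[Station],
                       country: Optional[Mapping[str, str]] = None,
                       split_lat: Optional[float] = None) -> dict[str, str]:
    """Assign each station to E/W Canada or E/W USA.

    East/west is split at longitude 90°W (exactly −90 counts as east);
    Canada/USA comes from a per-station country label, or a split latitude,
    else every station maps to "all".
    """
    labels = {}
    for s in stations:
        if country and s.id in country:
            nation = country[s.id]
        elif split_lat is not None:
            nation = "Canada" if s.lat >= split_lat else "USA"
        else:
            labels[s.id] = "all"
            continue
        ew = "W" if s.lon < -90.0 else "E"
        labels[s.id] = f"{ew}-{nation}"
    return labels


def _hourly_report(pairs: pd.DataFrame, floor: float,
                   min_pairs: int) -> pd.DataFrame:
    """Per-UTC-hour metrics and OmP-vs-OmA significance tests on pooled
    pairs (columns: hour, obs, fcst, anal)."""
    rows = []
    for hour, grp in pairs.groupby("hour"):
        m_omp = metrics(grp["obs"], grp["fcst"], floor=floor)
        m_oma = metrics(grp["obs"], grp["anal"], floor=floor)
        row = {
            "hour": int(hour),
            "n_pairs": m_omp["n"],
            "mean_omp": m_omp["bias"], "mean_oma": m_oma["bias"],
            "std_omp": m_omp["std"], "std_oma": m_oma["std"],
            "fc2_model": m_omp["fc2"], "fc2_analysis": m_oma["fc2"],
            "p_mean": np.nan, "p_var": np.nan,
            "significant_mean": False, "significant_var": False,
        }
        omp = (grp["obs"] - grp["fcst"]).to_numpy()
        oma = (grp["obs"] - grp["anal"]).to_numpy()
        if len(grp) >= min_pairs:
            t_res = sps.ttest_ind(omp, oma, equal_var=False)
            f = np.var(omp, ddof=1) / np.var(oma, ddof=1)
            dfn = dfd = len(grp) - 1
            p_f = 2.0 * min(sps.f.cdf(f, dfn, dfd), sps.f.sf(f, dfn, dfd))
            row.update(
                p_mean=float(t_res.pvalue), p_var=float(p_f),
                significant_mean=bool(t_res.pvalue < P_SIGNIFICANT),
                significant_var=bool(p_f < P_SIGNIFICANT),
            )
        rows.append(row)
    return pd.DataFrame(rows).sort_values("hour").reset_index(drop=True)


def internal_validate(products: Sequence, floor: float = 1.0,
                      min_pairs: int = 10) -> pd.DataFrame:
    """Coherence check at the assimilated stations themselves.

    For each analysis product, compares OmP with OmA at the stations the
    analysis ingested.  Expected: near-zero OmA bias and std_oma <= std_omp
    whenever the gain is positive.
    """
    rows = []
    for product in products:
        innov = product.innovations
        if len(innov) == 0:
            continue
        anal_at, _ = interpolate_to_stations(product.analysis, innov.stations)
        t = innov.valid_time
        rows.append(pd.DataFrame({
            "hour": (t.hour if t is not None else 0),
            "obs": innov.y_o, "fcst": innov.h_xf, "anal": anal_at,
        }))
    if not rows:
        raise ValueError("no products with accepted observations")
    return _hourly_report(pd.concat(rows, ignore_index=True), floor, min_pairs)


def cross_validate(
    forecasts: Mapping,
    observations: pd.DataFrame,
    stats: ErrorStatistics,
    pollutant: str,
    fraction: float = 0.9,
    n_replicates: int = 3,
    seed: int = 0,
    qc_config=None,
    bias_regions=None,
    floor: float = 1.0,
    min_pairs: int = 10,
    return_pairs: bool = False,
):
    """Holdout cross-validation of the full analysis chain.

    For each replicate, a random ``fraction`` of stations feeds the
    analysis; OmP and OmA are then evaluated at the withheld stations only.
    The pairs of all replicates are pooled before per-hour metrics and
    significance tests, as combining the replicates into one test buys
    statistical power.
    """
    from .grids import stations_from_frame

    obs = observations[observations["pollutant"] == pollutant].copy()
    if obs.empty:
        raise ValueError(f"no observations for pollutant {pollutant}")
    obs["time_utc"] = pd.to_datetime(obs["time_utc"], utc=True)
    stations = stations_from_frame(
        obs[["station_id", "lat", "lon", "land_use"]].drop_duplicates(
            "station_id"))
    splits = make_splits(stations, fraction=fraction,
                         n_replicates=n_replicates, seed=seed)
    by_id = {s.id: s for s in stations}

    pooled = []
    for split in splits:
        analysis_set = set(split.analysis_stations)
        holdout_set = set(split.holdout_stations)
        for t, fcst in forecasts.items():
            t = pd.Timestamp(t)
            hour_obs = obs[obs["time_utc"] == t]
            if hour_obs.empty:
                continue
            ana_obs = hour_obs[hour_obs["station_id"].isin(analysis_set)]
            product = analyze(fcst, ana_obs, stats, qc_config=qc_config,
                              bias_regions=bias_regions)
            hold_obs = hour_obs[hour_obs["station_id"].isin(holdout_set)]
            hold_stations = [by_id[i] for i in hold_obs["station_id"]]
            fcst_at, inside = interpolate_to_stations(fcst, hold_stations)
            anal_at, _ = interpolate_to_stations(product.analysis,
                                                 hold_stations)
            pooled.append(pd.DataFrame({
                "hour": t.hour,
                "obs": hold_obs["value"].to_numpy(),
                "fcst": fcst_at,
                "anal": anal_at,
                "replicate": split.replicate_index,
            })[inside])
    if not pooled:
        raise ValueError("no forecast hour matched any observations")
    pairs = pd.concat(pooled, ignore_index=True)
    report = _hourly_report(pairs, floor, min_pairs)
    report.attrs["mode"] = "cross"
    report.attrs["pollutant"] = pollutant
    report.attrs["fraction"] = fraction
    report.attrs["n_replicates"] = n_replicates
    report.attrs["seed"] = seed
    if return_pairs:
        return report, pairs
    return report
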