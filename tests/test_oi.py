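"""Optimal-interpolation core: distances, interpolation, innovation matrix,
weight solve and gain application, checked against dense-matrix oracles and
closed forms."""

import numpy as np
import pandas as pd
import pytest

from aqoi import (
    ErrorStatistics,
    GridField,
    InnovationVector,
    Station,
    analyze,
    apply_gain,
    build_innovation_matrix,
    great_circle_km,
    interpolate_to_stations,
    solve_weights,
)
from aqoi.geo import EARTH_RADIUS_KM
from aqoi.oi import increment_at_points, merge_colocated

KM_PER_DEG = EARTH_RADIUS_KM * np.pi / 180.0


def stats_with(sigma_b2=16.0, sigma_o2=9.0, lc_km=100.0, **kw):
    return ErrorStatistics(pollutant="O3", sigma_b2=sigma_b2, lc_km=lc_km,
                           sigma_o2_default=sigma_o2, **kw)


def uniform_grid(nlat=21, nlon=21, value=0.0, pollutant="O3"):
    lats = np.linspace(44.0, 46.0, nlat)
    lons = np.linspace(-75.0, -73.0, nlon)
    return GridField(lats=lats, lons=lons,
                     values=np.full((nlat, nlon), value),
                     pollutant=pollutant, dx_km=10.0)


class TestGreatCircle:
    def test_identity(self):
        assert great_circle_km(45.0, -73.0, 45.0, -73.0) == 0.0

    def test_one_degree_at_equator(self):
        # one degree of longitude on the equator is R*pi/180
        assert great_circle_km(0.0, 0.0, 0.0, 1.0) == pytest.approx(
            KM_PER_DEG, abs=1e-9)

    def test_symmetry_and_positivity(self, rng):
        a = rng.uniform([-80, -170], [80, 170], size=(100, 2))
        b = rng.uniform([-80, -170], [80, 170], size=(100, 2))
        d_ab = great_circle_km(a[:, 0], a[:, 1], b[:, 0], b[:, 1])
        d_ba = great_circle_km(b[:, 0], b[:, 1], a[:, 0], a[:, 1])
        np.testing.assert_allclose(d_ab, d_ba, rtol=0, atol=1e-12)
        assert (d_ab > 0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            great_circle_km(91.0, 0.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            great_circle_km(0.0, 181.0, 0.0, 0.0)


class TestInterpolation:
    def test_constant_field(self):
        field = uniform_grid(value=7.5)
        stations = [Station("a", 44.3, -74.7), Station("b", 45.9, -73.1)]
        values, inside = interpolate_to_stations(field, stations)
        assert inside.all()
        np.testing.assert_allclose(values, 7.5)

    def test_cell_center_exact(self):
        field = uniform_grid(nlat=5, nlon=5)
        field.values[2, 3] = 42.0
        st = [Station("a", float(field.lats[2]), float(field.lons[3]))]
        values, _ = interpolate_to_stations(field, st)
        assert values[0] == pytest.approx(42.0)

    def test_plane_reproduced_exactly(self, rng):
        # bilinear interpolation is exact for fields linear in lat and lon
        field = uniform_grid()
        a, b = 3.0, -2.0
        glat, glon = np.meshgrid(field.lats, field.lons, indexing="ij")
        field = field.with_values(a * glat + b * glon)
        lats = rng.uniform(44.05, 45.95, 20)
        lons = rng.uniform(-74.95, -73.05, 20)
        stations = [Station(f"s{i}", float(la), float(lo))
                    for i, (la, lo) in enumerate(zip(lats, lons))]
        values, _ = interpolate_to_stations(field, stations)
        np.testing.assert_allclose(values, a * lats + b * lons, rtol=1e-12)

    def test_outside_station_flagged_not_extrapolated(self):
        field = uniform_grid(value=1.0)
        values, inside = interpolate_to_stations(
            field, [Station("out", 50.0, -73.5), Station("in", 45.0, -74.0)])
        assert not inside[0] and inside[1]
        assert np.isnan(values[0]) and values[1] == pytest.approx(1.0)


def innovation(stations, d=None, pollutant="O3"):
    n = len(stations)
    d = np.zeros(n) if d is None else np.asarray(d, dtype=float)
    return InnovationVector(stations=list(stations), y_o=d,
                            h_xf=np.zeros(n), pollutant=pollutant)


class TestInnovationMatrix:
    def test_single_station_scalar(self):
        innov = innovation([Station("a", 45.0, -73.0)])
        A = build_innovation_matrix(innov, stats_with(16.0, 9.0))
        np.testing.assert_allclose(A, [[25.0]])

    def test_two_stations_off_diagonal(self):
        # stations one Lc apart along a meridian: off-diagonal is sf^2 / e
        dlat = 100.0 / KM_PER_DEG
        innov = innovation([Station("a", 45.0, -73.0),
                            Station("b", 45.0 + dlat, -73.0)])
        A = build_innovation_matrix(innov, stats_with(16.0, 9.0, lc_km=100.0))
        assert A[0, 1] == pytest.approx(16.0 * np.exp(-1.0), rel=1e-9)
        assert A[0, 1] == pytest.approx(5.886, abs=5e-4)
        np.testing.assert_allclose(A, A.T)

    def test_positive_definite(self, rng):
        stations = [Station(f"s{i}", float(la), float(lo))
                    for i, (la, lo) in enumerate(
                        zip(rng.uniform(44, 46, 30), rng.uniform(-76, -73, 30)))]
        A = build_innovation_matrix(innovation(stations), stats_with())
        assert np.linalg.eigvalsh(A).min() > 0


class TestSolveWeights:
    def test_zero_innovations(self):
        A = np.diag([25.0, 25.0])
        np.testing.assert_allclose(solve_weights(A, np.zeros(2)), 0.0)

    def test_decoupled_diagonal_limit(self):
        # far-apart stations with short Lc: A is effectively diagonal
        stations = [Station("a", 44.0, -76.0), Station("b", 46.0, -73.0)]
        stats = stats_with(16.0, 9.0, lc_km=5.0)
        A = build_innovation_matrix(innovation(stations), stats)
        d = np.array([5.0, -2.0])
        np.testing.assert_allclose(solve_weights(A, d), d / 25.0, rtol=1e-6)

    def test_matches_explicit_inverse(self, rng):
        stations = [Station(f"s{i}", float(la), float(lo))
                    for i, (la, lo) in enumerate(
                        zip(rng.uniform(44, 46, 5), rng.uniform(-76, -73, 5)))]
        A = build_innovation_matrix(innovation(stations), stats_with())
        d = rng.standard_normal(5)
        np.testing.assert_allclose(solve_weights(A, d),
                                   np.linalg.inv(A) @ d, rtol=1e-10)


class TestApplyGain:
    def test_zero_innovations_leave_forecast(self):
        field = uniform_grid(value=30.0)
        stations = [Station("a", 45.0, -74.0)]
        innov = InnovationVector(stations, np.array([30.0]), np.array([30.0]),
                                 "O3")
        stats = stats_with()
        w = solve_weights(build_innovation_matrix(innov, stats), innov.d)
        product = apply_gain(field, innov, w, stats)
        np.testing.assert_allclose(product.analysis.values, 30.0)
        np.testing.assert_allclose(product.increment.values, 0.0)

    def test_single_obs_scalar_closed_form(self):
        # at the observation site the scalar OI update is delta*sf^2/(sf^2+so^2)
        field = uniform_grid(nlat=5, nlon=5, value=0.0)
        st = Station("a", float(field.lats[2]), float(field.lons[2]))
        innov = InnovationVector([st], np.array([5.0]), np.array([0.0]), "O3")
        stats = stats_with(16.0, 9.0)
        w = solve_weights(build_innovation_matrix(innov, stats), innov.d)
        product = apply_gain(field, innov, w, stats)
        assert product.analysis.values[2, 2] == pytest.approx(
            5.0 * 16.0 / 25.0, rel=1e-12)
        assert product.analysis.values[2, 2] == pytest.approx(3.2)

    def test_single_obs_exponential_decay(self):
        st = Station("a", 45.0, -74.0)
        innov = InnovationVector([st], np.array([5.0]), np.array([0.0]), "O3")
        stats = stats_with(16.0, 9.0, lc_km=100.0)
        w = solve_weights(build_innovation_matrix(innov, stats), innov.d)
        at_station = increment_at_points([45.0], [-74.0], innov, w, stats)[0]
        for d_km in (50.0, 100.0, 250.0):
            dlat = d_km / KM_PER_DEG
            inc = increment_at_points([45.0 + dlat], [-74.0], innov, w,
                                      stats)[0]
            assert inc / at_station == pytest.approx(np.exp(-d_km / 100.0),
                                                     rel=1e-6)

    def test_pollutant_mismatch_rejected(self):
        field = uniform_grid(pollutant="O3")
        innov = innovation([Station("a", 45.0, -74.0)], pollutant="NO2")
        with pytest.raises(ValueError, match="pollutant"):
            apply_gain(field, innov, np.zeros(1), stats_with())


class TestOracleEquivalence:
    def test_dense_matrix_oracle(self, rng):
        """Analysis equals x^f + (HB)^T (H(HB)^T + R)^-1 d built densely."""
        field = uniform_grid(nlat=12, nlon=12, value=25.0)
        n = 20
        lats = rng.uniform(44.1, 45.9, n)
        lons = rng.uniform(-74.9, -73.1, n)
        stations = [Station(f"s{i}", float(la), float(lo))
                    for i, (la, lo) in enumerate(zip(lats, lons))]
        d = rng.standard_normal(n) * 4.0
        stats = stats_with(16.0, 9.0, lc_km=80.0)
        innov = InnovationVector(stations, d, np.zeros(n), "O3")
        A = build_innovation_matrix(innov, stats)
        w = solve_weights(A, innov.d)
        product = apply_gain(field, innov, w, stats)

        # independent dense construction
        glat, glon = np.meshgrid(field.lats, field.lons, indexing="ij")
        pts = np.column_stack([glat.ravel(), glon.ravel()])
        sf = 4.0
        hb = np.empty((pts.shape[0], n))
        for k in range(n):
            dist = great_circle_km(pts[:, 0], pts[:, 1], lats[k], lons[k])
            hb[:, k] = sf * sf * np.exp(-dist / 80.0)
        a_dense = np.empty((n, n))
        for i in range(n):
            dist = great_circle_km(lats[i], lons[i], lats, lons)
            a_dense[i] = sf * sf * np.exp(-dist / 80.0)
        a_dense[np.diag_indices(n)] = sf * sf + 9.0
        expected = 25.0 + (hb @ np.linalg.inv(a_dense) @ d).reshape(field.shape)
        np.testing.assert_allclose(product.analysis.values, expected,
                                   rtol=1e-10)

    def test_sigma_o_limits(self):
        field = uniform_grid(nlat=5, nlon=5, value=10.0)
        st = Station("a", float(field.lats[2]), float(field.lons[2]))
        innov = InnovationVector([st], np.array([20.0]), np.array([10.0]),
                                 "O3")
        # perfect observation: analysis reproduces it at the coincident cell
        tight = stats_with(16.0, 1e-12)
        w = solve_weights(build_innovation_matrix(innov, tight), innov.d)
        assert apply_gain(field, innov, w, tight).analysis.values[2, 2] == \
            pytest.approx(20.0, abs=1e-6)
        # useless observation: forecast untouched
        loose = stats_with(16.0, 1e12)
        w = solve_weights(build_innovation_matrix(innov, loose), innov.d)
        np.testing.assert_allclose(
            apply_gain(field, innov, w, loose).analysis.values, 10.0,
            atol=1e-6)

    def test_permutation_invariance(self, rng):
        field = uniform_grid(nlat=8, nlon=8)
        n = 10
        lats = rng.uniform(44.1, 45.9, n)
        lons = rng.uniform(-74.9, -73.1, n)
        d = rng.standard_normal(n)
        stats = stats_with()

        def run(order):
            stations = [Station(f"s{i}", float(lats[i]), float(lons[i]))
                        for i in order]
            innov = InnovationVector(stations, d[order],
                                     np.zeros(n), "O3")
            w = solve_weights(build_innovation_matrix(innov, stats), innov.d)
            return apply_gain(field, innov, w, stats).analysis.values

        base = run(np.arange(n))
        shuffled = rng.permutation(n)
        np.testing.assert_allclose(run(shuffled), base, rtol=1e-10)


class TestColocation:
    def test_nearby_stations_merged(self):
        stations = [Station("a", 45.0, -74.0), Station("b", 45.001, -74.0),
                    Station("c", 45.5, -74.0)]
        innov = InnovationVector(stations, np.array([10.0, 14.0, 5.0]),
                                 np.zeros(3), "O3")
        merged = merge_colocated(innov)
        assert len(merged) == 2
        assert merged.y_o[0] == pytest.approx(12.0)


class TestAnalyzePipeline:
    def _obs_frame(self, scene, t):
        return scene.observations[scene.observations["time_utc"] == t]

    def test_all_rejected_returns_forecast(self, small_scene, pm25_stats):
        from aqoi import QCConfig
        t = small_scene.config.times()[0]
        cfg = QCConfig(range_limits={"PM2.5": (1e5, 1e6)})
        with pytest.warns(UserWarning, match="no QC-accepted"):
            product = analyze(small_scene.forecast[t],
                              self._obs_frame(small_scene, t),
                              pm25_stats, qc_config=cfg)
        np.testing.assert_allclose(product.analysis.values,
                                   small_scene.forecast[t].values)
        assert product.qc_counts["accepted"] == 0

    def test_increment_bookkeeping(self, small_scene, pm25_stats):
        t = small_scene.config.times()[0]
        product = analyze(small_scene.forecast[t],
                          self._obs_frame(small_scene, t), pm25_stats)
        np.testing.assert_allclose(
            product.increment.values,
            product.analysis.values - product.forecast.values,
            atol=1e-12)

    def test_analysis_beats_forecast_against_truth(self, small_scene,
                                                   pm25_stats):
        improved = 0
        for t in small_scene.config.times():
            truth = small_scene.truth[t].values
            product = analyze(small_scene.forecast[t],
                              self._obs_frame(small_scene, t), pm25_stats)
            if (np.std(product.analysis.values - truth)
                    < np.std(small_scene.forecast[t].values - truth)):
                improved += 1
        assert improved == len(small_scene.config.times())
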