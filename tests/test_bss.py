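"""Boundary buffering and bicubic / Clough-Tocher interpolation."""

import numpy as np
import pytest

from stinterp.bss import (
    BicubicGridInterpolator,
    bss_loocv,
    buffer_ring_locations,
    build_buffer,
    interp_grid_bicubic,
    interp_scattered_cubic,
)
from stinterp.core import STSeries, StationGrid
from tests.conftest import edge_masks, per_station_mae


class TestBuffer:
    @pytest.mark.parametrize("nr,nc", [(7, 10), (2, 2), (3, 5)])
    def test_ring_count_formula(self, nr, nc):
        g = StationGrid.regular(nr, nc)
        lon, lat = buffer_ring_locations(g)
        assert lon.size == (nr + 2) * (nc + 2) - nr * nc

    def test_ring_strictly_outside_bounding_box(self, grid7x10):
        lon, lat = buffer_ring_locations(grid7x10)
        inside = (
            (lon >= grid7x10.lon.min()) & (lon <= grid7x10.lon.max())
            & (lat >= grid7x10.lat.min()) & (lat <= grid7x10.lat.max())
        )
        assert not inside.any()

    def test_constant_field_buffer_is_constant(self, grid7x10):
        dom = build_buffer(grid7x10.lon, grid7x10.lat, np.full(70, 3.5), grid7x10)
        assert np.allclose(dom.buffer_values, 3.5)

    def test_2x2_k3_matches_brute_force(self):
        g = StationGrid.regular(2, 2, lon0=0.0, lat0=1.0, spacing_lon=1.0, spacing_lat=1.0)
        vals = np.array([1.0, 2.0, 3.0, 4.0])
        dom = build_buffer(g.lon, g.lat, vals, g, k_nearest=3)
        for blon, blat, bval in zip(dom.buffer_lon, dom.buffer_lat, dom.buffer_values):
            d = np.hypot(g.lon - blon, g.lat - blat)
            nearest3 = np.argsort(d, kind="stable")[:3]
            assert bval == pytest.approx(vals[nearest3].mean())

    def test_buffer_values_within_real_range(self, grid7x10):
        rng = np.random.default_rng(0)
        vals = rng.uniform(10, 90, 70)
        dom = build_buffer(grid7x10.lon, grid7x10.lat, vals, grid7x10)
        assert (dom.buffer_values >= vals.min()).all()
        assert (dom.buffer_values <= vals.max()).all()

    def test_k_exceeding_points_rejected(self, grid7x10):
        with pytest.raises(ValueError, match="k_nearest"):
            build_buffer(grid7x10.lon[:5], grid7x10.lat[:5], np.ones(5), grid7x10,
                         k_nearest=6)


class TestGridBicubic:
    def test_exact_at_nodes(self):
        rng = np.random.default_rng(1)
        x, y = np.arange(5.0), np.arange(6.0)
        Z = rng.standard_normal((5, 6))
        f = BicubicGridInterpolator(x, y, Z)
        gx, gy = np.meshgrid(x, y, indexing="ij")
        assert np.allclose(f(gx.ravel(), gy.ravel()), Z.ravel(), atol=1e-12)

    def test_linear_precision(self):
        x, y = np.linspace(0, 4, 5), np.linspace(0, 3, 4)
        X, Y = np.meshgrid(x, y, indexing="ij")
        Z = 2 * X + 3 * Y + 1
        q = np.random.default_rng(2).uniform([0, 0], [4, 3], (40, 2))
        out = interp_grid_bicubic(x, y, Z, q[:, 0], q[:, 1])
        assert np.allclose(out, 2 * q[:, 0] + 3 * q[:, 1] + 1, atol=1e-10)

    def test_polynomial_products_reproduced_exactly(self):
        # centered differences are exact for x^2 in x and y in y, so the
        # Hermite surface reproduces z = x^2 y to rounding error
        rng = np.random.default_rng(3)
        q = rng.uniform(0.2, 0.8, (60, 2))
        x = np.linspace(0, 1, 9)
        X, Y = np.meshgrid(x, x, indexing="ij")
        out = interp_grid_bicubic(x, x, X**2 * Y, q[:, 0], q[:, 1])
        assert np.abs(out - q[:, 0] ** 2 * q[:, 1]).max() < 1e-12

    def test_convergence_order_on_smooth_surface(self):
        # max error for z = sin(3x)cos(2y) should shrink at ~O(h^2) or better
        rng = np.random.default_rng(3)
        q = rng.uniform(0.2, 0.8, (60, 2))
        errs = []
        for m in (9, 17, 33):
            x = np.linspace(0, 1, m)
            X, Y = np.meshgrid(x, x, indexing="ij")
            out = interp_grid_bicubic(x, x, np.sin(3 * X) * np.cos(2 * Y),
                                      q[:, 0], q[:, 1])
            errs.append(
                np.abs(out - np.sin(3 * q[:, 0]) * np.cos(2 * q[:, 1])).max()
            )
        assert errs[1] <= errs[0] / 3.0
        assert errs[2] <= errs[1] / 3.0

    def test_c1_continuity_across_shared_edges(self):
        rng = np.random.default_rng(4)
        x, y = np.arange(6.0), np.arange(5.0)
        f = BicubicGridInterpolator(x, y, rng.standard_normal((6, 5)))
        # directional derivatives from both sides of interior edges
        for xe in x[1:-1]:
            ys = rng.uniform(0.1, 3.9, 10)
            gl = f.gradient(np.full(10, xe - 1e-9), ys)
            gr = f.gradient(np.full(10, xe + 1e-9), ys)
            assert np.allclose(gl[0], gr[0], atol=1e-6)
            assert np.allclose(gl[1], gr[1], atol=1e-6)

    def test_monomial_coefficients_reproduce_surface(self):
        # the 16 a_ij of one cell evaluated as a plain double polynomial
        rng = np.random.default_rng(5)
        f = BicubicGridInterpolator(np.arange(4.0), np.arange(4.0),
                                    rng.standard_normal((4, 4)))
        A = f.cell_coefficients(1, 1)
        for u, v in rng.uniform(0, 1, (10, 2)):
            poly = sum(
                A[i, j] * u**i * v**j for i in range(4) for j in range(4)
            )
            assert f(1.0 + u, 1.0 + v)[0] == pytest.approx(poly, abs=1e-12)

    def test_query_outside_grid_rejected(self):
        f = BicubicGridInterpolator(np.arange(3.0), np.arange(3.0), np.zeros((3, 3)))
        with pytest.raises(ValueError, match="outside"):
            f([5.0], [1.0])


class TestScatteredCubic:
    def test_exact_at_data_points(self):
        rng = np.random.default_rng(6)
        lon, lat = rng.uniform(0, 3, (2, 15))
        vals = rng.standard_normal(15)
        out = interp_scattered_cubic(lon, lat, vals, lon[3:6], lat[3:6])
        assert np.allclose(out, vals[3:6], atol=1e-12)

    def test_linear_precision_inside_hull(self):
        rng = np.random.default_rng(7)
        lon, lat = rng.uniform(0, 3, (2, 25))
        vals = lon - lat
        q = rng.uniform(1.0, 2.0, (20, 2))
        out = interp_scattered_cubic(lon, lat, vals, q[:, 0], q[:, 1])
        assert np.allclose(out, q[:, 0] - q[:, 1], atol=1e-10)

    def test_corner_query_fails_without_buffer_succeeds_with(self, grid7x10):
        g = grid7x10
        mask = np.ones(70, bool)
        mask[0] = False  # drop corner station 1
        rng = np.random.default_rng(8)
        vals = rng.uniform(20, 60, 70)
        with pytest.raises(ValueError, match="convex hull"):
            interp_scattered_cubic(g.lon[mask], g.lat[mask], vals[mask],
                                   g.lon[0], g.lat[0])
        dom = build_buffer(g.lon[mask], g.lat[mask], vals[mask], g)
        out = interp_scattered_cubic(
            dom.all_lon(), dom.all_lat(), dom.all_values(), g.lon[0], g.lat[0]
        )
        assert np.isfinite(out[0])
        lo, hi = vals[mask].min(), vals[mask].max()
        assert lo - 0.1 * (hi - lo) <= out[0] <= hi + 0.1 * (hi - lo)


class TestLOOCV:
    def test_constant_field_zero_error(self, grid7x10):
        s = STSeries(grid7x10, np.full((70, 2), 9.0))
        for f in bss_loocv(s):
            assert np.allclose(f.predicted, 9.0, atol=1e-10)

    def test_planar_field_interior_exact_corners_finite(self, planar_series_7x10):
        folds = bss_loocv(planar_series_7x10)
        maes = per_station_mae(folds)
        edge, corner = edge_masks()
        assert np.isfinite(maes).all()
        assert maes[~edge].max() <= 1e-9
        assert maes[corner].max() < 5.0  # finite, modest buffer-induced error

    def test_all_70_stations_predicted(self, grid7x10):
        rng = np.random.default_rng(9)
        s = STSeries(grid7x10, rng.uniform(20, 80, (70, 3)))
        folds = bss_loocv(s)
        assert len(folds) == 70
        assert all(np.isfinite(f.predicted).all() for f in folds)

    def test_predictions_within_inflated_envelope(self, grid7x10):
        rng = np.random.default_rng(10)
        s = STSeries(grid7x10, rng.uniform(20, 80, (70, 4)))
        lo, hi = s.values.min(), s.values.max()
        pad = 0.1 * (hi - lo)
        for f in bss_loocv(s):
            assert (f.predicted >= lo - pad).all()
            assert (f.predicted <= hi + pad).all()

    def test_buffering_beats_nearest_neighbor_extrapolation_at_corners(self):
        from stinterp.synthetic import generate, smooth_gradient_spec
        from stinterp.core import pairwise_distance

        s = generate(smooth_gradient_spec(seed=11, n_times=12))
        folds = bss_loocv(s)
        maes = per_station_mae(folds)
        _, corner = edge_masks()
        # fallback: predict each corner by its nearest remaining station
        D = pairwise_distance(s.grid)
        nn_maes = []
        for k in np.where(corner)[0]:
            d = D[k].copy()
            d[k] = np.inf
            nn = np.argmin(d)
            nn_maes.append(np.mean(np.abs(s.values[k] - s.values[nn])))
        assert maes[corner].mean() <= np.mean(nn_maes)
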