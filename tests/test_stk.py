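"""Separable variograms, empirical estimation, kriging and the STK pipeline."""

import numpy as np
import pytest

from stinterp.core import STSeries, StationGrid, pairwise_distance
from stinterp.stk import (
    FAMILIES,
    MarginalVariogram,
    SeparableVariogram,
    back_transform,
    empirical_st_variogram,
    eval_separable,
    fit_separable,
    krige,
    stk_loocv,
)
from stinterp.synthetic import generate, generate_separable_gp, SyntheticSpec


class TestMarginalVariogram:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_zero_lag_is_nugget_and_saturates_at_one(self, family):
        m = MarginalVariogram(family, range_=2.0, nugget_fraction=0.2)
        assert m.gamma_bar(0.0) == pytest.approx(0.2)
        assert m.gamma_bar(1e6) == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_nondecreasing(self, family):
        m = MarginalVariogram(family, range_=3.0, nugget_fraction=0.1)
        lags = np.linspace(0, 30, 200)
        g = m.gamma_bar(lags)
        assert (np.diff(g) >= -1e-12).all()

    def test_spherical_exactly_one_beyond_range(self):
        m = MarginalVariogram("spherical", range_=2.0)
        assert m.gamma_bar(2.0) == pytest.approx(1.0)
        assert m.gamma_bar(5.0) == pytest.approx(1.0)

    def test_negative_lag_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            MarginalVariogram("exponential", 1.0).gamma_bar(-1.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            MarginalVariogram("exponential", -1.0)
        with pytest.raises(ValueError):
            MarginalVariogram("exponential", 1.0, nugget_fraction=1.0)
        with pytest.raises(ValueError):
            MarginalVariogram("cubic", 1.0)


class TestSeparable:
    def test_reduces_to_temporal_at_zero_spatial_lag(self):
        m = SeparableVariogram(
            3.0,
            MarginalVariogram("exponential", 10.0, nugget_fraction=0.0),
            MarginalVariogram("exponential", 2.0, nugget_fraction=0.0),
        )
        taus = np.array([0.5, 1.0, 4.0])
        assert np.allclose(m.gamma(0.0, taus), 3.0 * m.temporal.gamma_bar(taus))

    def test_saturation_at_joint_sill(self):
        m = SeparableVariogram(
            2.5, MarginalVariogram("spherical", 1.0), MarginalVariogram("spherical", 1.0)
        )
        assert m.gamma(10.0, 10.0) == pytest.approx(2.5)

    def test_half_half_hand_value(self):
        # gammas both 0.5 -> sill * (0.5 + 0.5 - 0.25) = 1.5 for sill 2
        m = SeparableVariogram(
            2.0,
            MarginalVariogram("exponential", 1.0),
            MarginalVariogram("exponential", 1.0),
        )
        h = tau = -np.log(0.5)
        assert eval_separable(m, h, tau) == pytest.approx(1.5)

    def test_nugget_identity_at_origin(self):
        ns, nt, sill = 0.2, 0.3, 4.0
        m = SeparableVariogram(
            sill,
            MarginalVariogram("gaussian", 1.0, nugget_fraction=ns),
            MarginalVariogram("gaussian", 1.0, nugget_fraction=nt),
        )
        assert m.gamma(0.0, 0.0) == pytest.approx(sill * (ns + nt - ns * nt))

    def test_covariance_variogram_identity(self):
        m = SeparableVariogram(
            1.7,
            MarginalVariogram("matern", 100.0, nugget_fraction=0.1),
            MarginalVariogram("exponential", 3.0, nugget_fraction=0.05),
        )
        h = np.array([0.0, 50.0, 400.0])
        tau = np.array([0.0, 2.0, 9.0])
        assert np.allclose(m.sill - m.covariance(h, tau), m.gamma(h, tau))


class TestEmpiricalVariogram:
    def test_two_station_hand_example(self):
        g = StationGrid(np.array([1, 2]), np.array([0.0, 1.0]), np.array([0.0, 0.0]))
        s = STSeries(g, np.array([[0.0, 2.0], [1.0, 3.0]]))
        emp = empirical_st_variogram(s, n_spatial_bins=2, max_h=200.0, max_tlag=1)
        # pure spatial lag: 0.5 * ((0-1)^2 + (2-3)^2) / 2 = 0.5
        assert emp.gamma[2, 0] == pytest.approx(0.5)

    def test_white_noise_flat_near_variance(self, grid7x10):
        rng = np.random.default_rng(0)
        vals = rng.standard_normal((70, 88))
        emp = empirical_st_variogram(STSeries(grid7x10, vals))
        finite = emp.gamma[np.isfinite(emp.gamma)]
        assert np.all(np.abs(finite - 1.0) < 0.2)

    def test_time_constant_field_has_no_temporal_structure(self, grid7x10):
        rng = np.random.default_rng(1)
        col = rng.standard_normal(70)
        vals = np.repeat(col[:, None], 10, axis=1)
        emp = empirical_st_variogram(STSeries(grid7x10, vals), max_tlag=3)
        for b in range(1, emp.gamma.shape[0]):
            row = emp.gamma[b]
            finite = np.isfinite(row)
            if finite.sum() > 1:
                assert np.allclose(row[finite], row[finite][0], rtol=1e-9)

    def test_zero_zero_cell_excluded(self, grid7x10):
        rng = np.random.default_rng(2)
        emp = empirical_st_variogram(
            STSeries(grid7x10, rng.standard_normal((70, 12)))
        )
        assert emp.counts[0, 0] == 0 and np.isnan(emp.gamma[0, 0])


class TestFitSeparable:
    def _noise_free_emp(self, model, grid):
        D = pairwise_distance(grid)
        edges = np.linspace(0, 0.75 * D.max(), 9)
        centers = np.r_[0.0, 0.5 * (edges[:-1] + edges[1:])]
        tlags = np.arange(7)
        H = np.broadcast_to(centers[:, None], (9, 7))
        TAU = np.broadcast_to(tlags[None, :], (9, 7)).astype(float)
        gamma = model.gamma(H, TAU)
        counts = np.full((9, 7), 100.0)
        gamma = gamma.copy()
        gamma[0, 0] = np.nan
        counts[0, 0] = 0
        from stinterp.stk import EmpiricalSTVariogram

        return EmpiricalSTVariogram(centers, edges, tlags, gamma, counts)

    def test_exact_surface_recovered_within_one_percent(self, grid7x10):
        truth = SeparableVariogram(
            1.3,
            MarginalVariogram("exponential", 150.0, nugget_fraction=0.1),
            MarginalVariogram("exponential", 2.5, nugget_fraction=0.05),
        )
        emp = self._noise_free_emp(truth, grid7x10)
        fit = fit_separable(emp, "exponential", "exponential")
        assert fit.model.sill == pytest.approx(1.3, rel=0.01)
        assert fit.model.spatial.range_ == pytest.approx(150.0, rel=0.01)
        assert fit.model.temporal.range_ == pytest.approx(2.5, rel=0.01)
        assert fit.mse < 1e-10

    def test_simulated_gp_ranges_recovered(self, grid7x10):
        sm = MarginalVariogram("exponential", 200.0)
        tm = MarginalVariogram("exponential", 3.0)
        Z = generate_separable_gp(grid7x10, 88, sm, tm, sill=1.0, seed=3)
        emp = empirical_st_variogram(STSeries(grid7x10, Z))
        fit = fit_separable(emp, "exponential", "exponential")
        assert fit.model.spatial.range_ == pytest.approx(200.0, rel=0.3)
        assert fit.model.temporal.range_ == pytest.approx(3.0, rel=0.3)

    def test_weighting_modes_differ_on_unbalanced_bins(self, grid7x10):
        rng = np.random.default_rng(4)
        Z = generate_separable_gp(
            grid7x10, 40,
            MarginalVariogram("exponential", 150.0),
            MarginalVariogram("exponential", 2.0), sill=1.0, seed=5,
        )
        emp = empirical_st_variogram(STSeries(grid7x10, Z))
        # perturb one sparse bin so weighting matters
        emp.counts[-1, -1] = 1.0
        emp.gamma[-1, -1] = 5.0
        f_eq = fit_separable(emp, "exponential", "exponential", weights="equal")
        f_pc = fit_separable(emp, "exponential", "exponential", weights="pair_counts")
        assert not np.isclose(f_eq.model.sill, f_pc.model.sill, rtol=1e-3)

    def test_too_few_bins_rejected(self):
        from stinterp.stk import EmpiricalSTVariogram

        emp = EmpiricalSTVariogram(
            np.array([0.0, 1.0]), np.array([0.0, 2.0]), np.array([0]),
            np.array([[np.nan], [1.0]]), np.array([[0.0], [5.0]]),
        )
        with pytest.raises(ValueError, match="bins"):
            fit_separable(emp)


@pytest.fixture(scope="module")
def model():
    return SeparableVariogram(
        1.0,
        MarginalVariogram("exponential", 150.0),
        MarginalVariogram("exponential", 2.0),
    )


class TestKrige:
    def test_exact_at_data_points_with_zero_nugget(self, grid5x5, model):
        rng = np.random.default_rng(0)
        s = STSeries(grid5x5, rng.standard_normal((25, 8)))
        p, v = krige(s, model, grid5x5.lon[12], grid5x5.lat[12], k_t=5)
        assert np.abs(p - s.values[12]).max() <= 1e-8
        assert np.abs(v).max() <= 1e-8

    def test_weights_sum_to_one_via_constant_field(self, grid5x5, model):
        s = STSeries(grid5x5, np.ones((25, 6)))
        p, _ = krige(s, model, 52.3, 25.2, k_t=4)
        assert np.allclose(p, 1.0, atol=1e-10)

    def test_variance_nonnegative_off_data(self, grid5x5, model):
        rng = np.random.default_rng(1)
        s = STSeries(grid5x5, rng.standard_normal((25, 6)))
        _, v = krige(s, model, 52.26, 25.27, k_t=5)
        assert (v >= -1e-10).all()

    def test_three_point_system_matches_independent_solve(self, model):
        g = StationGrid(np.array([1, 2, 3]), np.array([0.0, 1.0, 0.0]),
                        np.array([0.0, 0.0, 1.0]))
        z = np.array([[1.0], [2.0], [3.0]])
        s = STSeries(g, z)
        target = (0.4, 0.3)
        p, v = krige(s, model, target[0], target[1], k_t=1)
        # independent assembly and solve of the ordinary kriging system
        import scipy.linalg

        D = pairwise_distance(g)
        C = model.covariance(D, 0.0)
        np.fill_diagonal(C, model.sill)
        d0 = g.lon * 0.0
        from stinterp.core import GREAT_CIRCLE

        d0 = GREAT_CIRCLE.pairwise([target[0]], [target[1]], g.lon, g.lat)[0]
        c0 = model.covariance(d0, 0.0)
        A = np.zeros((4, 4))
        A[:3, :3] = C
        A[3, :3] = A[:3, 3] = 1.0
        sol = scipy.linalg.solve(A, np.r_[c0, 1.0])
        assert p[0] == pytest.approx(float(sol[:3] @ z[:, 0]), rel=1e-10)
        assert v[0] == pytest.approx(float(model.sill - sol[:3] @ c0 - sol[3]), abs=1e-10)

    def test_off_grid_time_rejected(self, grid5x5, model):
        s = STSeries(grid5x5, np.ones((25, 4)))
        with pytest.raises(ValueError, match="time grid"):
            krige(s, model, 52.0, 26.0, times=[9])


class TestBackTransform:
    def test_zero_variance_identity(self):
        assert back_transform(np.array([2.0]), 0.0)[0] == pytest.approx(100.0)

    def test_hand_value(self):
        assert back_transform(np.array([1.0]), 0.04)[0] == pytest.approx(10.4713, abs=1e-4)

    def test_exact_correction_is_larger(self):
        conv = back_transform(np.array([1.0]), 0.1)[0]
        exact = back_transform(np.array([1.0]), 0.1, exact=True)[0]
        assert exact > conv > 10.0

    def test_correction_never_shrinks(self):
        for s2 in (0.0, 0.01, 0.5):
            assert back_transform(np.array([0.0]), s2)[0] >= 1.0

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            back_transform(np.array([1.0]), -0.1)


@pytest.fixture(scope="module")
def small_result():
    spec = SyntheticSpec(n_rows=4, n_cols=5, n_times=24, seed=7)
    series = generate(spec)
    pairs = [("exponential", "exponential"), ("gaussian", "exponential"),
             ("spherical", "spherical")]
    return series, stk_loocv(series, family_pairs=pairs)


class TestSTKLOOCV:
    def test_winner_has_minimal_pooled_mse(self, small_result):
        _, res = small_result
        table = res.selection_table
        assert table["loocv_mse_log"].iloc[0] == table["loocv_mse_log"].min()
        assert (res.selected_pair[0], res.selected_pair[1]) == (
            table.loc[0, "spatial_family"], table.loc[0, "temporal_family"]
        )

    def test_all_requested_pairs_evaluated(self, small_result):
        _, res = small_result
        assert len(res.selection_table) == 3

    def test_predictions_positive(self, small_result):
        _, res = small_result
        for f in res.folds:
            assert (f.predicted > 0).all()

    def test_log_folds_consistent_with_final(self, small_result):
        series, res = small_result
        # final = 10^(log prediction) * correction >= 10^(log prediction)
        for fl, f in zip(res.folds_log, res.folds):
            assert np.all(f.predicted >= 10.0**fl.predicted - 1e-9)

    def test_noise_free_field_interpolated_closely(self):
        spec = SyntheticSpec(n_rows=4, n_cols=5, n_times=24, sill_log=0.0,
                             outlier_rate=0.0)
        series = generate(spec)
        res = stk_loocv(
            series, family_pairs=[("exponential", "exponential")],
            trend_kind="tensor_spline",
            trend_options={"k_time": series.n_times},  # resolve log-seasonal shape
        )
        interior = [f for f in res.folds
                    if f.station_id in (7, 8, 9, 12, 13, 14)]
        for f in interior:
            mape = 100.0 * np.mean(np.abs(f.observed - f.predicted) / f.observed)
            assert mape <= 1.0
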