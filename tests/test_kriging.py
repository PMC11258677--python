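"""Ordinary kriging, normal scores, SGCS and holdout validation."""

import numpy as np
import pytest

from canopygeo import (VariogramModel, etype, holdout_validate, model_gamma,
                       normal_scores, ok_predict, ok_predict_points, sgcs,
                       sgcs_points, simulate_grf_at_points)
from canopygeo.grids import GridGeometry
from canopygeo.kriging import SgcsResult


@pytest.fixture
def scattered_data(exp_model):
    rng = np.random.default_rng(5)
    pts = rng.uniform(0, 30, size=(60, 2))
    vals = np.clip(0.56 + 0.09 * rng.standard_normal(60), 0, 1)
    return pts, vals


class TestOrdinaryKriging:
    def test_exact_at_data_points(self, scattered_data, exp_model):
        pts, vals = scattered_data
        pred, var = ok_predict_points(pts, vals, exp_model, pts, radius=1e9)
        np.testing.assert_allclose(pred, vals, atol=1e-8)

    def test_single_datum_unit_weight(self, exp_model):
        pred, _ = ok_predict_points(np.array([[5.0, 5.0]]), np.array([0.7]),
                                    exp_model, np.array([[1.0, 2.0], [8.0, 3.0]]),
                                    radius=1e9)
        np.testing.assert_allclose(pred, 0.7)

    def test_two_point_system_solved_by_hand(self):
        m = VariogramModel("exponential", 0.001, 0.008, 10.0)
        dpts = np.array([[0.0, 0.0], [4.0, 0.0]])
        dv = np.array([0.3, 0.7])
        target = np.array([[1.0, 1.0]])
        g = lambda h: model_gamma(m, h)
        a = np.array([[0.0, g(4.0), 1.0], [g(4.0), 0.0, 1.0], [1.0, 1.0, 0.0]])
        b = np.array([g(np.hypot(1, 1)), g(np.hypot(3, 1)), 1.0])
        lam0, lam1, mu = np.linalg.solve(a, b)
        pred, var = ok_predict_points(dpts, dv, m, target)
        assert pred[0] == pytest.approx(lam0 * 0.3 + lam1 * 0.7)
        assert var[0] == pytest.approx(lam0 * b[0] + lam1 * b[1] + mu)

    def test_weights_sum_to_one_everywhere(self, scattered_data, exp_model):
        pts, vals = scattered_data
        rng = np.random.default_rng(0)
        targets = rng.uniform(-5, 35, size=(500, 2))
        _, _, wsum = ok_predict_points(pts, vals, exp_model, targets,
                                       radius=1e9, return_weight_sums=True)
        assert np.nanmax(np.abs(wsum - 1.0)) < 1e-8

    def test_pure_nugget_gives_neighborhood_mean(self, scattered_data):
        pts, vals = scattered_data
        nug = VariogramModel("exponential", 0.01, 0.0, 1.0)
        pred, _ = ok_predict_points(pts, vals, nug, np.array([[15.0, 15.0]]),
                                    max_n=60, radius=1e9)
        assert pred[0] == pytest.approx(vals.mean())

    def test_coincident_points_deduplicated(self, exp_model):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 0.0]])
        vals = np.array([0.2, 0.6, 0.8])
        with pytest.warns(UserWarning, match="coincident"):
            pred, _ = ok_predict_points(pts, vals, exp_model,
                                        np.array([[0.0, 0.0]]), radius=1e9)
        assert pred[0] == pytest.approx(0.4)  # averaged duplicate

    def test_empty_neighborhood_masked(self, scattered_data, exp_model):
        pts, vals = scattered_data
        pred, var = ok_predict_points(pts, vals, exp_model,
                                      np.array([[500.0, 500.0]]), radius=10.0)
        assert np.isnan(pred[0]) and np.isnan(var[0])

    def test_grid_wrapper_shapes(self, scattered_data, exp_model):
        pts, vals = scattered_data
        geom = GridGeometry(0, 0, 5.0, 7, 7)
        grid = ok_predict(pts, vals, exp_model, geom)
        assert grid.prediction.shape == (7, 7)
        assert np.all(grid.variance[np.isfinite(grid.variance)] >= 0)


class TestNormalScores:
    def test_round_trip_identity_on_untied_data(self):
        v = np.random.default_rng(1).random(200)
        scores, nst = normal_scores(v)
        np.testing.assert_allclose(nst.back_transform(scores), v, atol=1e-12)

    def test_scores_are_standard_normal_ish(self):
        v = np.random.default_rng(2).lognormal(size=2000)
        scores, _ = normal_scores(v)
        assert scores.mean() == pytest.approx(0.0, abs=0.01)
        assert scores.std() == pytest.approx(1.0, abs=0.02)
        from scipy.stats import skew
        assert abs(skew(scores)) < 0.02

    def test_median_maps_near_zero(self):
        v = np.random.default_rng(3).random(501)
        scores, _ = normal_scores(v)
        assert scores[np.argsort(v)[250]] == pytest.approx(0.0, abs=1e-12)

    def test_out_of_range_scores_clipped_to_bounds(self):
        v = np.random.default_rng(4).random(50) * 0.5 + 0.2
        _, nst = normal_scores(v)
        out = nst.back_transform(np.array([-10.0, 10.0]), bounds=(0.0, 1.0))
        assert 0.0 <= out[0] <= v.min()
        assert v.max() <= out[1] <= 1.0

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            normal_scores(np.ones(10))


class TestSgcs:
    def test_zero_nugget_conditioning_exact(self, exp_model):
        m = VariogramModel("exponential", 0.0, 0.009, 8.0)
        geom = GridGeometry(0, 0, 1.0, 12, 12)
        nodes = geom.node_coords()
        rng = np.random.default_rng(11)
        di = rng.choice(nodes.shape[0], size=15, replace=False)
        dv = np.clip(0.56 + 0.09 * rng.standard_normal(15), 0.05, 0.95)
        res = sgcs(nodes[di], dv, m, geom, n_real=4, seed=3)
        flat = res.realizations.reshape(4, -1)
        np.testing.assert_allclose(flat[:, di], np.tile(dv, (4, 1)), atol=1e-7)

    def test_realizations_independent_and_reproducible(self, scattered_data):
        pts, vals = scattered_data
        m = VariogramModel("exponential", 0.0, 0.009, 8.0)
        coords = np.random.default_rng(9).uniform(0, 30, size=(40, 2))
        a = sgcs_points(pts, vals, m, coords, n_real=2, seed=7)
        b = sgcs_points(pts, vals, m, coords, n_real=2, seed=7)
        np.testing.assert_array_equal(a.realizations, b.realizations)
        assert not np.array_equal(a.realizations[0], a.realizations[1])

    def test_far_from_data_spread_matches_sill(self):
        # data confined to a corner; distant nodes are unconditioned, so the
        # ensemble spread there approaches the data marginal's sd (the sill's
        # square root when data variance == sill)
        m = VariogramModel("exponential", 0.0, 0.009, 4.0)
        rng = np.random.default_rng(13)
        dpts = rng.uniform(0, 8, size=(40, 2))
        raw = simulate_grf_at_points(dpts, m, seed=1)
        dv = 0.5 + (raw - raw.mean()) / raw.std() * np.sqrt(0.009)
        far = rng.uniform(30, 40, size=(25, 2))
        res = sgcs_points(dpts, dv, m, far, n_real=200, seed=2)
        assert res.realizations.std() == pytest.approx(np.sqrt(0.009), rel=0.15)

    def test_etype_matches_per_cell_loop_oracle(self):
        reals = np.random.default_rng(0).random((10, 5, 4))
        res = SgcsResult(reals, reals.mean(axis=0), reals.var(axis=0), seed=0)
        mean, var = etype(res)
        for i in range(5):
            for j in range(4):
                cell = [reals[r, i, j] for r in range(10)]
                assert mean[i, j] == pytest.approx(np.mean(cell))
                assert var[i, j] == pytest.approx(np.var(cell))

    def test_single_realization_etype(self, scattered_data):
        pts, vals = scattered_data
        m = VariogramModel("exponential", 0.0, 0.009, 8.0)
        coords = np.random.default_rng(1).uniform(0, 30, size=(20, 2))
        res = sgcs_points(pts, vals, m, coords, n_real=1, seed=0)
        np.testing.assert_array_equal(res.etype_mean, res.realizations[0])
        np.testing.assert_array_equal(res.etype_variance, 0.0)


class TestHoldoutValidation:
    def test_dense_smooth_field_high_r2(self):
        m = VariogramModel("exponential", 0.0, 0.009, 15.0)
        rng = np.random.default_rng(21)
        pts = rng.uniform(0, 40, size=(400, 2))
        vals = np.clip(0.56 + simulate_grf_at_points(pts, m, seed=2), 0, 1)
        res, table = holdout_validate(pts, vals, frac_train=0.8, seed=0,
                                      method="ok", model=m)
        assert res.r2 > 0.9
        assert table.shape[1] == 4  # x, y, observed, predicted

    def test_full_fraction_misuse_rejected(self, scattered_data):
        pts, vals = scattered_data
        with pytest.raises(ValueError):
            holdout_validate(pts, vals, frac_train=1.0)

    def test_same_seed_identical_metrics(self, scattered_data, exp_model):
        pts, vals = scattered_data
        a, _ = holdout_validate(pts, vals, seed=3, method="ok", model=exp_model)
        b, _ = holdout_validate(pts, vals, seed=3, method="ok", model=exp_model)
        assert (a.r2, a.rmse, a.n) == (b.r2, b.rmse, b.n)

    def test_sgcs_etype_route_runs(self, scattered_data):
        pts, vals = scattered_data
        m = VariogramModel("exponential", 0.0, 0.009, 8.0)
        res, _ = holdout_validate(pts, vals, seed=1, method="sgcs_etype",
                                  model=m, n_real=8)
        assert res.n == 12
        assert np.isfinite(res.rmse)


class TestSmoothingContrast:
    def test_ok_surface_smoother_than_any_realization(self):
        m = VariogramModel("exponential", 0.0, 0.009, 8.0)
        rng = np.random.default_rng(31)
        geom = GridGeometry(0, 0, 1.5, 16, 16)
        dpts = rng.uniform(0, 22, size=(40, 2))
        raw = simulate_grf_at_points(dpts, m, seed=4)
        dv = 0.5 + (raw - raw.mean()) / raw.std() * np.sqrt(0.009)
        ok = ok_predict(dpts, dv, m, geom, radius=1e9)
        sim = sgcs(dpts, dv, m, geom, n_real=10, seed=5)
        ok_var = np.nanvar(ok.prediction)
        for r in range(10):
            assert ok_var < np.var(sim.realizations[r])
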