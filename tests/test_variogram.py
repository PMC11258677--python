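"""Semivariogram estimation, model evaluation and fitting."""

import numpy as np
import pytest

from canopygeo import (EmpiricalVariogram, VariogramModel, anisotropy_ratio,
                       classify_nsr, directional_suite, empirical_variogram,
                       fit_model, model_gamma, simulate_grf_at_points)


def brute_force_variogram(points, values, lag_width, max_lag):
    """Independent oracle: exhaustive pair enumeration into bins."""
    n = len(values)
    bins = {}
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.hypot(*(points[i] - points[j])))
            if d > max_lag:
                continue
            b = min(int(d / lag_width), int(np.ceil(max_lag / lag_width)) - 1)
            bins.setdefault(b, []).append((d, 0.5 * (values[i] - values[j]) ** 2))
    out = {}
    for b, pairs in sorted(bins.items()):
        ds, sqs = zip(*pairs)
        out[b] = (np.mean(ds), np.mean(sqs), len(pairs))
    return out


class TestEmpiricalVariogram:
    def test_matches_pair_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        pts = rng.uniform(0, 10, size=(60, 2))
        vals = rng.random(60)
        emp = empirical_variogram(pts, vals, lag_width=1.5, max_lag=8.0)
        oracle = brute_force_variogram(pts, vals, 1.5, 8.0)
        assert len(emp) == len(oracle)
        for k, (lag, gamma, count) in enumerate(oracle.values()):
            assert emp.lags[k] == pytest.approx(lag)
            assert emp.gamma[k] == pytest.approx(gamma)
            assert emp.counts[k] == count

    def test_two_points_single_bin(self):
        pts = np.array([[0.0, 0.0], [3.0, 4.0]])
        emp = empirical_variogram(pts, [0.2, 0.8], lag_width=10.0, max_lag=10.0)
        assert len(emp) == 1
        assert emp.gamma[0] == pytest.approx(0.5 * 0.6**2)
        assert emp.counts[0] == 1

    def test_white_noise_is_flat_at_sigma2(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 100, size=(400, 2))
        vals = rng.normal(0, 2.0, size=400)
        emp = empirical_variogram(pts, vals, lag_width=10.0, max_lag=60.0)
        assert np.all(np.abs(emp.gamma - 4.0) < 0.8)
        # slope of gamma over lag is statistically indistinguishable from 0
        slope = np.polyfit(emp.lags, emp.gamma, 1)[0]
        assert abs(slope * emp.lags.max()) < 0.5

    def test_empty_result_error(self):
        pts = np.array([[0.0, 0.0], [100.0, 0.0]])
        with pytest.raises(ValueError):
            empirical_variogram(pts, [0.0, 1.0], lag_width=1.0, max_lag=5.0)


class TestModelGamma:
    @pytest.mark.parametrize("family", ["linear", "spherical", "exponential", "gaussian"])
    def test_zero_lag_is_zero(self, family):
        m = VariogramModel(family, 0.3, 0.7, 10.0)
        assert model_gamma(m, 0.0) == 0.0

    def test_reference_model_at_range(self, reference_model):
        # 0.0012 + 0.0077 * (1 - 1/e)
        assert model_gamma(reference_model, 10_200.0) == pytest.approx(0.006067, abs=1e-6)

    def test_exponential_sill_asymptote(self, reference_model):
        assert model_gamma(reference_model, 1e9) == pytest.approx(0.0089, rel=1e-9)
        assert reference_model.sill == pytest.approx(0.0089)

    def test_spherical_reaches_sill_at_range(self):
        m = VariogramModel("spherical", 0.1, 0.9, 5.0)
        assert model_gamma(m, 5.0) == pytest.approx(1.0)
        assert model_gamma(m, 50.0) == pytest.approx(1.0)

    def test_negative_lag_rejected(self, exp_model):
        with pytest.raises(ValueError):
            model_gamma(exp_model, -1.0)


class TestFit:
    def test_noiseless_bins_recover_exactly(self, reference_model):
        h = np.linspace(500, 30_000, 12)
        emp = EmpiricalVariogram(h, model_gamma(reference_model, h),
                                 np.full(h.size, 50))
        best, results = fit_model(emp)
        assert best.model.family == "exponential"
        assert best.r2 == pytest.approx(1.0, abs=1e-6)
        assert best.rss == pytest.approx(0.0, abs=1e-12)
        assert best.model.nugget == pytest.approx(0.0012, rel=0.01)
        assert best.model.partial_sill == pytest.approx(0.0077, rel=0.01)
        assert best.model.range_ == pytest.approx(10_200.0, rel=0.01)
        # the generating family's RSS beats (or ties) every other family
        for r in results:
            assert best.rss <= r.rss + 1e-15

    @pytest.mark.parametrize("family", ["spherical", "gaussian", "linear"])
    def test_other_families_also_selfrecover(self, family):
        truth = VariogramModel(family, 0.2, 0.8, 12.0)
        h = np.linspace(1, 40, 14)
        emp = EmpiricalVariogram(h, model_gamma(truth, h), np.full(h.size, 30))
        best, _ = fit_model(emp, families=[family])
        assert best.rss == pytest.approx(0.0, abs=1e-10)

    def test_nsr_classification(self):
        m = VariogramModel("exponential", 0.0012, 0.0077, 10_200.0)
        assert 100 * m.nsr == pytest.approx(13.48, abs=0.01)
        assert classify_nsr(m.nsr) == "strong"
        assert classify_nsr(0.5) == "moderate"
        assert classify_nsr(0.9) == "weak"

    def test_too_few_bins_rejected(self):
        emp = EmpiricalVariogram([1.0, 2.0, 3.0], [0.1, 0.2, 0.3], [5, 5, 5])
        with pytest.raises(ValueError):
            fit_model(emp)


class TestDirectional:
    def _aniso_points(self, seed=0, ratio=2.0, angle=135.0):
        """Geometric anisotropy: isotropic field on stretched coordinates."""
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 60, size=(700, 2))
        t = np.radians(angle)
        u = np.array([np.cos(t), np.sin(t)])
        v = np.array([-np.sin(t), np.cos(t)])
        # shrink the along-angle coordinate: correlation persists longest there
        stretched = np.column_stack([(pts @ u) / ratio, pts @ v])
        m = VariogramModel("exponential", 0.0, 1.0, 8.0)
        vals = simulate_grf_at_points(stretched, m, seed=seed)
        return pts, vals

    def test_isotropic_field_directions_agree(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 60, size=(600, 2))
        m = VariogramModel("exponential", 0.0, 1.0, 6.0)
        vals = simulate_grf_at_points(pts, m, seed=5)
        suite = directional_suite(pts, vals, lag_width=4.0, max_lag=24.0)
        omni = suite["omnidirectional"]
        for theta, ev in suite["directional"].items():
            assert ev is not None
            shared = np.isin(ev.lags, omni.lags)
            # directional curves stay near the omnidirectional one
            assert np.mean(np.abs(ev.gamma - np.interp(ev.lags, omni.lags, omni.gamma))
                           / omni.gamma.mean()) < 0.35

    def test_stretched_field_flags_slow_direction(self):
        pts, vals = self._aniso_points(seed=3)
        suite = directional_suite(pts, vals, lag_width=4.0, max_lag=24.0)
        g135 = suite["directional"][135.0]
        g45 = suite["directional"][45.0]
        # the 135-degree curve rises slowest at short lags
        k = min(3, len(g135), len(g45))
        assert np.mean(g135.gamma[:k]) < np.mean(g45.gamma[:k])

    def test_direction_assignment_matches_angle_oracle(self):
        rng = np.random.default_rng(9)
        pts = rng.uniform(0, 10, size=(40, 2))
        vals = rng.random(40)
        theta, tol = 45.0, 22.5
        emp = empirical_variogram(pts, vals, lag_width=3.0, max_lag=12.0,
                                  direction=theta, tolerance=tol)
        total = 0
        for i in range(40):
            for j in range(i + 1, 40):
                dx, dy = pts[j] - pts[i]
                d = np.hypot(dx, dy)
                if d > 12.0:
                    continue
                ang = np.degrees(np.arctan2(dy, dx)) % 180.0
                diff = min(abs(ang - theta), 180.0 - abs(ang - theta))
                total += diff <= tol
        assert emp.counts.sum() == total


class TestAnisotropyRatio:
    def test_identical_inputs_ratio_one(self):
        emp = EmpiricalVariogram([1.0, 2.0], [0.5, 0.8], [10, 10])
        lags, k = anisotropy_ratio(emp, emp)
        assert np.allclose(k, 1.0)

    def test_ratio_homogeneity(self):
        g1 = EmpiricalVariogram([1.0, 2.0], [0.5, 0.8], [10, 10])
        g2 = EmpiricalVariogram([1.0, 2.0], [0.25, 0.4], [10, 10])
        _, k = anisotropy_ratio(g2, g1)
        _, k2 = anisotropy_ratio(g1, g1)
        assert np.allclose(k, 0.5 * k2 * 1.0)
        doubled = EmpiricalVariogram([1.0, 2.0], [1.0, 1.6], [10, 10])
        _, k3 = anisotropy_ratio(doubled, g1)
        assert np.allclose(k3, 2.0)

    def test_isotropic_grf_ratio_near_one(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 60, size=(600, 2))
        m = VariogramModel("exponential", 0.0, 1.0, 6.0)
        vals = simulate_grf_at_points(pts, m, seed=2)
        g0 = empirical_variogram(pts, vals, lag_width=4.0, max_lag=20.0,
                                 direction=0.0)
        g90 = empirical_variogram(pts, vals, lag_width=4.0, max_lag=20.0,
                                  direction=90.0)
        _, k = anisotropy_ratio(g0, g90)
        assert np.mean(np.abs(k - 1.0)) < 0.2
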