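"""Kernel-density morphospace, the proportional-overlap statistic,
centroid-distance dispersion tests and rarefaction of variance."""

import numpy as np
import pytest
from scipy.stats import norm

from melanomorph.morphospace import (GridSpec, centroid_distance_test,
                                     density_from_grid_values, fit_density,
                                     proportional_overlap, rarefy_variance,
                                     shared_bandwidth,
                                     silverman_bandwidth_1d, total_variance)

TWO_PHI = 2 * norm.cdf(-1)  # minimum-overlap of unit normals offset by 2


def _grid(lo=-6, hi=8, n=151):
    return GridSpec(lo, hi, lo, hi, n, n)


def _normal_density(grid, mean):
    X, Y = np.meshgrid(grid.x, grid.y, indexing="ij")
    return density_from_grid_values(
        grid, norm.pdf(X, mean[0], 1.0) * norm.pdf(Y, mean[1], 1.0))


class TestFitDensity:
    def test_mode_at_cluster(self):
        grid = GridSpec(0, 10, 0, 10, 41, 41)
        pts = np.full((20, 2), 5.0) + np.random.default_rng(0).normal(0, 1e-3, (20, 2))
        d = fit_density(pts, grid, (0.5, 0.5))
        i, j = np.unravel_index(np.argmax(d.values), d.values.shape)
        assert grid.x[i] == pytest.approx(5.0, abs=0.26)
        assert grid.y[j] == pytest.approx(5.0, abs=0.26)

    def test_duplication_invariance(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(3, 1, (50, 2)) + 5
        grid = GridSpec(0, 16, 0, 16, 64, 64)
        a = fit_density(pts, grid, (0.5, 0.5))
        b = fit_density(np.vstack([pts, pts, pts]), grid, (0.5, 0.5))
        assert np.allclose(a.values, b.values, atol=1e-12)

    def test_points_outside_grid_error(self):
        grid = GridSpec(0, 1, 0, 1, 32, 32)
        with pytest.raises(ValueError, match="outside the grid"):
            fit_density(np.array([[0.5, 0.5], [2.0, 0.5], [0.5, 0.5]]),
                        grid, (0.1, 0.1))

    def test_kde_matches_analytic_density(self):
        # large-n KDE within 2% total variation of the discretized analytic
        # standard normal on the same grid
        grid = GridSpec(-5, 5, -5, 5, 151, 151)
        ana = _normal_density(grid, (0, 0))
        pts = np.random.default_rng(2).normal(0, 1, (100_000, 2))
        kde = fit_density(pts, grid, (0.2, 0.2))
        tv = 0.5 * np.abs(ana.values - kde.values).sum()
        assert tv < 0.02


class TestBandwidth:
    def test_zero_spread_error(self):
        with pytest.raises(ValueError, match="spread"):
            shared_bandwidth(np.ones((20, 2)))

    def test_too_few_points_error(self):
        with pytest.raises(ValueError, match="10"):
            shared_bandwidth(np.random.default_rng(0).normal(0, 1, (5, 2)))

    def test_scale_equivariance(self):
        pts = np.random.default_rng(3).normal(100, 10, (200, 2))
        h1 = shared_bandwidth(pts)
        h2 = shared_bandwidth(pts * 7.0)
        assert np.allclose(h2, 7.0 * h1, rtol=1e-12)

    def test_silverman_closed_form(self):
        # n=1000 standard normal: within 10% of sigma * (1/n)^(1/6)
        x = np.random.default_rng(4).normal(0, 1, 1000)
        expected = 1.0 * (1.0 / 1000) ** (1.0 / 6.0)
        assert silverman_bandwidth_1d(x) == pytest.approx(expected, rel=0.10)


class TestOverlap:
    def test_self_overlap_is_one(self):
        d = _normal_density(_grid(), (0, 0))
        assert proportional_overlap(d, d).overlap == pytest.approx(1.0, abs=1e-12)

    def test_symmetry_and_range(self):
        a = _normal_density(_grid(), (0, 0))
        b = _normal_density(_grid(), (1.3, 0.4))
        ab = proportional_overlap(a, b).overlap
        ba = proportional_overlap(b, a).overlap
        assert ab == ba
        assert 0.0 < ab < 1.0

    def test_disjoint_supports_near_zero(self):
        grid = GridSpec(-30, 30, -30, 30, 301, 301)
        rng = np.random.default_rng(5)
        a = fit_density(rng.normal(-20, 0.3, (500, 2)), grid, (0.3, 0.3))
        b = fit_density(rng.normal(20, 0.3, (500, 2)), grid, (0.3, 0.3))
        assert proportional_overlap(a, b).overlap < 1e-6

    def test_translation_monotonicity(self):
        grid = _grid(-8, 12, 201)
        prev = 1.0
        for delta in np.linspace(0.0, 6.0, 13):
            ov = proportional_overlap(_normal_density(grid, (0, 0)),
                                      _normal_density(grid, (delta, 0))).overlap
            assert ov <= prev + 1e-12
            prev = ov

    def test_gaussian_offset_analytic_value(self):
        grid = GridSpec(-7, 9, -8, 8, 301, 301)
        a = _normal_density(grid, (0, 0))
        b = _normal_density(grid, (2, 0))
        assert proportional_overlap(a, b).overlap == pytest.approx(TWO_PHI, abs=0.01)

    def test_kde_overlap_converges_to_analytic(self):
        # sampled normals, small bandwidth, fine grid
        rng = np.random.default_rng(42)
        grid = GridSpec(-6, 8, -6, 6, 201, 201)
        a = fit_density(rng.normal([0, 0], 1, (20_000, 2)), grid, (0.1, 0.1))
        b = fit_density(rng.normal([2, 0], 1, (20_000, 2)), grid, (0.1, 0.1))
        assert proportional_overlap(a, b).overlap == pytest.approx(TWO_PHI, abs=0.01)

    def test_grid_refinement_convergence(self):
        vals = []
        for n in (101, 202):
            grid = GridSpec(-7, 9, -8, 8, n, n)
            vals.append(proportional_overlap(
                _normal_density(grid, (0, 0)), _normal_density(grid, (2, 0))).overlap)
        assert abs(vals[0] - vals[1]) < 0.005

    def test_mismatched_grids_error(self):
        a = _normal_density(_grid(n=151), (0, 0))
        b = _normal_density(_grid(n=161), (0, 0))
        with pytest.raises(ValueError, match="grid"):
            proportional_overlap(a, b)

    def test_mismatched_bandwidth_error(self):
        grid = GridSpec(0, 10, 0, 10, 32, 32)
        pts = np.random.default_rng(0).uniform(2, 8, (30, 2))
        a = fit_density(pts, grid, (0.5, 0.5))
        b = fit_density(pts, grid, (0.6, 0.6))
        with pytest.raises(ValueError, match="bandwidth"):
            proportional_overlap(a, b)


class TestCentroidDistance:
    def test_translation_invariance(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, (100, 2))
        res = centroid_distance_test({"a": a, "b": a + 50.0}, standardize=False)
        assert res.f_statistic == pytest.approx(0.0, abs=1e-18)
        assert res.group_mean_distance["a"] == pytest.approx(
            res.group_mean_distance["b"], rel=1e-12)

    def test_scaling_triples_mean_distance(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, (100, 2))
        b = a.mean(0) + 3.0 * (a - a.mean(0))
        res = centroid_distance_test({"a": a, "b": b}, standardize=False)
        assert res.group_mean_distance["b"] == pytest.approx(
            3.0 * res.group_mean_distance["a"], rel=1e-9)

    def test_null_rejection_rate(self):
        # equal dispersion in both groups: p ~ uniform, ~5% rejections
        rej = 0
        reps = 400
        for rep in range(reps):
            rng = np.random.default_rng(90_000 + rep)
            res = centroid_distance_test(
                {"a": rng.normal(0, 1, (200, 2)), "b": rng.normal([4, 2], 1, (200, 2))})
            rej += res.p_value <= 0.05
        half_width = 1.96 * np.sqrt(0.05 * 0.95 / reps)
        assert abs(rej / reps - 0.05) < half_width + 0.01

    def test_degenerate_group_zero_distances(self):
        rng = np.random.default_rng(8)
        res = centroid_distance_test(
            {"a": np.full((10, 2), 3.0), "b": rng.normal(0, 1, (10, 2))},
            standardize=False)
        assert res.group_mean_distance["a"] == 0.0
        assert np.isfinite(res.f_statistic)


class TestRarefaction:
    def test_full_size_exact_zero_spread(self):
        pts = np.random.default_rng(9).normal(0, 1, (60, 2))
        curve = rarefy_variance(pts, [10, 30, 60], n_reps=150, seed=1)
        assert curve.mean[-1] == curve.full_value
        assert curve.upper[-1] - curve.lower[-1] == 0.0
        assert curve.full_value == pytest.approx(total_variance(pts))

    def test_determinism(self):
        pts = np.random.default_rng(10).normal(0, 1, (80, 2))
        a = rarefy_variance(pts, [20, 40], n_reps=120, seed=5)
        b = rarefy_variance(pts, [20, 40], n_reps=120, seed=5)
        assert np.array_equal(a.mean, b.mean)
        assert np.array_equal(a.lower, b.lower)

    def test_unbiased_under_subsampling(self):
        # n-1 variance estimator is unbiased under without-replacement
        # subsampling of an iid normal sample
        rng = np.random.default_rng(11)
        pts = rng.normal(0, 2, (2000, 2))
        curve = rarefy_variance(pts, [50], n_reps=2000, seed=2)
        full = total_variance(pts)
        se = curve.mean[0] * np.sqrt(2 / (50 - 1)) / np.sqrt(2000)
        assert abs(curve.mean[0] - full) < 3 * se * np.sqrt(2)

    def test_size_errors(self):
        pts = np.random.default_rng(0).normal(0, 1, (30, 2))
        with pytest.raises(ValueError):
            rarefy_variance(pts, [1, 10], n_reps=100, seed=0)
        with pytest.raises(ValueError):
            rarefy_variance(pts, [40], n_reps=100, seed=0)
        with pytest.raises(ValueError):
            rarefy_variance(pts, [10], n_reps=50, seed=0)
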