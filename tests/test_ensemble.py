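"""Ensemble projection, averaged distance matrices, and diagnostics."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

import reefscape as rs
from reefscape.ensemble import ProjectionEnsemble


def _random_ensemble(n_repeats, n_samples, dims=3, seed=0):
    rng = np.random.default_rng(seed)
    return ProjectionEnsemble.from_point_sets(
        rng.standard_normal((n_repeats, n_samples, dims))
    )


class TestFromPointSets:
    def test_average_is_elementwise_mean_of_planted_repeats(self):
        # two hand-built 3-point configurations on a line
        p1 = np.array([[0.0], [1.0], [3.0]])
        p2 = np.array([[0.0], [2.0], [5.0]])
        ens = ProjectionEnsemble.from_point_sets([p1, p2])
        d1 = np.array([[0, 1, 3], [1, 0, 2], [3, 2, 0]], dtype=float)
        d2 = np.array([[0, 2, 5], [2, 0, 3], [5, 3, 0]], dtype=float)
        np.testing.assert_allclose(ens.avg_distance, (d1 + d2) / 2)

    def test_average_matrix_is_symmetric_zero_diagonal_nonnegative(self):
        ens = _random_ensemble(4, 12)
        D = ens.avg_distance
        np.testing.assert_allclose(D, D.T)
        np.testing.assert_allclose(np.diag(D), 0.0)
        assert D.min() >= 0

    def test_average_satisfies_triangle_inequality(self):
        # the elementwise mean of Euclidean matrices stays metric
        for seed in range(3):
            D = _random_ensemble(5, 15, seed=seed).avg_distance
            n = D.shape[0]
            for i in range(n):
                for j in range(n):
                    for k in range(n):
                        assert D[i, k] <= D[i, j] + D[j, k] + 1e-9


class TestRunEnsemble:
    def test_single_repeat_average_equals_its_distance_matrix(self):
        X = np.random.default_rng(0).standard_normal((30, 8))
        ens = rs.run_ensemble(X, n_repeats=1, n_components=2)
        np.testing.assert_array_equal(ens.avg_distance, ens.distance_matrices[0])

    def test_same_base_seed_reproduces_bitwise(self):
        X = np.random.default_rng(1).standard_normal((30, 8))
        a = rs.run_ensemble(X, n_repeats=2, n_components=2, base_seed=5)
        b = rs.run_ensemble(X, n_repeats=2, n_components=2, base_seed=5)
        np.testing.assert_array_equal(a.avg_distance, b.avg_distance)
        assert a.seeds == [5, 6]

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="samples"):
            rs.run_ensemble(np.ones((3, 4)), n_components=3)

    def test_projection_increases_distance_contrast_on_clustered_data(self):
        # counterpart of the observation that the projection roughly doubles
        # the IQM relative to raw high-dimensional distances
        rng = np.random.default_rng(2)
        centers = rng.standard_normal((3, 30)) * 4
        X = np.vstack([c + 0.5 * rng.standard_normal((20, 30)) for c in centers])
        ens = rs.run_ensemble(X, n_repeats=3, n_components=3, base_seed=0)
        assert rs.iqm(ens.avg_distance) > rs.iqm(squareform(pdist(X)))


class TestConvergence:
    def test_identical_repeats_give_zero_diffs(self):
        p = np.random.default_rng(0).standard_normal((10, 3))
        ens = ProjectionEnsemble.from_point_sets([p, p, p])
        conv = rs.convergence(ens)
        np.testing.assert_allclose(conv.rel_mean_abs_diff, 0.0, atol=1e-12)
        np.testing.assert_allclose(conv.rel_max_abs_diff, 0.0, atol=1e-12)

    def test_two_repeats_match_running_mean_identity(self):
        # with N = 2 the running means are M1 = D1, M2 = (D1 + D2)/2, so the
        # diff is |D2 - D1| / 2 normalized by the mean off-diagonal of D1
        ens = _random_ensemble(2, 8, seed=3)
        d1, d2 = ens.distance_matrices
        iu = np.triu_indices(8, k=1)
        expected = np.mean(np.abs(d2 - d1)[iu] / 2) / np.mean(d1[iu])
        conv = rs.convergence(ens)
        assert conv.rel_mean_abs_diff[0] == pytest.approx(expected, rel=1e-12)

    def test_iid_repeats_diff_series_decays(self):
        # Monte-Carlo: for i.i.d. repeats the running mean converges, so the
        # log-log slope of the diff series must be negative
        conv = rs.convergence(_random_ensemble(50, 25, seed=4))
        slope = np.polyfit(np.log(conv.n), np.log(conv.rel_mean_abs_diff), 1)[0]
        assert slope < 0

    def test_mean_diff_bounded_by_max_diff(self):
        conv = rs.convergence(_random_ensemble(20, 15, seed=5))
        assert np.all(conv.rel_mean_abs_diff <= conv.rel_max_abs_diff + 1e-15)


class TestIqm:
    def test_equidistant_points_give_zero(self):
        D = np.ones((4, 4)) - np.eye(4)
        assert rs.iqm(D) == 0.0

    def test_four_points_on_a_line(self):
        # points at 0, 1, 2, 4 enumerate distances {1, 2, 4, 1, 3, 2}
        pts = np.array([[0.0], [1.0], [2.0], [4.0]])
        dists = [1.0, 2.0, 4.0, 1.0, 3.0, 2.0]
        q1, med, q3 = np.quantile(dists, [0.25, 0.5, 0.75], method="linear")
        expected = (q3 - q1) / med
        D = squareform(pdist(pts))
        assert rs.iqm(D) == pytest.approx(expected, rel=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(1e-3, 1e3))
    def test_scale_invariance(self, seed, c):
        D = _random_ensemble(1, 10, seed=seed).avg_distance
        assert rs.iqm(c * D) == pytest.approx(rs.iqm(D), rel=1e-9)

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError, match="median"):
            rs.iqm(np.zeros((4, 4)))


class TestTopologyDiagnostics:
    def test_identity_embedding_scores_one(self):
        X = np.random.default_rng(0).standard_normal((40, 5))
        assert rs.dlp(X, X.copy(), k=10) == 1.0
        assert rs.rta(X, X.copy(), n_triplets=2000, seed=0) == 1.0

    def test_k_equals_n_minus_one_is_trivially_one(self):
        rng = np.random.default_rng(1)
        X, Y = rng.standard_normal((2, 25, 4))
        assert rs.dlp(X, Y, k=24) == 1.0

    def test_random_embedding_matches_chance_levels(self):
        rng = np.random.default_rng(7)
        n, k = 200, 20
        X = rng.standard_normal((n, 10))
        Y = rng.standard_normal((n, 3))
        assert rs.dlp(X, Y, k=k) == pytest.approx(k / (n - 1), abs=0.05)
        assert rs.rta(X, Y, n_triplets=50_000, seed=1) == pytest.approx(0.5, abs=0.05)

    def test_rta_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        X, Y = rng.standard_normal((2, 30, 4))
        assert rs.rta(X, Y, 5000, seed=9) == rs.rta(X, Y, 5000, seed=9)


class TestPca:
    def test_planar_data_fully_explained_by_two_components(self):
        rng = np.random.default_rng(0)
        basis = rng.standard_normal((2, 10))
        X = rng.standard_normal((50, 2)) @ basis
        _, frac = rs.pca_project(X, 2)
        assert frac.sum() == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_cloud_spreads_variance_evenly(self):
        # eigenvalue oracle: the sample covariance of an isotropic Gaussian
        # has nearly equal eigenvalues, so each fraction is close to 1/d
        X = np.random.default_rng(1).standard_normal((4000, 4))
        _, frac = rs.pca_project(X, 4)
        np.testing.assert_allclose(frac, 0.25, atol=0.02)
        assert np.all(np.diff(frac) <= 1e-12)

    def test_deterministic_axes(self):
        X = np.random.default_rng(2).standard_normal((30, 6))
        p1, _ = rs.pca_project(X, 3)
        p2, _ = rs.pca_project(X, 3)
        np.testing.assert_array_equal(p1, p2)

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            rs.pca_project(np.ones((5, 3)), 5)

    def test_pca_method_forces_single_repeat(self):
        X = np.random.default_rng(3).standard_normal((20, 6))
        ens = rs.run_ensemble(X, method="pca", n_components=2, n_repeats=50)
        assert ens.n_repeats == 1
        assert ens.method == "pca"
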