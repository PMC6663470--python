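import numpy as np
import pytest
import scipy.linalg

import specguide as sg
from specguide.guided_embedding import _criterion_for

from conftest import random_weighted_graph


def _parts(g):
    ops = sg.normalize(g)
    basis = sg.eigendecompose(ops)
    return ops, basis, sg.sqrt_laplacian_exact(basis)


class TestCriterionExact:
    def test_identity_reverts_to_adjacency(self, fixture_ops, fixture_sqrtL):
        """M = I collapses the criterion matrix to the normalized adjacency."""
        coop = sg.CooperationProfile.identity(fixture_ops.n_nodes)
        C = sg.criterion_matrix_exact(fixture_ops, fixture_sqrtL, coop)
        assert np.max(np.abs(C - fixture_ops.A)) < 1e-12

    def test_zero_profile_zero_matrix(self, fixture_ops, fixture_sqrtL):
        coop = sg.CooperationProfile(np.zeros(fixture_ops.n_nodes))
        C = sg.criterion_matrix_exact(fixture_ops, fixture_sqrtL, coop)
        np.testing.assert_allclose(C, 0.0, atol=1e-14)

    def test_triangle_alternate_sqrt_route(self, triangle):
        """Entrywise agreement with an independent square root (scipy.linalg.sqrtm,
        Schur-based) instead of the spectral reconstruction."""
        ops, basis, sqrtL = _parts(triangle)
        coop = sg.CooperationProfile(np.array([1., 1., 0.]))
        C = sg.criterion_matrix_exact(ops, sqrtL, coop)
        S2 = np.real(scipy.linalg.sqrtm(ops.L))
        C2 = np.diag(coop.m) - S2 @ np.diag(coop.m) @ S2
        np.testing.assert_allclose(C, C2, atol=1e-8)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            sg.CooperationProfile(np.array([1.0, -0.5]))


class TestCriterionApproximations:
    def test_linear_identity_is_A(self, fixture_ops):
        coop = sg.CooperationProfile.identity(fixture_ops.n_nodes)
        np.testing.assert_allclose(
            sg.criterion_matrix_linear(fixture_ops, coop), fixture_ops.A,
            atol=1e-14)

    def test_linear_entrywise_average(self, fixture_ops):
        """Edge (i,j) is reweighted by the mean cooperation (m_i + m_j)/2;
        an edge with one zero endpoint survives at half weight."""
        n = fixture_ops.n_nodes
        rng = np.random.default_rng(1)
        m = rng.uniform(0, 2, n)
        C = sg.criterion_matrix_linear(fixture_ops, sg.CooperationProfile(m))
        i, j = np.nonzero(fixture_ops.A)
        np.testing.assert_allclose(
            C[i, j], fixture_ops.A[i, j] * (m[i] + m[j]) / 2, atol=1e-14)
        m01 = np.ones(n)
        m01[0] = 0.0
        C01 = sg.criterion_matrix_linear(fixture_ops, sg.CooperationProfile(m01))
        j0 = np.flatnonzero(fixture_ops.A[0])[0]
        assert C01[0, j0] == pytest.approx(fixture_ops.A[0, j0] / 2)

    def test_quadratic_identity_is_A(self, fixture_ops):
        """At M = I the length-2-path terms cancel: A + 2A^2/8 - A^2/4 = A."""
        coop = sg.CooperationProfile.identity(fixture_ops.n_nodes)
        np.testing.assert_allclose(
            sg.criterion_matrix_quadratic(fixture_ops, coop), fixture_ops.A,
            atol=1e-12)

    def test_quadratic_triangle_hand_computed(self, triangle):
        """K3 with m = (1,1,0): entry (1,2) = a12*1 + [2 a13 a32 /8 - 0*a13 a32/4]
        since the only length-2 path 1-3-2 is penalized by m3 = 0."""
        ops, _, _ = _parts(triangle)
        m = np.array([1., 1., 0.])
        C = sg.criterion_matrix_quadratic(ops, sg.CooperationProfile(m))
        a = 0.5  # every normalized entry of K3
        # linear part: a * (m1+m2)/2 = 0.5; quadratic: (m1+m2)*a*a/8 - m3*a*a/4
        expected_12 = a * 1.0 + 2 * a * a / 8 - 0.0
        assert C[0, 1] == pytest.approx(expected_12, abs=1e-12)
        # entry (1,3): linear a*(1+0)/2; paths 1-2-3 penalized by m2 = 1
        expected_13 = a * 0.5 + 1.0 * a * a / 8 - 1.0 * a * a / 4
        assert C[0, 2] == pytest.approx(expected_13, abs=1e-12)

    def test_quadratic_beats_linear_mostly(self, fixture_ops, fixture_sqrtL):
        n = fixture_ops.n_nodes
        wins = 0
        for seed in range(20):
            m = np.random.default_rng(seed).uniform(0, 1.5, n)
            coop = sg.CooperationProfile(m)
            C = sg.criterion_matrix_exact(fixture_ops, fixture_sqrtL, coop)
            d_lin = np.linalg.norm(
                C - sg.criterion_matrix_linear(fixture_ops, coop), "fro")
            d_quad = np.linalg.norm(
                C - sg.criterion_matrix_quadratic(fixture_ops, coop), "fro")
            wins += d_quad <= d_lin
        assert wins >= 16  # vast majority of trials

    def test_orderK_error_nonincreasing(self, fixture_ops, fixture_sqrtL):
        n = fixture_ops.n_nodes
        for seed in range(20):
            m = np.random.default_rng(100 + seed).uniform(0, 1.5, n)
            coop = sg.CooperationProfile(m)
            C = sg.criterion_matrix_exact(fixture_ops, fixture_sqrtL, coop)
            ds = [np.linalg.norm(
                C - sg.criterion_matrix_orderK(fixture_ops, coop, K), "fro")
                for K in (1, 2, 5, 10, 20)]
            assert all(a >= b - 1e-10 for a, b in zip(ds, ds[1:]))

    def test_approximation_hierarchy(self, fixture_ops, fixture_sqrtL):
        """exact-vs-linear >= exact-vs-quadratic >= exact-vs-order20."""
        n = fixture_ops.n_nodes
        m = np.random.default_rng(9).uniform(0, 1.2, n)
        coop = sg.CooperationProfile(m)
        C = sg.criterion_matrix_exact(fixture_ops, fixture_sqrtL, coop)
        d_lin = np.linalg.norm(C - sg.criterion_matrix_linear(fixture_ops, coop), "fro")
        d_quad = np.linalg.norm(
            C - sg.criterion_matrix_quadratic(fixture_ops, coop), "fro")
        d_20 = np.linalg.norm(
            C - sg.criterion_matrix_orderK(fixture_ops, coop, 20), "fro")
        assert d_lin >= d_quad >= d_20

    def test_orderK_high_order_spectrum_close(self, fixture_ops, fixture_sqrtL):
        """Order-20 spectrum is indistinguishable from exact except possibly
        at the very top: the bulk error is far below the top-3 error scale."""
        n = fixture_ops.n_nodes
        coop = sg.CooperationProfile((np.arange(n) < n // 2).astype(float))
        C = sg.criterion_matrix_exact(fixture_ops, fixture_sqrtL, coop)
        C20 = sg.criterion_matrix_orderK(fixture_ops, coop, 20)
        z = np.sort(scipy.linalg.eigvalsh(C))[::-1]
        z20 = np.sort(scipy.linalg.eigvalsh(C20))[::-1]
        diff = np.abs(z - z20)
        assert diff[3:].max() <= 10 * max(diff[:3].max(), 1e-12)


class TestGuidedSpectrum:
    def test_triangle_identity_adjacency_spectrum(self, triangle):
        ops, basis, sqrtL = _parts(triangle)
        coop = sg.CooperationProfile.identity(3)
        C = sg.criterion_matrix_exact(ops, sqrtL, coop)
        spec = sg.guided_spectrum(C, ops, sqrtL, coop)
        np.testing.assert_allclose(spec.zetas, [1.0, -0.5, -0.5], atol=1e-10)

    def test_zero_profile(self, fixture_ops, fixture_sqrtL):
        n = fixture_ops.n_nodes
        coop = sg.CooperationProfile(np.zeros(n))
        C = sg.criterion_matrix_exact(fixture_ops, fixture_sqrtL, coop)
        spec = sg.guided_spectrum(C, fixture_ops, fixture_sqrtL, coop)
        np.testing.assert_allclose(spec.zetas, 0.0, atol=1e-12)

    def test_rayleigh_decomposition(self, fixture_ops, fixture_sqrtL):
        """zeta_k = mu_k - xi_k for the exact criterion."""
        n = fixture_ops.n_nodes
        m = np.random.default_rng(2).uniform(0, 1.5, n)
        coop = sg.CooperationProfile(m)
        C = sg.criterion_matrix_exact(fixture_ops, fixture_sqrtL, coop)
        spec = sg.guided_spectrum(C, fixture_ops, fixture_sqrtL, coop)
        np.testing.assert_allclose(
            spec.zetas, spec.mu_equiv - spec.xi_equiv, atol=1e-8)

    def test_bounds_hold_over_seeds(self):
        """m_max >= zeta_1 and zeta_N >= -2 m_max on 50 random profiles."""
        g = sg.synth_fixture((10, 10, 10), 0.4, 0.1, seed=0)
        ops, _, sqrtL = _parts(g)
        for seed in range(50):
            m = np.random.default_rng(seed).uniform(0, 3.0, 30)
            coop = sg.CooperationProfile(m)
            C = sg.criterion_matrix_exact(ops, sqrtL, coop)
            spec = sg.guided_spectrum(C, ops, sqrtL, coop)
            assert spec.zetas[0] <= coop.m_max + 1e-8
            assert spec.zetas[-1] >= -2 * coop.m_max - 1e-8

    def test_outside_subspace_mid_spectrum(self, fixture_ops, fixture_sqrtL):
        """With binary M, eigenvectors with zeta ~ 0 in mid-spectrum have both
        mu ~ 0 and xi ~ 0: they concentrate (almost) entirely outside the
        focus set.  The joint null is approximate, not exact — the two
        individual null spaces intersect trivially in general — so mu and
        xi are small but not machine-zero."""
        n = fixture_ops.n_nodes
        s = (np.arange(n) < 2 * n // 3).astype(float)
        coop = sg.CooperationProfile(s)
        C = sg.criterion_matrix_exact(fixture_ops, fixture_sqrtL, coop)
        spec = sg.guided_spectrum(C, fixture_ops, fixture_sqrtL, coop)
        zero_z = np.abs(spec.zetas) < 1e-6
        assert zero_z.sum() > 0
        assert np.all(np.abs(spec.mu_equiv[zero_z]) < 1e-3)
        assert np.all(np.abs(spec.xi_equiv[zero_z]) < 1e-3)
        np.testing.assert_allclose(
            spec.mu_equiv[zero_z], spec.xi_equiv[zero_z], atol=1e-6)

    def test_few_jointly_optimal_eigenvectors(self, fixture_ops, fixture_sqrtL):
        """Only a few eigenvectors combine high concentration with low
        localized frequency."""
        n = fixture_ops.n_nodes
        s = (np.arange(n) < n // 2).astype(float)
        coop = sg.CooperationProfile(s)
        C = sg.criterion_matrix_exact(fixture_ops, fixture_sqrtL, coop)
        spec = sg.guided_spectrum(C, fixture_ops, fixture_sqrtL, coop)
        tol = 0.1
        joint = np.sum((spec.mu_equiv > 1 - tol) & (spec.xi_equiv < tol))
        assert joint <= (n // 2) / 2

    def test_asymmetric_input_rejected(self, fixture_ops, fixture_sqrtL):
        n = fixture_ops.n_nodes
        bad = np.triu(np.ones((n, n)))
        with pytest.raises(ValueError, match="symmetric"):
            sg.guided_spectrum(bad, fixture_ops, fixture_sqrtL,
                               sg.CooperationProfile.identity(n))


class TestEmbed:
    def test_unguided_equals_adjacency_embedding(self, fixture_ops, fixture_sqrtL):
        n = fixture_ops.n_nodes
        coop = sg.CooperationProfile.identity(n)
        C = sg.criterion_matrix_exact(fixture_ops, fixture_sqrtL, coop)
        spec = sg.guided_spectrum(C, fixture_ops, fixture_sqrtL, coop)
        lam, V = scipy.linalg.eigh(fixture_ops.A)
        order = np.argsort(lam)[::-1]
        V = V[:, order]
        X = sg.embed(spec, (2, 3))
        for col in range(2):
            v = V[:, col + 1]
            x = X[:, col]
            assert min(np.linalg.norm(x - v), np.linalg.norm(x + v)) < 1e-8

    def test_different_pairs_differ(self, fixture_ops, fixture_sqrtL):
        n = fixture_ops.n_nodes
        coop = sg.CooperationProfile.identity(n)
        C = sg.criterion_matrix_exact(fixture_ops, fixture_sqrtL, coop)
        spec = sg.guided_spectrum(C, fixture_ops, fixture_sqrtL, coop)
        X12 = sg.embed(spec, (1, 2))
        X23 = sg.embed(spec, (2, 3))
        assert not np.allclose(X12, X23)

    def test_ring_baseline_lies_on_circle(self):
        """Laplacian embedding of a ring: sine/cosine eigenvectors put all
        nodes on a circle."""
        n = 40
        A = np.zeros((n, n))
        idx = np.arange(n)
        A[idx, (idx + 1) % n] = 1.0
        A = A + A.T
        g = sg.Graph(node_ids=[str(i) for i in range(n)], A_raw=A)
        basis = sg.eigendecompose(sg.normalize(g))
        X = basis.U[:, 1:3]  # second and third smallest eigenvalues
        r = np.linalg.norm(X, axis=1)
        assert np.std(r) / np.mean(r) < 1e-8

    def test_degenerate_pair_warns(self, triangle):
        ops, basis, sqrtL = _parts(triangle)
        coop = sg.CooperationProfile.identity(3)
        C = sg.criterion_matrix_exact(ops, sqrtL, coop)
        spec = sg.guided_spectrum(C, ops, sqrtL, coop)
        with pytest.warns(UserWarning, match="degenerate"):
            sg.embed(spec, (2, 3))  # zeta_2 = zeta_3 = -1/2 on K3


class TestProcrustes:
    def test_self_alignment_identity(self):
        X = np.random.default_rng(0).normal(size=(20, 2))
        aligned, R = sg.procrustes_align(X, X)
        np.testing.assert_allclose(R, np.eye(2), atol=1e-10)
        np.testing.assert_allclose(aligned, X, atol=1e-10)

    def test_exact_recovery_of_planted_rotation(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 2))
        theta = 1.1
        R0 = np.array([[np.cos(theta), -np.sin(theta)],
                       [np.sin(theta), np.cos(theta)]])
        aligned, R = sg.procrustes_align(X, X @ R0)
        assert np.linalg.norm(aligned - X @ R0, "fro") <= 1e-10
        np.testing.assert_allclose(R.T @ R, np.eye(2), atol=1e-12)

    def test_reflection_recovered(self):
        X = np.random.default_rng(2).normal(size=(25, 2))
        F = np.array([[1.0, 0.0], [0.0, -1.0]])
        aligned, _ = sg.procrustes_align(X, X @ F)
        assert np.linalg.norm(aligned - X @ F, "fro") <= 1e-10

    def test_noisy_alignment_beats_unaligned(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(40, 2))
            theta = rng.uniform(0.3, 3.0)
            R0 = np.array([[np.cos(theta), -np.sin(theta)],
                           [np.sin(theta), np.cos(theta)]])
            Y = X @ R0 + 0.05 * rng.normal(size=X.shape)
            aligned, R = sg.procrustes_align(X, Y)
            assert (np.linalg.norm(aligned - Y, "fro")
                    <= np.linalg.norm(X - Y, "fro"))
            np.testing.assert_allclose(R.T @ R, np.eye(2), atol=1e-10)

    def test_rank_zero_warns_identity(self):
        X = np.zeros((5, 2))
        with pytest.warns(UserWarning, match="rank-0"):
            aligned, R = sg.procrustes_align(X, np.zeros((5, 2)))
        np.testing.assert_array_equal(R, np.eye(2))


class TestFocusSweep:
    def test_focus_all_is_flat(self, fixture_graph):
        n = fixture_graph.n_nodes
        traj = sg.focus_sweep(fixture_graph, np.arange(n), n_steps=5)
        for si in range(1, 5):
            np.testing.assert_allclose(traj.coords[si], traj.coords[0],
                                       atol=1e-8)

    def test_endpoint_consistent_with_single_shot(self, fixture_graph):
        """The final step equals a direct m=0-off-focus computation up to an
        orthogonal transform (norms and pairwise distances preserved)."""
        n = fixture_graph.n_nodes
        focus = np.arange(n // 3)
        traj = sg.focus_sweep(fixture_graph, focus, n_steps=6)
        ops = sg.normalize(fixture_graph)
        basis = sg.eigendecompose(ops)
        sqrtL = sg.sqrt_laplacian_exact(basis)
        coop = sg.CooperationProfile.focus(n, focus, 0.0)
        C = sg.criterion_matrix_exact(ops, sqrtL, coop)
        spec = sg.guided_spectrum(C, ops, sqrtL, coop)
        X = sg.embed(spec, (2, 3))
        np.testing.assert_allclose(
            np.linalg.norm(traj.endpoint, axis=1),
            np.linalg.norm(X, axis=1), atol=1e-8)
        _, R = sg.procrustes_align(X, traj.endpoint)
        np.testing.assert_allclose(X @ R, traj.endpoint, atol=1e-8)

    def test_focus_class_moves_to_periphery(self, fixture_graph):
        """At t = 0 the focus class sits farther from the origin, on average,
        than the de-emphasized nodes (empirical on the packaged fixture)."""
        focus = fixture_graph.class_indices("A")
        traj = sg.focus_sweep(fixture_graph, focus, n_steps=11)
        r = np.linalg.norm(traj.endpoint, axis=1)
        mask = np.zeros(fixture_graph.n_nodes, bool)
        mask[focus] = True
        assert r[mask].mean() > r[~mask].mean()

    def test_transforms_orthogonal(self, fixture_graph):
        traj = sg.focus_sweep(
            fixture_graph, fixture_graph.class_indices("B"), n_steps=6)
        for R in traj.transforms:
            np.testing.assert_allclose(R.T @ R, np.eye(2), atol=1e-10)

    def test_linear_approx_runs(self, fixture_graph):
        traj = sg.focus_sweep(fixture_graph,
                              fixture_graph.class_indices("A"),
                              n_steps=4, approx="linear")
        assert traj.coords.shape[0] == 4

    def test_disconnected_rejected(self):
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = 1.0
        A[2, 3] = A[3, 2] = 1.0
        g = sg.Graph(node_ids=list("abcd"), A_raw=A)
        with pytest.raises(ValueError, match="connected"):
            sg.focus_sweep(g, np.array([0]), n_steps=3)

    def test_bad_steps_rejected(self, fixture_graph):
        with pytest.raises(ValueError):
            sg.focus_sweep(fixture_graph, np.array([0]), n_steps=1)
        with pytest.raises(ValueError):
            sg.focus_sweep(fixture_graph, np.array([]), n_steps=5)


class TestClusterEndpoint:
    def _blob_trajectory(self):
        rng = np.random.default_rng(0)
        blob1 = rng.normal([3, 3], 0.1, size=(15, 2))
        blob2 = rng.normal([-3, -3], 0.1, size=(15, 2))
        coords = np.vstack([blob1, blob2])[None, :, :].repeat(2, axis=0)
        return sg.Trajectory(
            steps=np.array([1.0, 0.0]),
            coords=coords,
            focus_idx=np.arange(30),
            node_ids=[str(i) for i in range(30)],
        )

    def test_two_planted_blobs_recovered(self):
        traj = self._blob_trajectory()
        labels, k, sil = sg.cluster_endpoint(traj, range(2, 6), seed=0)
        assert k == 2
        assert len(set(labels[:15])) == 1 and len(set(labels[15:])) == 1
        assert sil > 0.9

    def test_k_one_rejected(self):
        with pytest.raises(ValueError, match="k must be >= 2"):
            sg.cluster_endpoint(self._blob_trajectory(), [1], seed=0)

    def test_too_many_clusters_rejected(self):
        with pytest.raises(ValueError):
            sg.cluster_endpoint(self._blob_trajectory(), range(2, 40), seed=0)

    def test_seed_determinism(self):
        traj = self._blob_trajectory()
        l1, k1, _ = sg.cluster_endpoint(traj, range(2, 6), seed=3)
        l2, k2, _ = sg.cluster_endpoint(traj, range(2, 6), seed=3)
        assert k1 == k2
        np.testing.assert_array_equal(l1, l2)
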