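"""Covariance PCA, cosine content, generalized correlation and networks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import topotraj as tt
from topotraj.correlation import cosine_content_of
from conftest import pseudo_ca_topology, random_rigid_motion


class TestCovariancePca:
    def test_single_axis_oscillation(self):
        n = 200
        coords = np.zeros((n, 1, 3))
        coords[:, 0, 0] = np.sin(np.linspace(0, 6 * np.pi, n))
        traj = tt.Trajectory(pseudo_ca_topology(1), coords)
        m = tt.covariance_pca(traj)
        assert m.eigenvalues[0] > 1e-3
        np.testing.assert_allclose(m.eigenvalues[1:], 0.0, atol=1e-12)
        np.testing.assert_allclose(np.abs(m.eigenvectors[:, 0]), [1, 0, 0], atol=1e-10)

    def test_anticorrelated_pair_analytic(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 4000)
        coords = np.zeros((4000, 2, 3))
        coords[:, 0, 0] = a
        coords[:, 1, 0] = -a
        m = tt.covariance_pca(tt.Trajectory(pseudo_ca_topology(2), coords))
        assert m.eigenvalues[0] == pytest.approx(2 * a.var(ddof=1), rel=1e-10)
        v = m.eigenvectors[:, 0]
        # antisymmetric x-mode
        assert abs(v[0]) == pytest.approx(abs(v[3]), abs=1e-10)
        assert v[0] * v[3] < 0

    def test_isotropic_noise_eigenvalue_spread(self):
        ens = tt.sample_correlated_ensemble(tt.EnsembleRecipe(4, 6000, seed=5))
        m = tt.covariance_pca(ens)
        assert m.eigenvalues[0] / m.eigenvalues[-1] < 1.25

    def test_psd_and_trace_identity(self):
        ens = tt.sample_correlated_ensemble(
            tt.EnsembleRecipe(3, 500, seed=8, covariance=tt.isotropic_correlation_cov(
                tt.block_correlation_matrix(3, [[0, 1]], 0.7)))
        )
        m = tt.covariance_pca(ens)
        assert m.eigenvalues.min() >= -1e-8
        assert m.eigenvalues.sum() == pytest.approx(np.trace(m.covariance), rel=1e-8)

    def test_zero_variance_trajectory(self):
        traj = tt.Trajectory(pseudo_ca_topology(2), np.ones((5, 2, 3)))
        m = tt.covariance_pca(traj)
        np.testing.assert_allclose(m.eigenvalues, 0.0, atol=1e-14)


class TestCosineContent:
    def test_exact_cosine_is_one(self):
        N = 500
        p = np.cos(np.pi * (np.arange(N) + 0.5) / N)
        assert cosine_content_of(p, 1) == pytest.approx(1.0, abs=1e-9)

    def test_constant_projection_is_zero(self):
        assert cosine_content_of(np.full(400, 2.5), 1) == pytest.approx(0.0, abs=1e-12)

    def test_zero_projection_defined_as_zero(self):
        assert cosine_content_of(np.zeros(100), 1) == 0.0

    def test_random_walk_flagged_unconverged(self):
        traj = tt.random_walk_trajectory(5, 300, 1.0, seed=44)
        model = tt.covariance_pca(traj)
        report = tt.convergence_report(model, traj)
        assert report.cosine_contents[0] >= 0.5
        assert not report.converged

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(-100, 100), min_size=5, max_size=200), st.integers(1, 3))
    def test_bounded_for_arbitrary_projections(self, values, component):
        c = cosine_content_of(np.asarray(values), component)
        assert 0.0 <= c <= 1.0


class TestGaussianMi:
    def test_independent_near_zero(self):
        rng = np.random.default_rng(3)
        X, Y = rng.normal(0, 1, (6000, 3)), rng.normal(0, 1, (6000, 3))
        mi = tt.gaussian_mi(X, Y)
        assert tt.generalized_correlation(mi) < 0.05

    def test_identical_capped_near_one(self):
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (500, 3))
        mi = tt.gaussian_mi(X, X)
        r = tt.generalized_correlation(mi)
        assert np.isfinite(mi) and 0.999 < r <= 1.0

    def test_closed_form_isotropic(self):
        rho = 0.6
        cov = tt.isotropic_correlation_cov(np.array([[1, rho], [rho, 1]]))
        ens = tt.sample_correlated_ensemble(tt.EnsembleRecipe(2, 5000, seed=42, covariance=cov))
        mi = tt.gaussian_mi(ens.coords[:, 0, :], ens.coords[:, 1, :])
        assert mi == pytest.approx(-1.5 * np.log(1 - rho**2), abs=0.05)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            tt.gaussian_mi(np.zeros((4, 3)), np.zeros((4, 3)))


class TestGeneralizedCorrelation:
    def test_zero_mi_zero_r(self):
        assert tt.generalized_correlation(0.0) == 0.0

    def test_negative_mi_clamped(self):
        assert tt.generalized_correlation(-0.01) == 0.0

    def test_monotone_increasing(self):
        mis = np.linspace(0, 5, 40)
        rs = [tt.generalized_correlation(m) for m in mis]
        assert all(b >= a for a, b in zip(rs, rs[1:]))
        assert all(0 <= r <= 1 for r in rs)

    def test_anticorrelated_collinear_is_one(self):
        rng = np.random.default_rng(5)
        X = np.zeros((2000, 3))
        X[:, 0] = rng.normal(0, 1, 2000)
        r = tt.generalized_correlation(tt.gaussian_mi(X, -X))
        assert r > 0.999


class TestCorrelationMatrix:
    def test_two_atom_symmetric(self):
        cov = tt.isotropic_correlation_cov(np.array([[1, 0.5], [0.5, 1]]))
        ens = tt.sample_correlated_ensemble(tt.EnsembleRecipe(2, 800, seed=7, covariance=cov))
        m = tt.correlation_matrix(ens, None)
        assert m.values[0, 1] == m.values[1, 0]
        np.testing.assert_allclose(np.diag(m.values), 1.0)

    def test_block_design_recovery(self):
        rho = tt.block_correlation_matrix(6, [[0, 1, 2]], rho_within=0.8)
        ens = tt.sample_correlated_ensemble(
            tt.EnsembleRecipe(6, 5000, seed=9, covariance=tt.isotropic_correlation_cov(rho))
        )
        m = tt.correlation_matrix(ens, None)
        np.testing.assert_allclose(m.values[np.triu_indices(6, 1)],
                                   rho[np.triu_indices(6, 1)], atol=0.05)

    def test_frame_permutation_invariance(self):
        cov = tt.isotropic_correlation_cov(np.array([[1, 0.4], [0.4, 1]]))
        ens = tt.sample_correlated_ensemble(tt.EnsembleRecipe(2, 600, seed=10, covariance=cov))
        m1 = tt.correlation_matrix(ens, None)
        rng = np.random.default_rng(0)
        shuffled = tt.Trajectory(ens.topology, ens.coords[rng.permutation(600)])
        m2 = tt.correlation_matrix(shuffled, None)
        np.testing.assert_allclose(m1.values, m2.values, atol=1e-10)

    def test_rigid_body_removed_leaves_no_correlation(self):
        # rigid tumbling plus independent jitter: after superposition the
        # residual motions should be essentially uncorrelated (the fit
        # itself induces only weak couplings once atoms outnumber the
        # rigid degrees of freedom)
        n_atoms = 20
        rng = np.random.default_rng(11)
        base = rng.normal(0, 5, (n_atoms, 3))
        coords = []
        for _ in range(800):
            R, t = random_rigid_motion(rng)
            coords.append(base @ R.T + t + rng.normal(0, 0.1, base.shape))
        traj = tt.Trajectory(pseudo_ca_topology(n_atoms), np.stack(coords))
        fitted = np.stack(
            [tt.superpose(traj.coords[f], base, np.arange(n_atoms)).apply(traj.coords[f])
             for f in range(traj.n_frames)]
        )
        m = tt.correlation_matrix(tt.Trajectory(traj.topology, fitted), None)
        off = m.values[np.triu_indices(n_atoms, 1)]
        assert np.max(off) < 0.3


class TestBuildNetwork:
    @staticmethod
    def _matrix(values, kinds):
        n = values.shape[0]
        return tt.GeneralizedCorrelationMatrix(
            values, np.arange(n), list(kinds),
            ["P" if k == "protein" else "D" for k in kinds], list(range(1, n + 1)),
        )

    def test_hand_counted_edges(self):
        v = np.eye(4)
        pairs = {(0, 2): 0.75, (0, 3): 0.9, (1, 2): 0.71, (1, 3): 0.3, (0, 1): 0.95}
        for (i, j), r in pairs.items():
            v[i, j] = v[j, i] = r
        m = self._matrix(v, ["protein", "protein", "dna", "dna"])
        _, counts = tt.build_network(m, threshold=0.7)
        assert counts.protein_dna == 3
        assert counts.n_edges == 4

    def test_threshold_one_keeps_exact_ones_only(self):
        v = np.eye(3)
        v[0, 1] = v[1, 0] = 1.0
        v[0, 2] = v[2, 0] = 0.999999
        m = self._matrix(v, ["protein"] * 3)
        _, counts = tt.build_network(m, threshold=1.0)
        assert counts.n_edges == 1

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(12)
        raw = rng.uniform(0, 1, (8, 8))
        v = np.clip((raw + raw.T) / 2, 0, 1)
        np.fill_diagonal(v, 1.0)
        m = self._matrix(v, ["protein"] * 8)
        counts = [tt.build_network(m, th)[1].n_edges for th in np.linspace(0.1, 1.0, 10)]
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_planted_domain_pairs_recovered(self):
        # 4 linker nodes x 3 intercalating nodes correlated pairwise
        n = 10
        kinds = ["protein"] * 7 + ["dna"] * 3
        v = np.eye(n)
        linker, inter = {0, 1, 2, 3}, {4, 5, 6}
        planted = 0
        for i in linker:
            for j in inter:
                v[i, j] = v[j, i] = 0.9
                planted += 1
        m = self._matrix(v, kinds)
        _, counts = tt.build_network(
            m, threshold=0.7, domains={"linker": linker, "intercalating": inter}
        )
        assert counts.domain_pairs[("intercalating", "linker")] == planted == 12
        assert counts.domain_pairs[("linker", "linker")] == 0
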