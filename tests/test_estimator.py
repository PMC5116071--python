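"""Moment-matching estimator: closed form, invariances, sampling variance."""

import numpy as np
import pytest
from scipy.stats import ortho_group

from multiherit.estimator import (
    CovariateMatrix,
    HeritabilityHE,
    ProjectedData,
    TraitMatrix,
    fit_moment_matching,
    project_out_covariates,
    sampling_variance,
    trait_reliability,
)
from multiherit.synthetic import SimulationSpec, simulate_traits


def brute_force_he(y, K):
    """Scalar Haseman-Elston oracle: OLS of pairwise products on (K_ij, delta_ij)."""
    n = len(y)
    prods = np.outer(y, y).ravel()
    A = np.column_stack([K.ravel(), np.eye(n).ravel()])
    (sa, se), *_ = np.linalg.lstsq(A, prods, rcond=None)
    return sa / (sa + se), sa, se


# hand-enumerable N=6, M=2 fixture: block-structured K, integer traits
K6 = np.array([
    [1.0, 0.5, 0.0, 0.0, 0.0, 0.0],
    [0.5, 1.0, 0.0, 0.0, 0.0, 0.0],
    [0.0, 0.0, 1.0, 0.25, 0.0, 0.0],
    [0.0, 0.0, 0.25, 1.0, 0.0, 0.0],
    [0.0, 0.0, 0.0, 0.0, 1.0, 0.0],
    [0.0, 0.0, 0.0, 0.0, 0.0, 1.0],
])
Y6 = np.array([[1.0, 2.0], [2.0, 1.0], [0.0, 1.0], [1.0, 0.0],
               [-1.0, 1.0], [-2.0, -1.0]])


class TestMomentMatching:
    def test_hand_computed_fixture(self):
        """v_K = 0.625, Sigma_A = [[3.2,4.4],[4.4,3.2]], Sigma_E has -41/30 etc."""
        D = fit_moment_matching(ProjectedData(Y=Y6, K=K6, dof=6))
        assert D.v_K == pytest.approx(0.625)
        assert D.k_bar == pytest.approx(1.0)
        assert D.kappa == pytest.approx(53 / 48)
        np.testing.assert_allclose(D.Sigma_A, [[3.2, 4.4], [4.4, 3.2]], atol=1e-12)
        np.testing.assert_allclose(
            D.Sigma_E,
            [[-41 / 30, -107 / 30], [-107 / 30, -56 / 30]], atol=1e-12,
        )
        assert D.h2_raw == pytest.approx(6.4 / (6.4 - 97 / 30))
        assert D.h2 == 1.0  # clamped for reporting

    @pytest.mark.parametrize("seed", range(5))
    def test_scalar_degenerates_to_brute_force(self, small_panel, seed):
        g, K = small_panel
        spec = SimulationSpec(n_samples=200, n_traits=1, seed=seed)
        Y = simulate_traits(K, spec)
        D = fit_moment_matching(ProjectedData(Y=Y.Y, K=K.K, dof=200))
        h2_oracle, sa, se = brute_force_he(Y.Y[:, 0], K.K)
        assert D.h2_raw == pytest.approx(h2_oracle, abs=1e-8)
        assert D.Sigma_A[0, 0] == pytest.approx(sa, abs=1e-8)
        assert D.Sigma_E[0, 0] == pytest.approx(se, abs=1e-8)

    def test_rotation_invariance(self, small_panel, rng):
        _, K = small_panel
        spec = SimulationSpec(n_samples=200, n_traits=4, seed=9)
        Y = simulate_traits(K, spec)
        base = fit_moment_matching(ProjectedData(Y=Y.Y, K=K.K, dof=200)).h2_raw
        for _ in range(10):
            T = ortho_group.rvs(4, random_state=rng)
            rot = fit_moment_matching(ProjectedData(Y=Y.Y @ T, K=K.K, dof=200)).h2_raw
            assert abs(rot - base) < 1e-10

    def test_weighted_average_identity(self, small_panel):
        """Multivariate h2 = sum_m gamma_m h2_m, gamma from per-trait variances."""
        _, K = small_panel
        spec = SimulationSpec(n_samples=200, n_traits=3, seed=21)
        Y = simulate_traits(K, spec)
        D = fit_moment_matching(ProjectedData(Y=Y.Y, K=K.K, dof=200))
        h2_m, var_m = [], []
        for m in range(3):
            Dm = fit_moment_matching(ProjectedData(Y=Y.Y[:, m:m + 1], K=K.K, dof=200))
            h2_m.append(Dm.h2_raw)
            var_m.append(Dm.t_P)
        gamma = np.array(var_m) / np.sum(var_m)
        assert D.h2_raw == pytest.approx(float(gamma @ h2_m), abs=1e-8)

    def test_unbiased_covariance_recovery(self, small_panel, rng):
        _, K = small_panel
        SA = np.array([[0.5, 0.2], [0.2, 0.4]])
        SE = np.array([[0.5, -0.1], [-0.1, 0.6]])
        spec = SimulationSpec(n_samples=200, n_traits=2, Sigma_A=SA, Sigma_E=SE, seed=0)
        acc_A = np.zeros((2, 2))
        acc_E = np.zeros((2, 2))
        n_rep = 500
        for _ in range(n_rep):
            Y = simulate_traits(K, spec, rng=rng)
            D = fit_moment_matching(ProjectedData(Y=Y.Y, K=K.K, dof=200))
            acc_A += D.Sigma_A
            acc_E += D.Sigma_E
        np.testing.assert_allclose(acc_A / n_rep, SA, atol=0.1)
        np.testing.assert_allclose(acc_E / n_rep, SE, atol=0.1)

    def test_no_contrast_raises(self):
        with pytest.raises(ValueError, match="v_K"):
            fit_moment_matching(ProjectedData(Y=np.ones((5, 1)), K=np.eye(5), dof=5))


class TestSamplingVariance:
    def test_perfectly_correlated_equals_scalar(self, small_panel):
        _, K = small_panel
        rng = np.random.default_rng(4)
        y = rng.standard_normal(200)
        Y_multi = np.column_stack([y, 2 * y, -0.5 * y])  # rank-1 phenotypic cov
        P1 = ProjectedData(Y=y[:, None], K=K.K, dof=200)
        Pm = ProjectedData(Y=Y_multi, K=K.K, dof=200)
        se1 = sampling_variance(P1, fit_moment_matching(P1))
        sem = sampling_variance(Pm, fit_moment_matching(Pm))
        assert sem == pytest.approx(se1, rel=1e-10)

    def test_independent_traits_reduce_variance_fivefold(self, small_panel):
        """For M=5 uncorrelated equal-variance traits, var is exactly 1/5 of
        the scalar variance under the eigenvalue form of the approximation."""
        _, K = small_panel
        P = ProjectedData(Y=np.zeros((200, 1)), K=K.K, dof=200)
        base = fit_moment_matching(
            ProjectedData(Y=np.random.default_rng(0).standard_normal((200, 1)),
                          K=K.K, dof=200)
        )
        # construct decompositions with prescribed phenotypic covariance
        base.Sigma_A = np.zeros((1, 1))
        base.Sigma_E = np.eye(1)
        base.t_P = 1.0
        var_scalar = sampling_variance(P, base) ** 2
        base.Sigma_A = np.zeros((5, 5))
        base.Sigma_E = np.eye(5)
        base.t_P = 5.0
        var_multi = sampling_variance(P, base) ** 2
        assert var_multi == pytest.approx(var_scalar / 5, rel=1e-12)

    def test_matches_monte_carlo_sd(self, small_panel, rng):
        _, K = small_panel
        spec = SimulationSpec(n_samples=200, n_traits=3, Sigma_A=0.4, Sigma_E=0.6,
                              seed=0)
        h2s, ses = [], []
        for _ in range(300):
            Y = simulate_traits(K, spec, rng=rng)
            P = ProjectedData(Y=Y.Y, K=K.K, dof=200)
            D = fit_moment_matching(P)
            h2s.append(D.h2_raw)
            ses.append(sampling_variance(P, D))
        assert np.std(h2s) == pytest.approx(np.mean(ses), rel=0.25)

    def test_depends_only_on_phenotypic_structure(self, small_panel):
        """Same phenotypic covariance, different h2 point estimates -> same se."""
        _, K = small_panel
        rng = np.random.default_rng(8)
        P = ProjectedData(Y=rng.standard_normal((200, 2)), K=K.K, dof=200)
        D = fit_moment_matching(P)
        se1 = sampling_variance(P, D)
        D.t_A, D.t_E = 0.9 * D.t_P, 0.1 * D.t_P  # changing the split is a no-op
        assert sampling_variance(P, D) == se1


class TestCovariateProjection:
    def _data(self, small_panel, m=2, q=3, seed=5):
        _, K = small_panel
        rng = np.random.default_rng(seed)
        X = np.column_stack([np.ones(200), rng.standard_normal((200, q - 1))])
        Y = rng.standard_normal((200, m)) + X @ rng.standard_normal((q, m))
        return Y, K.K, X

    def test_no_covariates_is_identity(self, small_panel):
        Y, K, _ = self._data(small_panel)
        P = project_out_covariates(Y, K, None)
        np.testing.assert_array_equal(P.Y, Y)
        assert P.dof == 200

    def test_intercept_only_centers(self, small_panel):
        Y, K, _ = self._data(small_panel)
        P = project_out_covariates(Y, K, np.ones((200, 1)))
        assert P.dof == 199
        # squared norms preserved under the (N-1)-basis of centered data
        Yc = Y - Y.mean(axis=0)
        np.testing.assert_allclose(P.Y.T @ P.Y, Yc.T @ Yc, atol=1e-8)
        P0 = np.eye(200) - np.ones((200, 200)) / 200
        assert np.trace(P.K) == pytest.approx(np.trace(P0 @ K @ P0))

    def test_invariant_to_basis_choice(self, small_panel):
        """Any orthonormal null-space basis gives the same h2 (to 1e-10)."""
        Y, K, X = self._data(small_panel)
        P1 = project_out_covariates(Y, K, X)
        rng = np.random.default_rng(1)
        Q = ortho_group.rvs(P1.dof, random_state=rng)  # U2 = U1 Q is another basis
        P2 = ProjectedData(Y=Q.T @ P1.Y, K=Q.T @ P1.K @ Q, dof=P1.dof)
        h1 = fit_moment_matching(P1).h2_raw
        h2 = fit_moment_matching(P2).h2_raw
        assert abs(h1 - h2) < 1e-10

    def test_invariant_to_x_span_noise(self, small_panel):
        Y, K, X = self._data(small_panel)
        h_ref = fit_moment_matching(project_out_covariates(Y, K, X)).h2_raw
        rng = np.random.default_rng(2)
        Y_noisy = Y + X @ rng.standard_normal((X.shape[1], Y.shape[1])) * 10
        h_noisy = fit_moment_matching(project_out_covariates(Y_noisy, K, X)).h2_raw
        assert abs(h_ref - h_noisy) < 1e-8

    def test_rank_deficient_names_columns(self, small_panel):
        Y, K, X = self._data(small_panel)
        Xbad = np.column_stack([X, X[:, 1]])
        with pytest.raises(ValueError, match="collinear"):
            project_out_covariates(Y, K, CovariateMatrix(Xbad))


class TestTraitReliability:
    def test_identical_vectors(self):
        assert trait_reliability([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_perfect_reversal(self):
        x = np.array([-1.0, 0.0, 1.0])
        assert trait_reliability(x, -x) == pytest.approx(-1.0)

    def test_arithmetic_oracle(self):
        assert trait_reliability([1, 2, 3, 4], [1.1, 2.1, 2.9, 4.2]) == pytest.approx(
            0.9931170108161257
        )

    def test_constant_vectors_raise(self):
        with pytest.raises(ValueError, match="variance"):
            trait_reliability([1, 1, 1], [1, 1, 1])


class TestHeritabilityHEClass:
    def test_sklearn_params_round_trip(self):
        est = HeritabilityHE(n_permutations=10, random_state=3)
        est2 = HeritabilityHE(**est.get_params())
        assert est2.get_params() == est.get_params()

    def test_fit_attributes(self, small_panel):
        _, K = small_panel
        spec = SimulationSpec(n_samples=200, n_traits=2, seed=1)
        Y = simulate_traits(K, spec)
        est = HeritabilityHE(n_permutations=49, random_state=0).fit(Y, K)
        assert 0 <= est.h2_ <= 1
        assert est.se_ > 0
        assert 0 < est.p_wald_ <= 1
        assert est.p_perm_ >= 1 / 50
        assert est.sigma_a_.shape == (2, 2)
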