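import numpy as np
import pytest

from plrnnssm.data import TrajectoryData
from plrnnssm.estep import (assemble_quadratic, compute_posterior,
                            posterior_covariance, relu_moments, solve_map)
from plrnnssm.model import PLRNNParams, generate
from plrnnssm.observation import ObsParamsBOLD, ObsParamsGaussian

from conftest import random_gaussian_obs, random_plrnn
from oracles import kalman_smoother


def make_lds_problem(M, N, T, seed):
    p = random_plrnn(M, seed=seed, linear=True)
    obs = random_gaussian_obs(N, M, seed=seed, linear=True)
    F = np.diag(p.A) + p.W
    r = np.random.default_rng(seed + 77)
    Z = np.zeros((T, M))
    Z[0] = p.mu0 + np.sqrt(p.Sigma) * r.standard_normal(M)
    for t in range(1, T):
        Z[t] = F @ Z[t - 1] + p.h + np.sqrt(p.Sigma) * r.standard_normal(M)
    X = Z @ obs.B.T + np.sqrt(obs.Gamma) * r.standard_normal((T, N))
    return p, obs, TrajectoryData(X=X), F


def dense_neg_hessian(qf, d):
    T, M = qf.T, qf.M
    P = np.zeros((T * M, T * M))
    for lag, arr in qf.neg_hessian_blocks(d).items():
        for t in range(arr.shape[0]):
            P[t * M:(t + 1) * M, (t + lag) * M:(t + lag + 1) * M] += arr[t]
            if lag > 0:
                P[(t + lag) * M:(t + lag + 1) * M, t * M:(t + 1) * M] += arr[t].T
    return P


class TestAssemble:
    def test_finite_difference_hessian_scalar(self):
        # M=1, T=2: hand-checkable 2x2 Hessian vs second differences
        p = PLRNNParams(mu0=np.array([0.3]), A=np.array([0.6]),
                        W=np.array([[0.0]]), C=np.zeros((1, 0)),
                        h=np.array([0.2]), Sigma=np.array([0.5]))
        obs = ObsParamsGaussian(B=np.array([[1.2]]), Gamma=np.array([0.7]))
        data = TrajectoryData(X=np.array([[0.5], [1.0]]))
        qf = assemble_quadratic(p, obs, data)
        d = np.ones((2, 1), dtype=bool)

        def obj(z):
            Z = z.reshape(2, 1)
            phi = Z * d
            v = -0.5 * (Z[0, 0] - 0.3) ** 2 / 0.5
            v += -0.5 * (Z[1, 0] - 0.6 * Z[0, 0] - 0.2) ** 2 / 0.5
            v += -0.5 * np.sum((data.X.ravel() - 1.2 * phi.ravel()) ** 2) / 0.7
            return v

        eps = 1e-5
        H = np.zeros((2, 2))
        for i in range(2):
            for j in range(2):
                zpp = np.zeros(2); zpp[i] += eps; zpp[j] += eps
                zpm = np.zeros(2); zpm[i] += eps; zpm[j] -= eps
                zmp = np.zeros(2); zmp[i] -= eps; zmp[j] += eps
                zmm = np.zeros(2); zmm[i] -= eps; zmm[j] -= eps
                H[i, j] = (obj(zpp) - obj(zpm) - obj(zmp) + obj(zmm)) / (4 * eps * eps)
        np.testing.assert_allclose(dense_neg_hessian(qf, d), -H, atol=1e-5)

    def test_quadratic_reproduces_objective(self):
        # -1/2 z^T P z + z^T v (+ const) equals direct evaluation for fixed d
        p = random_plrnn(3, seed=2)
        obs = random_gaussian_obs(2, 3, seed=2)
        data = TrajectoryData(X=np.random.default_rng(3).normal(size=(8, 2)))
        qf = assemble_quadratic(p, obs, data)
        r = np.random.default_rng(4)
        for _ in range(5):
            z = r.normal(size=(8, 3))
            d = z > 0
            P = dense_neg_hessian(qf, d)
            v = qf.linear_term(d).ravel()
            quad = -0.5 * z.ravel() @ P @ z.ravel() + z.ravel() @ v
            const = quad - qf.objective(z)
            # const must not depend on z within the region; check via 2nd point
            z2 = np.where(d, np.abs(r.normal(size=z.shape)),
                          -np.abs(r.normal(size=z.shape)))
            quad2 = -0.5 * z2.ravel() @ P @ z2.ravel() + z2.ravel() @ v
            assert quad2 - qf.objective(z2) == pytest.approx(const, abs=1e-8)

    def test_singular_sigma_rejected(self):
        p = random_plrnn(2, seed=1)
        obs = random_gaussian_obs(2, 2, seed=1)
        data = TrajectoryData(X=np.zeros((4, 2)))
        p.Sigma = np.array([1.0, 0.0])
        with pytest.raises(ValueError):
            assemble_quadratic(p, obs, data)

    def test_prior_only_limit(self):
        # B = 0: maximizer is the deterministic latent path from mu0
        p = random_plrnn(2, seed=5, coupling=0.2)
        obs = ObsParamsGaussian(B=np.zeros((2, 2)), Gamma=np.ones(2))
        data = TrajectoryData(X=np.zeros((10, 2)))
        qf = assemble_quadratic(p, obs, data)
        z, d, _, conv = solve_map(qf)
        path, _ = generate(p, 10, z1=p.mu0, noise=False)
        np.testing.assert_allclose(z, path, atol=1e-8)


class TestSolveMap:
    @pytest.mark.parametrize("seed", range(4))
    def test_linear_limit_equals_kalman(self, seed):
        M, N, T = 3, 2, 40
        p, obs, data, F = make_lds_problem(M, N, T, seed)
        qf = assemble_quadratic(p, obs, data)
        z, d, _, conv = solve_map(qf)
        bias = np.tile(p.h, (T, 1))
        bias[0] = p.mu0
        mu_s, V_s, lag1, _ = kalman_smoother(
            F, bias, np.diag(p.Sigma), obs.B, np.zeros((T, N)),
            np.diag(obs.Gamma), p.mu0, np.diag(p.Sigma), data.X)
        assert np.abs(z - mu_s).max() < 1e-6

    def test_uninformative_observations(self):
        p = random_plrnn(2, seed=9, coupling=0.2)
        obs = ObsParamsGaussian(B=np.random.default_rng(1).normal(size=(2, 2)),
                                Gamma=1e12 * np.ones(2))
        data = TrajectoryData(X=np.random.default_rng(2).normal(size=(12, 2)))
        qf = assemble_quadratic(p, obs, data)
        z, *_ = solve_map(qf)
        path, _ = generate(p, 12, z1=p.mu0, noise=False)
        np.testing.assert_allclose(z, path, atol=1e-4)

    def test_consistent_solution(self):
        p = random_plrnn(3, seed=3)
        obs = random_gaussian_obs(2, 3, seed=3)
        data = TrajectoryData(X=np.random.default_rng(5).normal(size=(20, 2)))
        qf = assemble_quadratic(p, obs, data)
        z, d, rounds, conv = solve_map(qf)
        if conv:
            np.testing.assert_array_equal(z > 0, d)
        assert rounds <= 100

    def test_optimizer_oracle_small(self):
        # reduced version of the acceptance property (full 100 in acceptance)
        from scipy.optimize import minimize
        for seed in range(10):
            r = np.random.default_rng(seed)
            p = random_plrnn(2, seed=seed, coupling=1.0)
            obs = random_gaussian_obs(2, 2, seed=seed)
            data = TrajectoryData(X=r.normal(0, 1.5, (5, 2)))
            qf = assemble_quadratic(p, obs, data)
            z, *_ = solve_map(qf, n_starts=8, polish=True)
            best = -np.inf
            for k in range(10):
                z0 = np.random.default_rng(100 + k).normal(0, 2, 10)
                res = minimize(lambda zz: -qf.objective(zz.reshape(5, 2)), z0,
                               method="L-BFGS-B")
                best = max(best, -res.fun)
            assert qf.objective(z) >= best - 1e-6


class TestPosteriorCovariance:
    def test_scalar_case(self):
        # T=1, M=1: V = 1 / (precision sum)
        p = PLRNNParams(mu0=np.zeros(1), A=np.array([0.5]),
                        W=np.array([[0.0]]), C=np.zeros((1, 0)),
                        h=np.zeros(1), Sigma=np.array([0.5]))
        obs = ObsParamsGaussian(B=np.array([[2.0]]), Gamma=np.array([0.25]))
        data = TrajectoryData(X=np.array([[1.0]]))
        qf = assemble_quadratic(p, obs, data)
        d = np.ones((1, 1), dtype=bool)
        cov, _ = posterior_covariance(qf, d)
        expect = 1.0 / (1 / 0.5 + 4.0 / 0.25)
        assert cov[0][0, 0, 0] == pytest.approx(expect, abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_linear_limit_kalman_covariances(self, seed):
        M, N, T = 3, 2, 30
        p, obs, data, F = make_lds_problem(M, N, T, seed + 20)
        qf = assemble_quadratic(p, obs, data)
        z, d, *_ = solve_map(qf)
        cov, _ = posterior_covariance(qf, d)
        bias = np.tile(p.h, (T, 1))
        bias[0] = p.mu0
        _, V_s, lag1, _ = kalman_smoother(
            F, bias, np.diag(p.Sigma), obs.B, np.zeros((T, N)),
            np.diag(obs.Gamma), p.mu0, np.diag(p.Sigma), data.X)
        assert np.abs(cov[0] - V_s).max() < 1e-6
        assert np.abs(cov[1] - lag1).max() < 1e-6

    def test_dense_inverse_agreement_nonlinear(self):
        p = random_plrnn(3, seed=8)
        obs = random_gaussian_obs(2, 3, seed=8)
        data = TrajectoryData(X=np.random.default_rng(9).normal(size=(12, 2)))
        qf = assemble_quadratic(p, obs, data)
        d = np.random.default_rng(10).random((12, 3)) > 0.5
        cov, logdet = posterior_covariance(qf, d)
        P = dense_neg_hessian(qf, d)
        V = np.linalg.inv(P)
        M = 3
        for t in range(12):
            np.testing.assert_allclose(
                cov[0][t], V[t * M:(t + 1) * M, t * M:(t + 1) * M], atol=1e-10)
        assert logdet == pytest.approx(np.linalg.slogdet(P)[1], abs=1e-8)

    def test_bold_banded_covariance(self):
        p = random_plrnn(2, seed=11)
        kern = np.array([1.0, 0.5, 0.25])
        obs = ObsParamsBOLD(B=np.random.default_rng(1).normal(size=(2, 2)),
                            J=np.zeros((2, 0)), Gamma=np.ones(2), hrf=kern)
        data = TrajectoryData(X=np.random.default_rng(2).normal(size=(10, 2)))
        qf = assemble_quadratic(p, obs, data)
        d = np.random.default_rng(3).random((10, 2)) > 0.5
        cov, _ = posterior_covariance(qf, d)
        V = np.linalg.inv(dense_neg_hessian(qf, d))
        M = 2
        for lag in cov:
            for t in range(10 - lag):
                np.testing.assert_allclose(
                    cov[lag][t],
                    V[t * M:(t + 1) * M, (t + lag) * M:(t + lag + 1) * M],
                    atol=1e-10)

    def test_more_observations_never_increase_variance(self):
        M, N, T = 2, 2, 15
        p, obs, data, F = make_lds_problem(M, N, T, 31)
        qf1 = assemble_quadratic(p, obs, data)
        z, d, *_ = solve_map(qf1)
        cov1, _ = posterior_covariance(qf1, d)
        obs2 = ObsParamsGaussian(B=obs.B, Gamma=obs.Gamma / 10, linear=True)
        qf2 = assemble_quadratic(p, obs2, data)
        cov2, _ = posterior_covariance(qf2, d)
        v1 = np.einsum("tii->ti", cov1[0])
        v2 = np.einsum("tii->ti", cov2[0])
        assert np.all(v2 <= v1 + 1e-12)


class TestReluMoments:
    def test_standard_value(self):
        e, _, _ = relu_moments(0.0, 1.0)
        assert e == pytest.approx(1 / np.sqrt(2 * np.pi), abs=1e-10)

    def test_deterministic_limit(self):
        e, ez, e2 = relu_moments(5.0, 1e-6)
        assert e == pytest.approx(5.0, abs=1e-5)
        assert e2 == pytest.approx(25.0, rel=1e-5)

    def test_invalid_variance(self):
        with pytest.raises(ValueError):
            relu_moments(0.0, 0.0)


class TestExpectedLoglik:
    def test_point_mass_equals_objective(self):
        from plrnnssm.estep import LatentPosterior, expected_joint_loglik
        p = random_plrnn(2, seed=12)
        obs = random_gaussian_obs(2, 2, seed=12)
        data = TrajectoryData(X=np.random.default_rng(13).normal(size=(6, 2)))
        qf = assemble_quadratic(p, obs, data)
        z, d, *_ = solve_map(qf)
        T, M = 6, 2
        eps = 1e-14
        cov = {0: np.tile(eps * np.eye(M), (T, 1, 1)),
               1: np.zeros((T - 1, M, M))}
        phi = np.maximum(z, 0)
        post = LatentPosterior(
            z_map=z, d_omega=d, cov=cov, Ephi=phi,
            Ezphi=np.einsum("ti,tj->tij", z, phi),
            Ephiphi=np.einsum("ti,tj->tij", phi, phi),
            Czphi=np.einsum("ti,tj->tij", z[1:], phi[:-1]))
        ll = expected_joint_loglik(p, obs, post, data)
        consts = (-0.5 * T * np.sum(np.log(2 * np.pi * p.Sigma))
                  - 0.5 * T * np.sum(np.log(2 * np.pi * obs.Gamma)))
        assert ll == pytest.approx(qf.objective(z) + consts, abs=1e-6)

    def test_linear_em_monotone(self):
        from plrnnssm.training import TrainingConfig, _em_round
        p, obs, data, _ = make_lds_problem(3, 2, 25, 41)
        cfg = TrainingConfig(M=3, em_max_iter=15, em_tol=1e-12)
        *_, trace = _em_round(data, p, obs, cfg, sigma_fixed=p.Sigma,
                              update_b=True, update_gamma=True, z_warm=None)
        diffs = np.diff(trace)
        assert np.all(diffs > -1e-6 * np.maximum(np.abs(trace[:-1]), 1.0))
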