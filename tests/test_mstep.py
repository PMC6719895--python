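import numpy as np
import pytest

from plrnnssm.data import TrajectoryData
from plrnnssm.estep import (LatentPosterior, assemble_quadratic,
                            compute_posterior)
from plrnnssm.model import PLRNNParams, generate
from plrnnssm.mstep import (accumulate_stats, update_latent_params,
                            update_obs_params)
from plrnnssm.observation import ObsParamsBOLD, ObsParamsGaussian, emit

from conftest import random_gaussian_obs, random_plrnn
from oracles import kalman_smoother, lds_em_update


def point_mass_posterior(Z):
    T, M = Z.shape
    phi = np.maximum(Z, 0.0)
    cov = {0: np.zeros((T, M, M)), 1: np.zeros((T - 1, M, M))}
    return LatentPosterior(
        z_map=Z, d_omega=Z > 0, cov=cov, Ephi=phi,
        Ezphi=np.einsum("ti,tj->tij", Z, phi),
        Ephiphi=np.einsum("ti,tj->tij", phi, phi),
        Czphi=np.einsum("ti,tj->tij", Z[1:], phi[:-1]))


class TestObsUpdate:
    def test_noise_free_recovery(self):
        r = np.random.default_rng(0)
        M, N, P, T = 3, 4, 2, 200
        Z = r.normal(size=(T, M))
        Btrue = r.normal(size=(N, M))
        Jtrue = r.normal(size=(N, P))
        R = r.normal(size=(T, P))
        X = Z @ Btrue.T + R @ Jtrue.T    # delta kernel, raw-z convolution
        obs = ObsParamsBOLD(B=Btrue, J=Jtrue, Gamma=np.ones(N), hrf=np.ones(1))
        data = TrajectoryData(X=X, R=R)
        p = random_plrnn(M, seed=1)
        stats = accumulate_stats(point_mass_posterior(Z), data, p, obs)
        B, J, Gamma = update_obs_params(stats)
        np.testing.assert_allclose(B, Btrue, atol=1e-8)
        np.testing.assert_allclose(J, Jtrue, atol=1e-8)
        assert np.all(Gamma <= 1e-7)

    def test_no_nuisance_collapse(self):
        r = np.random.default_rng(1)
        M, N, T = 2, 3, 50
        Z = r.normal(size=(T, M))
        obs = ObsParamsBOLD(B=r.normal(size=(N, M)), J=np.zeros((N, 0)),
                            Gamma=np.ones(N), hrf=np.ones(1))
        data = TrajectoryData(X=r.normal(size=(T, N)))
        stats = accumulate_stats(point_mass_posterior(Z), data,
                                 random_plrnn(M, seed=2), obs)
        B, J, _ = update_obs_params(stats)
        np.testing.assert_allclose(B, stats.H1 @ np.linalg.inv(stats.H3),
                                   atol=1e-10)
        assert J.shape == (N, 0)

    def test_generic_least_squares_oracle(self):
        # matches a direct normal-equations solve on the expected design
        r = np.random.default_rng(3)
        M, N, P, T = 2, 3, 2, 40
        Z = r.normal(size=(T, M))
        R = r.normal(size=(T, P))
        X = r.normal(size=(T, N))
        obs = ObsParamsBOLD(B=r.normal(size=(N, M)), J=r.normal(size=(N, P)),
                            Gamma=np.ones(N), hrf=np.ones(1))
        stats = accumulate_stats(point_mass_posterior(Z),
                                 TrajectoryData(X=X, R=R),
                                 random_plrnn(M, seed=4), obs)
        B, J, _ = update_obs_params(stats)
        design = np.hstack([Z, R])
        Y_ref, *_ = np.linalg.lstsq(design, X, rcond=None)
        np.testing.assert_allclose(np.hstack([B, J]), Y_ref.T, atol=1e-8)


class TestLatentUpdate:
    def test_near_noiseless_recovery(self):
        # tiny process noise + point-mass posterior: near-exact recovery
        from conftest import limit_cycle_teacher
        teacher = limit_cycle_teacher(sigma=1e-8)
        Z, un = generate(teacher, 3000, seed=5, noise=True)
        assert not un
        obs = ObsParamsGaussian(B=np.eye(3), Gamma=np.ones(3))
        data = TrajectoryData(X=np.maximum(Z, 0.0))
        stats = accumulate_stats(point_mass_posterior(Z), data, teacher, obs)
        rec = update_latent_params(stats, lambda_reg=0.0, update_sigma=True)
        np.testing.assert_allclose(rec.A, teacher.A, atol=1e-3)
        np.testing.assert_allclose(rec.W, teacher.W, atol=1e-3)
        np.testing.assert_allclose(rec.h, teacher.h, atol=1e-3)
        assert np.all(np.diag(rec.W) == 0.0)

    def test_statistical_recovery_with_noise(self):
        from conftest import limit_cycle_teacher
        teacher = limit_cycle_teacher(sigma=1e-3)
        Z, _ = generate(teacher, 5000, seed=6, noise=True)
        obs = ObsParamsGaussian(B=np.eye(3), Gamma=np.ones(3))
        data = TrajectoryData(X=np.maximum(Z, 0.0))
        stats = accumulate_stats(point_mass_posterior(Z), data, teacher, obs)
        rec = update_latent_params(stats, update_sigma=True)
        assert np.abs(rec.A - teacher.A).max() < 0.05
        assert np.abs(rec.W - teacher.W).max() < 0.05
        np.testing.assert_allclose(rec.Sigma, teacher.Sigma, rtol=0.2)

    def test_ridge_shrinks_monotonically(self):
        r = np.random.default_rng(7)
        Z = r.normal(size=(100, 3))
        obs = ObsParamsGaussian(B=np.eye(3), Gamma=np.ones(3))
        data = TrajectoryData(X=r.normal(size=(100, 3)))
        stats = accumulate_stats(point_mass_posterior(Z), data,
                                 random_plrnn(3, seed=8), obs)
        prev = np.inf
        for lam in (0.0, 1.0, 10.0, 100.0, 1e4):
            rec = update_latent_params(stats, lambda_reg=lam)
            norm = (np.abs(rec.W).sum() + np.abs(rec.h).sum()
                    + np.abs(rec.A).sum())
            assert norm <= prev + 1e-9
            prev = norm

    def test_no_inputs_reduced_regression(self):
        r = np.random.default_rng(9)
        Z = r.normal(size=(60, 2))
        obs = ObsParamsGaussian(B=np.eye(2), Gamma=np.ones(2))
        data = TrajectoryData(X=r.normal(size=(60, 2)))
        stats = accumulate_stats(point_mass_posterior(Z), data,
                                 random_plrnn(2, seed=10), obs)
        rec = update_latent_params(stats)
        assert rec.C.shape == (2, 0)
        assert rec.K == 0

    def test_structural_constraints(self):
        p = random_plrnn(3, seed=11)
        obs = random_gaussian_obs(2, 3, seed=11)
        data = TrajectoryData(
            X=np.random.default_rng(12).normal(size=(30, 2)))
        qf = assemble_quadratic(p, obs, data)
        post = compute_posterior(qf)
        stats = accumulate_stats(post, data, p, obs)
        rec = update_latent_params(stats, update_sigma=True)
        assert np.all(np.diag(rec.W) == 0.0)
        assert np.all(rec.Sigma > 0)
        _, _, Gamma = update_obs_params(stats)
        assert np.all(Gamma > 0)


class TestAccumulate:
    def test_point_mass_equals_plain_cross_products(self):
        r = np.random.default_rng(13)
        Z = r.normal(size=(20, 2))
        X = r.normal(size=(20, 3))
        obs = ObsParamsGaussian(B=r.normal(size=(3, 2)), Gamma=np.ones(3))
        stats = accumulate_stats(point_mass_posterior(Z), TrajectoryData(X=X),
                                 random_plrnn(2, seed=14), obs)
        phi = np.maximum(Z, 0)
        np.testing.assert_allclose(stats.H1, X.T @ phi, atol=1e-12)
        np.testing.assert_allclose(stats.H3, phi.T @ phi, atol=1e-12)
        np.testing.assert_allclose(stats.G[:2, :2], (Z[:-1].T @ Z[:-1]),
                                   atol=1e-12)

    def test_delta_kernel_matches_unconvolved(self):
        r = np.random.default_rng(15)
        Z = r.normal(size=(20, 2))
        X = r.normal(size=(20, 2))
        obsb = ObsParamsBOLD(B=np.eye(2), J=np.zeros((2, 0)),
                             Gamma=np.ones(2), hrf=np.ones(1))
        stats = accumulate_stats(point_mass_posterior(Z), TrajectoryData(X=X),
                                 random_plrnn(2, seed=16), obsb)
        np.testing.assert_allclose(stats.H1, X.T @ Z, atol=1e-12)
        np.testing.assert_allclose(stats.H3, Z.T @ Z, atol=1e-12)

    def test_convolved_second_moment_dense_oracle(self):
        # M=1, T=4, kernel length 2: H3 vs brute force under dense MVN
        T, M = 4, 1
        r = np.random.default_rng(17)
        m = r.normal(size=(T, M))
        # random PD block-tridiagonal covariance via a dense SPD matrix
        Araw = r.normal(size=(T, T))
        Vfull = Araw @ Araw.T / T + np.eye(T)
        # zero out beyond lag 1 to match the stored band exactly
        for i in range(T):
            for j in range(T):
                if abs(i - j) > 1:
                    Vfull[i, j] = 0.0
        # ensure still PD
        Vfull += np.eye(T) * max(0.0, -np.linalg.eigvalsh(Vfull).min() + 0.1)
        cov = {0: Vfull[np.arange(T), np.arange(T)].reshape(T, 1, 1),
               1: Vfull[np.arange(T - 1), np.arange(1, T)].reshape(T - 1, 1, 1)}
        phi = np.maximum(m, 0)
        post = LatentPosterior(
            z_map=m, d_omega=m > 0, cov=cov, Ephi=phi,
            Ezphi=np.einsum("ti,tj->tij", m, phi),
            Ephiphi=np.einsum("ti,tj->tij", phi, phi),
            Czphi=np.einsum("ti,tj->tij", m[1:], phi[:-1]))
        kern = np.array([1.0, 0.5])
        obsb = ObsParamsBOLD(B=np.ones((1, 1)), J=np.zeros((1, 0)),
                             Gamma=np.ones(1), hrf=kern)
        data = TrajectoryData(X=r.normal(size=(T, 1)))
        stats = accumulate_stats(post, data, random_plrnn(1, seed=18), obsb)
        # brute force: psi = H z with z ~ N(m, Vfull)
        H = np.zeros((T, T))
        for t in range(T):
            H[t, t] = kern[0]
            if t > 0:
                H[t, t - 1] = kern[1]
        psi_mean = H @ m.ravel()
        psi_cov = H @ Vfull @ H.T
        H3_ref = np.sum(psi_mean ** 2) + np.trace(psi_cov)
        assert stats.H3[0, 0] == pytest.approx(H3_ref, abs=1e-10)


class TestFullSweepLdsOracle:
    def test_em_sweep_matches_textbook(self):
        M, N, T = 3, 2, 40
        p = random_plrnn(M, seed=20, linear=True)
        obs = random_gaussian_obs(N, M, seed=20, linear=True)
        F = np.diag(p.A) + p.W
        r = np.random.default_rng(21)
        Z = np.zeros((T, M))
        Z[0] = p.mu0
        for t in range(1, T):
            Z[t] = F @ Z[t - 1] + p.h + np.sqrt(p.Sigma) * r.standard_normal(M)
        X = Z @ obs.B.T + np.sqrt(obs.Gamma) * r.standard_normal((T, N))
        data = TrajectoryData(X=X)
        qf = assemble_quadratic(p, obs, data)
        post = compute_posterior(qf)
        stats = accumulate_stats(post, data, p, obs)
        B_new, _, G_new = update_obs_params(stats)
        p_new = update_latent_params(stats, update_sigma=True, linear=True)
        bias = np.tile(p.h, (T, 1))
        bias[0] = p.mu0
        mu_s, V_s, lag1, _ = kalman_smoother(
            F, bias, np.diag(p.Sigma), obs.B, np.zeros((T, N)),
            np.diag(obs.Gamma), p.mu0, np.diag(p.Sigma), X)
        ref = lds_em_update(mu_s, V_s, lag1, X)
        assert np.abs(np.diag(p_new.A) + p_new.W - ref["F"]).max() < 1e-6
        assert np.abs(p_new.h - ref["h"]).max() < 1e-6
        assert np.abs(B_new - ref["B"]).max() < 1e-6
        assert np.abs(G_new - ref["Gamma"]).max() < 1e-6
        assert np.abs(p_new.Sigma - ref["Sigma"]).max() < 1e-6
        assert np.abs(p_new.mu0 - ref["mu0"]).max() < 1e-6
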