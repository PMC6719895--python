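"""Closed-form M-step updates from posterior expectations.

Observation parameters solve a stacked least-squares problem over the
(expected) observation features; latent parameters are obtained row-wise —
each latent unit m regresses E[z_{m,t}] on (z_{m,t-1}, phi(z_{j != m,t-1}),
s_t, 1) using posterior expectations, which enforces diag(W) = 0
structurally.  Optional L2 regularization shrinks (A, W, C, h) toward zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import TrajectoryData
from .estep import LatentPosterior
from .model import PLRNNParams
from .observation import ObsParamsBOLD, ObsParamsGaussian, build_hrf_operator

__all__ = [
    "SufficientStats",
    "accumulate_stats",
    "update_obs_params",
    "update_latent_params",
    "expected_joint_loglik_from_stats",
]

_VAR_FLOOR = 1e-8
_RIDGE = 1e-8


@dataclass
class SufficientStats:
    """Posterior-expected cross-product sums feeding the closed-form updates."""

    # latent-side: g = [z_{t-1}; phi(z_{t-1}); s_t; 1], targets z_t (t = 2..T)
    G: np.ndarray            # (D, D) with D = 2M + K + 1
    b: np.ndarray            # (M, D)   sum E[z_t g^T]
    Ez2_sum: np.ndarray      # (M,)     sum_{t>=2} E[z_t^2]
    Ez1: np.ndarray          # (M,)
    Var1: np.ndarray         # (M,)     diag Var(z_1)
    s1: np.ndarray           # (K,)
    # observation-side feature psi (phi(z_t) or (hrf*z)_t)
    F2: np.ndarray           # (N, N)   sum x x^T
    F7: np.ndarray           # (N, P)   sum x r^T
    F8: np.ndarray           # (P, P)   sum r r^T
    H1: np.ndarray           # (N, M)   sum x E[psi]^T
    H2: np.ndarray           # (P, M)   sum r E[psi]^T
    H3: np.ndarray           # (M, M)   sum E[psi psi^T]
    T: int = 0
    M: int = 0
    K: int = 0
    P: int = 0


def _bold_feature_moments(post: LatentPosterior, kernel: np.ndarray,
                          convolve_activation: bool):
    """E[(hrf*z)_t] and sum_t E[(hrf*z)(hrf*z)^T] from banded covariance.

    Cross-lag covariance beyond the stored band is truncated (dropped).
    """
    T, M = post.T, post.M
    op = build_hrf_operator(T, M, kernel)
    base = post.Ephi if convolve_activation else post.z_map
    psi = op.apply(base)
    lag_max = max(post.cov)
    Cov = np.zeros((T, M, M))
    L = op.L
    k = op.kernel
    for a in range(L):
        for bb in range(L):
            l = abs(bb - a)
            if l > lag_max:
                continue
            hi = max(a, bb)
            arr = post.cov[l]
            blk = arr if bb >= a else arr.transpose(0, 2, 1)
            # Cov(z_{t-a}, z_{t-b}) for t >= hi maps to blk[t - hi]
            n = T - hi
            if n <= 0:
                continue
            Cov[hi:] += k[a] * k[bb] * blk[:n]
    H3 = np.einsum("ti,tj->ij", psi, psi) + Cov.sum(axis=0)
    return psi, H3


def accumulate_stats(post: LatentPosterior, data: TrajectoryData,
                     params: PLRNNParams, obs_params) -> SufficientStats:
    T, M = post.T, post.M
    K = data.K
    P = data.P if isinstance(obs_params, ObsParamsBOLD) else 0
    m = post.z_map
    V = post.cov[0]
    vdiag = np.einsum("tii->ti", V)
    Ezz = V + m[:, :, None] * m[:, None, :]
    C1 = post.cov.get(1)
    if T > 1:
        Ezz_cross = C1.transpose(0, 2, 1) + m[1:, :, None] * m[:-1, None, :]
    else:
        Ezz_cross = np.zeros((0, M, M))

    D = 2 * M + K + 1
    G = np.zeros((D, D))
    b = np.zeros((M, D))
    sl_z = slice(0, M)
    sl_p = slice(M, 2 * M)
    sl_s = slice(2 * M, 2 * M + K)
    sl_1 = 2 * M + K

    G[sl_z, sl_z] = Ezz[:-1].sum(axis=0)
    G[sl_z, sl_p] = post.Ezphi[:-1].sum(axis=0)
    G[sl_p, sl_z] = G[sl_z, sl_p].T
    G[sl_p, sl_p] = post.Ephiphi[:-1].sum(axis=0)
    G[sl_z, sl_1] = m[:-1].sum(axis=0)
    G[sl_p, sl_1] = post.Ephi[:-1].sum(axis=0)
    G[sl_1, sl_z] = G[sl_z, sl_1]
    G[sl_1, sl_p] = G[sl_p, sl_1]
    G[sl_1, sl_1] = T - 1
    if K > 0:
        S_next = data.S[1:]
        G[sl_z, sl_s] = np.einsum("ti,tk->ik", m[:-1], S_next)
        G[sl_p, sl_s] = np.einsum("ti,tk->ik", post.Ephi[:-1], S_next)
        G[sl_s, sl_z] = G[sl_z, sl_s].T
        G[sl_s, sl_p] = G[sl_p, sl_s].T
        G[sl_s, sl_s] = S_next.T @ S_next
        G[sl_s, sl_1] = S_next.sum(axis=0)
        G[sl_1, sl_s] = G[sl_s, sl_1]

    b[:, sl_z] = Ezz_cross.sum(axis=0)
    b[:, sl_p] = post.Czphi.sum(axis=0)
    b[:, sl_1] = m[1:].sum(axis=0)
    if K > 0:
        b[:, sl_s] = np.einsum("ti,tk->ik", m[1:], data.S[1:])

    Ez2_sum = (vdiag[1:] + m[1:] ** 2).sum(axis=0)

    # observation-side features
    if isinstance(obs_params, ObsParamsBOLD):
        psi, H3 = _bold_feature_moments(post, obs_params.kernel,
                                        obs_params.convolve_activation)
    else:
        psi = post.Ephi
        H3 = post.Ephiphi.sum(axis=0)
    X = data.X
    H1 = X.T @ psi
    F2 = X.T @ X
    if P > 0:
        R = data.R
        F7 = X.T @ R
        F8 = R.T @ R
        H2 = R.T @ psi
    else:
        F7 = np.zeros((data.N, 0))
        F8 = np.zeros((0, 0))
        H2 = np.zeros((0, M))

    s1 = data.S[0] if K > 0 else np.zeros(0)
    return SufficientStats(G=G, b=b, Ez2_sum=Ez2_sum, Ez1=m[0].copy(),
                           Var1=vdiag[0].copy(), s1=s1, F2=F2, F7=F7, F8=F8,
                           H1=H1, H2=H2, H3=H3, T=T, M=M, K=K, P=P)


def _solve_psd(Gram: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.solve(Gram, rhs)
    except np.linalg.LinAlgError:
        pass
    Gr = Gram + _RIDGE * np.eye(Gram.shape[0]) * max(1.0, np.trace(Gram) / Gram.shape[0])
    cond = np.linalg.cond(Gr)
    if not np.isfinite(cond) or cond > 1e15:
        raise np.linalg.LinAlgError(
            f"observation Gram singular after ridge (cond={cond:.3g})")
    return np.linalg.solve(Gr, rhs)


def update_obs_params(stats: SufficientStats):
    """Stacked least-squares solution Y = [B J] and diagonal Gamma."""
    Mdim, P, T = stats.M, stats.P, stats.T
    Gram = np.zeros((Mdim + P, Mdim + P))
    Gram[:Mdim, :Mdim] = stats.H3
    rhs = np.zeros((stats.F2.shape[0], Mdim + P))
    rhs[:, :Mdim] = stats.H1
    if P > 0:
        Gram[:Mdim, Mdim:] = stats.H2.T
        Gram[Mdim:, :Mdim] = stats.H2
        Gram[Mdim:, Mdim:] = stats.F8
        rhs[:, Mdim:] = stats.F7
    Y = _solve_psd(Gram, rhs.T).T
    B = Y[:, :Mdim]
    J = Y[:, Mdim:]
    Q = (stats.F2 - stats.H1 @ B.T - B @ stats.H1.T + B @ stats.H3 @ B.T)
    if P > 0:
        Q = (Q - stats.F7 @ J.T - J @ stats.F7.T + B @ stats.H2.T @ J.T
             + J @ stats.H2 @ B.T + J @ stats.F8 @ J.T)
    Gamma = np.maximum(np.diag(Q) / T, _VAR_FLOOR)
    return B, J, Gamma


def update_latent_params(stats: SufficientStats, lambda_reg: float = 0.0,
                         update_sigma: bool = True,
                         linear: bool = False,
                         sigma_fixed: np.ndarray | None = None) -> PLRNNParams:
    """Row-wise regularized normal-equation solves for the latent model."""
    M, K = stats.M, stats.K
    D = 2 * M + K + 1
    A = np.zeros(M)
    W = np.zeros((M, M))
    C = np.zeros((M, K))
    h = np.zeros(M)
    Sigma = np.zeros(M)
    betas = np.zeros((M, D))
    for mrow in range(M):
        idx = [mrow] + [M + j for j in range(M) if j != mrow] + \
              list(range(2 * M, 2 * M + K)) + [2 * M + K]
        idx = np.array(idx)
        Gm = stats.G[np.ix_(idx, idx)]
        if lambda_reg > 0:
            Gm = Gm + lambda_reg * np.eye(len(idx))
        beta = _solve_psd(Gm, stats.b[mrow, idx])
        A[mrow] = beta[0]
        off = [j for j in range(M) if j != mrow]
        W[mrow, off] = beta[1:M]
        C[mrow] = beta[M:M + K]
        h[mrow] = beta[M + K]
        full = np.zeros(D)
        full[idx] = beta
        betas[mrow] = full
        res2 = (stats.Ez2_sum[mrow] - 2.0 * full @ stats.b[mrow]
                + full @ stats.G @ full)
        Sigma[mrow] = max(res2, 0.0)
    mu0 = stats.Ez1 - (C @ stats.s1 if K > 0 else 0.0)
    if update_sigma:
        Sigma = np.maximum((Sigma + stats.Var1) / stats.T, _VAR_FLOOR)
    elif sigma_fixed is not None:
        Sigma = np.asarray(sigma_fixed, dtype=float).copy()
    else:
        Sigma = np.ones(M)
    return PLRNNParams(mu0=mu0, A=A, W=W, C=C, h=h, Sigma=Sigma, linear=linear)


def expected_joint_loglik_from_stats(params: PLRNNParams, obs_params,
                                     stats: SufficientStats) -> float:
    """Plug posterior expectations into the joint log density."""
    M, K, T = stats.M, stats.K, stats.T
    D = 2 * M + K + 1
    ll = 0.0
    # t = 1 prior term
    mu = params.mu0 + (params.C @ stats.s1 if K > 0 else 0.0)
    e1 = stats.Var1 + (stats.Ez1 - mu) ** 2
    ll -= 0.5 * np.sum(e1 / params.Sigma)
    # transition terms via the full-beta quadratic expansion
    for mrow in range(M):
        beta = np.zeros(D)
        beta[mrow] = params.A[mrow]
        beta[M:2 * M] = params.W[mrow]
        if K > 0:
            beta[2 * M:2 * M + K] = params.C[mrow]
        beta[2 * M + K] = params.h[mrow]
        res2 = (stats.Ez2_sum[mrow] - 2.0 * beta @ stats.b[mrow]
                + beta @ stats.G @ beta)
        ll -= 0.5 * res2 / params.Sigma[mrow]
    ll -= 0.5 * T * np.sum(np.log(2.0 * np.pi * params.Sigma))
    # observation terms
    B = obs_params.B
    Q = (stats.F2 - stats.H1 @ B.T - B @ stats.H1.T + B @ stats.H3 @ B.T)
    if stats.P > 0:
        J = obs_params.J
        Q = (Q - stats.F7 @ J.T - J @ stats.F7.T + B @ stats.H2.T @ J.T
             + J @ stats.H2 @ B.T + J @ stats.F8 @ J.T)
    ll -= 0.5 * np.sum(np.diag(Q) / obs_params.Gamma)
    ll -= 0.5 * T * np.sum(np.log(2.0 * np.pi * obs_params.Gamma))
    return float(ll)
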