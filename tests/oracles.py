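"""Independent reference implementations used only as test oracles.

These deliberately use different algorithms than the package (dense RTS
Kalman smoothing, dense matrix inversion, brute-force optimization,
Monte-Carlo integration) so that agreement is informative.
"""

from __future__ import annotations

import numpy as np


def kalman_smoother(F, bias, Q, Hobs, c_obs, Rn, mu1, V1, X):
    """Dense RTS smoother for x_t = H z_t + c_t + eta, z_t = F z_{t-1} + b_t + eps.

    F: (M, M); bias: (T, M) per-step drift; Q: (M, M); Hobs: (N, M);
    c_obs: (T, N); Rn: (N, N); z_1 ~ N(mu1, V1).  Returns (means (T, M),
    covs (T, M, M), lag1 (T-1, M, M) = Cov(z_t, z_{t+1}), loglik).
    """
    T, N = X.shape
    M = F.shape[0]
    mu_f = np.zeros((T, M))
    V_f = np.zeros((T, M, M))
    mu_p = np.zeros((T, M))
    V_p = np.zeros((T, M, M))
    loglik = 0.0
    for t in range(T):
        if t == 0:
            mp, Vp = mu1, V1
        else:
            mp = F @ mu_f[t - 1] + bias[t]
            Vp = F @ V_f[t - 1] @ F.T + Q
        mu_p[t], V_p[t] = mp, Vp
        yhat = Hobs @ mp + c_obs[t]
        Sm = Hobs @ Vp @ Hobs.T + Rn
        innov = X[t] - yhat
        Kg = Vp @ Hobs.T @ np.linalg.inv(Sm)
        mu_f[t] = mp + Kg @ innov
        V_f[t] = (np.eye(M) - Kg @ Hobs) @ Vp
        sign, ld = np.linalg.slogdet(2 * np.pi * Sm)
        loglik += -0.5 * (ld + innov @ np.linalg.solve(Sm, innov))
    # RTS backward pass
    mu_s = mu_f.copy()
    V_s = V_f.copy()
    lag1 = np.zeros((T - 1, M, M))
    for t in range(T - 2, -1, -1):
        Jt = V_f[t] @ F.T @ np.linalg.inv(V_p[t + 1])
        mu_s[t] = mu_f[t] + Jt @ (mu_s[t + 1] - mu_p[t + 1])
        V_s[t] = V_f[t] + Jt @ (V_s[t + 1] - V_p[t + 1]) @ Jt.T
        lag1[t] = Jt @ V_s[t + 1]           # Cov(z_t, z_{t+1} | X)
    return mu_s, V_s, lag1, loglik


def lds_em_update(mu_s, V_s, lag1, X, S=None):
    """One textbook LDS EM M-step (transition z_t = F z_{t-1} + h, obs x = B z).

    Returns dict with F (full transition matrix), h, B, Gamma (diag), Sigma
    (diag), mu0 from smoothed moments.
    """
    T, M = mu_s.shape
    Ezz = V_s + np.einsum("ti,tj->tij", mu_s, mu_s)
    Ezz_cross = lag1.transpose(0, 2, 1) + np.einsum(
        "ti,tj->tij", mu_s[1:], mu_s[:-1])   # E[z_{t+1} z_t^T]
    # transition + bias via augmented regressor [z; 1]
    G = np.zeros((M + 1, M + 1))
    G[:M, :M] = Ezz[:-1].sum(0)
    G[:M, M] = mu_s[:-1].sum(0)
    G[M, :M] = G[:M, M]
    G[M, M] = T - 1
    b = np.zeros((M, M + 1))
    b[:, :M] = Ezz_cross.sum(0)
    b[:, M] = mu_s[1:].sum(0)
    sol = np.linalg.solve(G, b.T).T
    F, h = sol[:, :M], sol[:, M]
    res = np.zeros(M)
    for m in range(M):
        beta = sol[m]
        res[m] = (Ezz[1:].sum(0)[m, m] - 2 * beta @ b[m] + beta @ G @ beta)
    Sigma = (res + np.diag(V_s[0])) / T
    # observation x = B z
    Bm = (X.T @ mu_s) @ np.linalg.inv(Ezz.sum(0))
    Q = X.T @ X - (X.T @ mu_s) @ Bm.T - Bm @ (X.T @ mu_s).T + Bm @ Ezz.sum(0) @ Bm.T
    Gamma = np.diag(Q) / T
    return {"F": F, "h": h, "B": Bm, "Gamma": Gamma, "Sigma": Sigma,
            "mu0": mu_s[0].copy()}


def mc_relu_moments(mi, mj, vi, vj, cij, n=1_000_000, seed=0):
    """Monte-Carlo (E[phi_j], E[z_i phi_j], E[phi_i phi_j]) and their SEs."""
    rng = np.random.default_rng(seed)
    cov = np.array([[vi, cij], [cij, vj]])
    L = np.linalg.cholesky(cov)
    zz = np.array([mi, mj]) + rng.standard_normal((n, 2)) @ L.T
    pi = np.maximum(zz[:, 0], 0.0)
    pj = np.maximum(zz[:, 1], 0.0)
    vals = np.stack([pj, zz[:, 0] * pj, pi * pj], axis=1)
    return vals.mean(0), vals.std(0) / np.sqrt(n)
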