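"""Global Laplace/MAP state inference for the PLRNN state-space model.

The posterior over the stacked latent path is piecewise Gaussian.  For a
fixed active-region configuration the log-posterior is an exact quadratic
whose negative Hessian is block-banded (tridiagonal for the instantaneous
Gaussian observation model, bandwidth equal to the HRF kernel length for the
BOLD model).  The MAP path is found by iterating (1) a banded linear solve
for fixed region indicator d and (2) flipping the indicator bits that are
inconsistent with the solution, with a cycle guard.  The state covariance is
the inverse negative Hessian at the MAP, of which only the block-banded part
is ever computed (via a super-block tridiagonal recursion that scales
linearly in T).  Rectified-Gaussian moments needed by the M-step follow in
closed form from these blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solveh_banded

from . import _rectnorm as rn
from .data import TrajectoryData
from .model import PLRNNParams
from .observation import (HRFConvolutionOperator, ObsParamsBOLD,
                          ObsParamsGaussian, build_hrf_operator)

__all__ = [
    "QuadraticForm",
    "LatentPosterior",
    "assemble_quadratic",
    "solve_map",
    "posterior_covariance",
    "relu_moments",
    "compute_posterior",
    "expected_joint_loglik",
]

_JITTER = 1e-8
_MAX_ROUNDS = 100


@dataclass
class QuadraticForm:
    """Structured representation of the piecewise-quadratic MAP objective.

    The MT x MT matrices of the compact formulation are never assembled
    densely; instead the parameter-derived constant pieces are stored and the
    negative Hessian / linear term are produced as per-lag block arrays for
    any region configuration d.
    """

    params: PLRNNParams
    obs: object
    data: TrajectoryData
    Sinv: np.ndarray = field(init=False)
    BtGB: np.ndarray = field(init=False)       # B^T Gamma^-1 B
    xg: np.ndarray = field(init=False)         # (T, M): B^T Gamma^-1 (x - J r)
    cvec: np.ndarray = field(init=False)       # (T, M) drift constants h + C s_t
    hrf_op: HRFConvolutionOperator = field(init=False)
    obs_lag_coef: np.ndarray | None = field(init=False, default=None)

    def __post_init__(self):
        p, o, d = self.params, self.obs, self.data
        T, M = d.T, p.M
        self.Sinv = 1.0 / p.Sigma
        Ginv = 1.0 / o.Gamma
        self.BtGB = o.B.T @ (Ginv[:, None] * o.B)
        resid = d.X.copy()
        if isinstance(o, ObsParamsBOLD) and o.P > 0:
            resid -= d.R @ o.J.T
        self.xg = (Ginv * resid) @ o.B
        self.cvec = np.tile(p.h, (T, 1))
        self.cvec[0] = p.mu0
        if p.K > 0 and d.S is not None:
            self.cvec += d.S @ p.C.T
        kernel = o.kernel if isinstance(o, ObsParamsBOLD) else np.ones(1)
        self.hrf_op = build_hrf_operator(T, M, kernel)
        if isinstance(o, ObsParamsBOLD):
            # c_{l}(t): scalar weight of BtGB in block (t, t+l) of H^T U3 H
            L = self.hrf_op.L
            coef = np.zeros((L, T))
            k = self.hrf_op.kernel
            for lag in range(L):
                for a in range(L - lag):
                    n_valid = T - lag - a
                    if n_valid > 0:
                        coef[lag, :n_valid] += k[a + lag] * k[a]
            self.obs_lag_coef = coef

    # -- structural properties ------------------------------------------------
    @property
    def T(self) -> int:
        return self.data.T

    @property
    def M(self) -> int:
        return self.params.M

    @property
    def lag_max(self) -> int:
        if self.obs_lag_coef is not None:
            return max(1, self.hrf_op.L - 1)
        return 1

    @property
    def is_bold(self) -> bool:
        return isinstance(self.obs, ObsParamsBOLD)

    def _transition_mats(self, d: np.ndarray) -> np.ndarray:
        """M_t = A + W D_t for t = 1..T-1, shape (T-1, M, M)."""
        p = self.params
        dmask = np.ones_like(d[:-1], dtype=float) if p.linear else d[:-1].astype(float)
        Mt = p.W[None, :, :] * dmask[:, None, :]
        Mt[:, np.arange(self.M), np.arange(self.M)] += p.A
        return Mt

    def neg_hessian_blocks(self, d: np.ndarray) -> dict[int, np.ndarray]:
        """Blocks of the negative Hessian: {lag: (T-lag, M, M)} for block (t, t+lag)."""
        p, T, M = self.params, self.T, self.M
        Mt = self._transition_mats(d)
        diag = np.tile(np.diag(self.Sinv), (T, 1, 1))
        diag[:-1] += np.einsum("tij,i,tik->tjk", Mt, self.Sinv, Mt)
        off = -(Mt.transpose(0, 2, 1) * self.Sinv[None, None, :])
        blocks = {0: diag, 1: off}
        df = np.ones_like(d, dtype=float) if p.linear else d.astype(float)
        if not self.is_bold:
            diag += self.BtGB[None, :, :] * (df[:, :, None] * df[:, None, :])
        else:
            act = self.obs.convolve_activation
            coef = self.obs_lag_coef
            for lag in range(min(self.hrf_op.L, T)):
                term = coef[lag, :T - lag, None, None] * self.BtGB[None, :, :]
                if act:
                    term = term * (df[:T - lag, :, None] * df[lag:, None, :])
                if lag == 0:
                    diag += term
                elif lag == 1:
                    off += term
                else:
                    blocks[lag] = blocks.get(lag, np.zeros((T - lag, M, M))) + term
        return blocks

    def linear_term(self, d: np.ndarray) -> np.ndarray:
        """(T, M) linear coefficient of the objective for region d."""
        Mt = self._transition_mats(d)
        v = self.Sinv * self.cvec
        v[:-1] -= np.einsum("tij,i,ti->tj", Mt, self.Sinv, self.cvec[1:])
        if not self.is_bold:
            obs_v = self.xg if self.params.linear else self.xg * d
            v = v + obs_v
        else:
            obs_v = self.hrf_op.apply_adjoint(self.xg)
            if self.obs.convolve_activation and not self.params.linear:
                obs_v = obs_v * d
            v = v + obs_v
        return v

    def objective(self, Z: np.ndarray) -> float:
        """True piecewise objective (Eq-5-type quadratic, no normalization consts)."""
        p, dta = self.params, self.data
        Z = Z.reshape(self.T, self.M)
        phi = p.phi(Z)
        val = -0.5 * np.sum(self.Sinv * (Z[0] - self.cvec[0]) ** 2)
        pred = Z[:-1] * p.A + phi[:-1] @ p.W.T + self.cvec[1:]
        val += -0.5 * np.sum(self.Sinv * (Z[1:] - pred) ** 2)
        if not self.is_bold:
            Xhat = phi @ self.obs.B.T
            resid = dta.X - Xhat
        else:
            base = phi if self.obs.convolve_activation else Z
            Xhat = self.hrf_op.apply(base) @ self.obs.B.T
            resid = dta.X - Xhat
            if self.obs.P > 0:
                resid = resid - dta.R @ self.obs.J.T
        val += -0.5 * np.sum(resid ** 2 / self.obs.Gamma)
        return float(val)


def assemble_quadratic(params: PLRNNParams, obs_params,
                       data: TrajectoryData) -> QuadraticForm:
    if np.any(params.Sigma <= 0) or np.any(obs_params.Gamma <= 0):
        raise ValueError("Sigma and Gamma must be invertible (positive)")
    return QuadraticForm(params, obs_params, data)


def _blocks_to_banded(blocks: dict[int, np.ndarray], T: int, M: int) -> np.ndarray:
    """Upper banded storage (scipy solveh_banded convention) from lag blocks."""
    lmax = max(blocks)
    u = lmax * M + (M - 1)
    ab = np.zeros((u + 1, T * M))
    for lag, arr in blocks.items():
        n = arr.shape[0]
        for r in range(M):
            for c in range(M):
                if lag == 0 and r > c:
                    continue
                row = u + r - c - lag * M
                if row < 0:
                    continue
                ab[row, lag * M + c::M][:n] = arr[:, r, c]
    return ab


def _solve_banded_psd(blocks: dict[int, np.ndarray], v: np.ndarray,
                      T: int, M: int) -> np.ndarray:
    ab = _blocks_to_banded(blocks, T, M)
    try:
        return solveh_banded(ab, v.ravel()).reshape(T, M)
    except np.linalg.LinAlgError:
        ab2 = ab.copy()
        ab2[-1] += _JITTER
        return solveh_banded(ab2, v.ravel()).reshape(T, M)


def _bitflip_search(qf: QuadraticForm, d0: np.ndarray, max_rounds: int):
    """Core fixed-point iteration from a region configuration d0."""
    T, M = qf.T, qf.M
    d = d0.copy()
    visited: set[bytes] = set()
    best_q = -np.inf
    best = None
    for rnd in range(1, max_rounds + 1):
        visited.add(d.tobytes())
        z = _solve_banded_psd(qf.neg_hessian_blocks(d), qf.linear_term(d), T, M)
        q = qf.objective(z)
        if q > best_q:
            best_q, best = q, (z, d.copy())
        newd = z > 0
        if np.array_equal(newd, d):
            return z, d, rnd, True, q
        if newd.tobytes() in visited:
            # cycle: flip only the most violated single bit
            viol = np.abs(z) * (newd != d)
            idx = np.unravel_index(np.argmax(viol), viol.shape)
            cand = d.copy()
            cand[idx] = ~cand[idx]
            if cand.tobytes() in visited:
                zb, db = best
                return zb, db, rnd, False, best_q
            d = cand
        else:
            d = newd
    zb, db = best
    return zb, db, max_rounds, False, best_q


def _dense_neg_hessian(qf: QuadraticForm, d: np.ndarray) -> np.ndarray:
    T, M = qf.T, qf.M
    P = np.zeros((T * M, T * M))
    for lag, arr in qf.neg_hessian_blocks(d).items():
        for t in range(arr.shape[0]):
            P[t * M:(t + 1) * M, (t + lag) * M:(t + lag + 1) * M] += arr[t]
            if lag > 0:
                P[(t + lag) * M:(t + lag + 1) * M, t * M:(t + 1) * M] += arr[t].T
    return P


def _qp_region_solve(qf: QuadraticForm, d: np.ndarray) -> np.ndarray | None:
    """Maximize the fixed-region quadratic subject to its sign constraints.

    Within region d the objective is concave quadratic; the sign-flipped
    variables y = S z >= 0 turn the problem into an NNLS after a Cholesky
    factorization.  Dense — small problems only (QP finishing step).
    """
    from scipy.optimize import nnls
    T, M = qf.T, qf.M
    P = _dense_neg_hessian(qf, d)
    v = qf.linear_term(d).ravel()
    s = np.where(d.ravel(), 1.0, -1.0)
    Pt = P * s[:, None] * s[None, :]
    qt = s * v
    try:
        R = np.linalg.cholesky(Pt).T          # Pt = R^T R
    except np.linalg.LinAlgError:
        return None
    rhs = np.linalg.solve(R.T, qt)
    y, _ = nnls(R, rhs)
    return (s * y).reshape(T, M)


def solve_map(qf: QuadraticForm, z_init: np.ndarray | None = None,
              max_rounds: int = _MAX_ROUNDS, n_starts: int = 1,
              polish: bool = False, seed: int = 0):
    """Fixed-point / bit-flip MAP search.

    Returns (z_map (T, M), d_omega (T, M) bool, n_rounds, converged).  The
    default single start begins at the regions of ``z_init`` (zeros if
    absent, e.g. a warm start from the previous EM iteration).  ``n_starts``
    adds random region initializations and keeps the best objective;
    ``polish`` runs greedy single-bit improvement sweeps afterwards (only
    sensible for small MT).
    """
    T, M = qf.T, qf.M
    if z_init is None:
        z_init = np.zeros((T, M))
    if qf.params.linear:
        d = np.ones((T, M), dtype=bool)
        z = _solve_banded_psd(qf.neg_hessian_blocks(d), qf.linear_term(d), T, M)
        return z, d, 1, True
    starts = [np.asarray(z_init) > 0]
    rng = np.random.default_rng(seed)
    for _ in range(max(0, n_starts - 1)):
        starts.append(rng.random((T, M)) > 0.5)
    best = None
    tot_rounds = 0
    endpoints = []
    for d0 in starts:
        z, d, rnds, conv, q = _bitflip_search(qf, d0, max_rounds)
        tot_rounds += rnds
        endpoints.append(d.copy())
        if best is None or q > best[-1]:
            best = (z, d, conv, q)
    z, d, conv, q = best
    if polish and T * M <= 12:
        # exact global maximum: constrained QP in every region
        for code in range(2 ** (T * M)):
            c = np.array([(code >> i) & 1 for i in range(T * M)],
                         dtype=bool).reshape(T, M)
            zc = _qp_region_solve(qf, c)
            if zc is None:
                continue
            qc = qf.objective(zc)
            if qc > q + 1e-12:
                z, q = zc, qc
                d = zc > 0
                conv = True
        return z, d, tot_rounds, conv
    if polish:
        # QP finishing step: sign-constrained maximization over candidate
        # regions (the bit-flip iteration cannot terminate at an optimum on a
        # region boundary).  Greedy single-bit region exploration around the
        # incumbent, each candidate solved as a constrained QP.
        improved = True
        sweeps = 0
        tried: set[bytes] = set()
        frontier = endpoints
        while improved and sweeps < 10:
            improved = False
            sweeps += 1
            cands = []
            for base in frontier:
                cands.append(base.copy())
                for idx in np.ndindex(T, M):
                    c = base.copy()
                    c[idx] = ~c[idx]
                    cands.append(c)
            frontier = [d]
            for c in cands:
                key = c.tobytes()
                if key in tried:
                    continue
                tried.add(key)
                zc = _qp_region_solve(qf, c)
                if zc is None:
                    continue
                qc = qf.objective(zc)
                if qc > q + 1e-10:
                    z, q = zc, qc
                    d = zc > 0
                    conv = True
                    improved = True
                    frontier = [d]
    return z, d, tot_rounds, conv


def _superblocks(blocks: dict[int, np.ndarray], T: int, M: int, S: int):
    """Group lag blocks into super-block tridiagonal (diag, offdiag) lists."""
    nb = (T + S - 1) // S
    sizes = [min(S, T - i * S) for i in range(nb)]
    diags, offs = [], []
    for i in range(nb):
        t0, si = i * S, sizes[i]
        D = np.zeros((si * M, si * M))
        for lag, arr in blocks.items():
            for a in range(si):
                b = a + lag
                if b < si and t0 + a < arr.shape[0]:
                    blk = arr[t0 + a]
                    D[a * M:(a + 1) * M, b * M:(b + 1) * M] = blk
                    if lag > 0:
                        D[b * M:(b + 1) * M, a * M:(a + 1) * M] = blk.T
        diags.append(D)
        if i + 1 < nb:
            sj = sizes[i + 1]
            E = np.zeros((si * M, sj * M))
            for lag, arr in blocks.items():
                if lag == 0:
                    continue
                for a in range(si):
                    b = a + lag - si  # index within super-block i+1
                    if 0 <= b < sj and t0 + a < arr.shape[0]:
                        E[a * M:(a + 1) * M, b * M:(b + 1) * M] = arr[t0 + a]
            offs.append(E)
    return diags, offs, sizes


def posterior_covariance(qf: QuadraticForm, d: np.ndarray):
    """Block-banded part of V = (negative Hessian)^-1 at region d.

    Returns ``(cov, logdet)`` where ``cov[lag]`` is a (T-lag, M, M) array of
    Cov(z_t, z_{t+lag}) for lag = 0..lag_max and ``logdet`` is
    log det(negative Hessian) (used for the Gaussian entropy).
    """
    T, M = qf.T, qf.M
    blocks = qf.neg_hessian_blocks(d)
    S = qf.lag_max
    diags, offs, sizes = _superblocks(blocks, T, M, S)
    nb = len(diags)
    fwd = [None] * nb
    bwd = [None] * nb
    fwd[0] = diags[0]
    logdet = 0.0
    for i in range(1, nb):
        sol = np.linalg.solve(fwd[i - 1], offs[i - 1])
        fwd[i] = diags[i] - offs[i - 1].T @ sol
    for D in fwd:
        sign, ld = np.linalg.slogdet(D)
        logdet += ld
    bwd[nb - 1] = diags[nb - 1]
    for i in range(nb - 2, -1, -1):
        sol = np.linalg.solve(bwd[i + 1], offs[i].T)
        bwd[i] = diags[i] - offs[i] @ sol
    Vii = []
    Vio = []
    for i in range(nb):
        P = fwd[i] + bwd[i] - diags[i]
        P = 0.5 * (P + P.T)
        Vii.append(np.linalg.inv(P))
    for i in range(nb - 1):
        Vio.append(-np.linalg.solve(fwd[i], offs[i] @ Vii[i + 1]))
    cov = {lag: np.zeros((T - lag, M, M)) for lag in range(S + 1)}
    for i in range(nb):
        t0, si = i * S, sizes[i]
        for a in range(si):
            for lag in range(S + 1):
                t = t0 + a
                if t + lag >= T:
                    continue
                b = a + lag
                if b < si:
                    cov[lag][t] = Vii[i][a * M:(a + 1) * M, b * M:(b + 1) * M]
                else:
                    bb = b - si
                    cov[lag][t] = Vio[i][a * M:(a + 1) * M, bb * M:(bb + 1) * M]
    # enforce symmetric positive marginal variances
    cov[0] = 0.5 * (cov[0] + cov[0].transpose(0, 2, 1))
    return cov, float(logdet)


def relu_moments(m, v, cov=None):
    """Closed-form rectified-Gaussian moments.

    For scalars/arrays ``m``, ``v`` returns (E[phi], E[z phi], E[phi phi])
    elementwise.  If ``cov`` (same-shape covariance between two coordinates)
    is given, the latter two are the cross moments E[z_i phi(z_j)] and
    E[phi(z_i) phi(z_j)] — in that case m and v must be tuples (mi, mj),
    (vi, vj).
    """
    if cov is None:
        m = np.asarray(m, dtype=float)
        v = np.asarray(v, dtype=float)
        if np.any(v <= 0):
            raise ValueError("variance must be positive")
        return rn.rect_mean(m, v), rn.rect_second_moment(m, v), rn.rect_second_moment(m, v)
    (mi, mj), (vi, vj) = m, v
    ezphi = rn.rect_cross_one_sided(mi, mj, vj, cov)
    ephiphi = rn.rect_cross_two_sided(mi, mj, vi, vj, cov)
    return rn.rect_mean(mj, vj), ezphi, ephiphi


@dataclass
class LatentPosterior:
    """MAP path, region indicator, covariance blocks and ReLU moments."""

    z_map: np.ndarray                  # (T, M)
    d_omega: np.ndarray                # (T, M) bool
    cov: dict                          # {lag: (T-lag, M, M)} Cov(z_t, z_{t+lag})
    Ephi: np.ndarray                   # (T, M)
    Ezphi: np.ndarray                  # (T, M, M)  E[z_{i,t} phi(z_{j,t})]
    Ephiphi: np.ndarray                # (T, M, M)  E[phi(z_i) phi(z_j)] at t
    Czphi: np.ndarray                  # (T-1, M, M) E[z_{i,t+1} phi(z_{j,t})]
    logdet_precision: float = 0.0
    n_flip_rounds: int = 0
    converged: bool = True

    @property
    def T(self) -> int:
        return self.z_map.shape[0]

    @property
    def M(self) -> int:
        return self.z_map.shape[1]

    def entropy(self) -> float:
        MT = self.T * self.M
        return 0.5 * (MT * np.log(2 * np.pi * np.e) - self.logdet_precision)


def _moments_from_gaussian(m: np.ndarray, cov: dict, linear: bool):
    """All same-time and lag-1 ReLU moments from MAP means and cov blocks."""
    T, M = m.shape
    V = cov[0]
    vdiag = np.clip(np.einsum("tii->ti", V), 1e-12, None)
    Ezz = V + m[:, :, None] * m[:, None, :]
    C1 = cov[1] if 1 in cov and T > 1 else np.zeros((max(T - 1, 0), M, M))
    Ezz_cross = C1.transpose(0, 2, 1) + m[1:, :, None] * m[:-1, None, :]
    if linear:
        return m.copy(), Ezz, Ezz, Ezz_cross
    # same-time: mi over rows i, phi over columns j
    mi = np.broadcast_to(m[:, :, None], (T, M, M))
    mj = np.broadcast_to(m[:, None, :], (T, M, M))
    vi = np.broadcast_to(vdiag[:, :, None], (T, M, M))
    vj = np.broadcast_to(vdiag[:, None, :], (T, M, M))
    Ephi = rn.rect_mean(m, vdiag)
    Ezphi = rn.rect_cross_one_sided(mi, mj, vj, V)
    Ephiphi = rn.rect_cross_two_sided(mi, mj, vi, vj, V)
    e2 = rn.rect_second_moment(m, vdiag)
    ii = np.arange(M)
    Ezphi[:, ii, ii] = e2
    Ephiphi[:, ii, ii] = e2
    # cross-time: z at t+1 (rows), phi(z) at t (cols); Cov(z_{i,t+1}, z_{j,t})
    if T > 1:
        Cz = C1.transpose(0, 2, 1)  # [t][i,j] = Cov(z_{i,t+1}, z_{j,t})
        mi1 = np.broadcast_to(m[1:, :, None], (T - 1, M, M))
        mj0 = np.broadcast_to(m[:-1, None, :], (T - 1, M, M))
        vj0 = np.broadcast_to(vdiag[:-1, None, :], (T - 1, M, M))
        Czphi = rn.rect_cross_one_sided(mi1, mj0, vj0, Cz)
    else:
        Czphi = np.zeros((0, M, M))
    return Ephi, Ezphi, Ephiphi, Czphi


def compute_posterior(qf: QuadraticForm, z_init: np.ndarray | None = None,
                      cov_params: PLRNNParams | None = None) -> LatentPosterior:
    """Full E-step: MAP search, covariance blocks, and ReLU moments.

    ``cov_params`` optionally re-evaluates the covariance (and moments) under
    different latent parameters (used to re-estimate V with Sigma = I after
    training).
    """
    z, d, rounds, conv = solve_map(qf, z_init)
    if cov_params is not None:
        qf_cov = assemble_quadratic(cov_params, qf.obs, qf.data)
    else:
        qf_cov = qf
    cov, logdet = posterior_covariance(qf_cov, d)
    Ephi, Ezphi, Ephiphi, Czphi = _moments_from_gaussian(z, cov, qf.params.linear)
    return LatentPosterior(z_map=z, d_omega=d, cov=cov, Ephi=Ephi,
                           Ezphi=Ezphi, Ephiphi=Ephiphi, Czphi=Czphi,
                           logdet_precision=logdet, n_flip_rounds=rounds,
                           converged=conv)


def expected_joint_loglik(params: PLRNNParams, obs_params, posterior,
                          data: TrajectoryData, rescale_sigma: bool = False,
                          stats=None) -> float:
    """E_q[log p(X, Z | theta)] under the Laplace posterior.

    With ``rescale_sigma`` the latent covariance Sigma is replaced by the
    identity for comparability across annealing steps.
    """
    from .mstep import accumulate_stats, expected_joint_loglik_from_stats
    if stats is None:
        stats = accumulate_stats(posterior, data, params, obs_params)
    p = params
    if rescale_sigma:
        p = PLRNNParams(mu0=params.mu0, A=params.A, W=params.W, C=params.C,
                        h=params.h, Sigma=np.ones(params.M), linear=params.linear)
    return expected_joint_loglik_from_stats(p, obs_params, stats)
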