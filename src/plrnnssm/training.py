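"""Stepwise annealed EM training protocol and baselines.

The annealing protocol runs: (0) random initialization biased toward stable
dynamics, (1) linear-SSM EM with Sigma = I, (2) PLRNN EM with Sigma = I,
(3) three PLRNN EM rounds with Sigma fixed at diag(10^-i) and the loading
matrix B frozen at its step-2 value (plus Gamma/J frozen in fMRI mode),
(4) a final posterior-covariance re-estimate with Sigma = I.  The random
baseline is a single PLRNN EM run with Sigma fixed at 1e-3; the LDS variant
runs the identical protocol with the identity in place of the ReLU.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .data import TrajectoryData
from .estep import assemble_quadratic, compute_posterior, LatentPosterior
from .model import PLRNNParams, generate
from .mstep import (SufficientStats, accumulate_stats,
                    expected_joint_loglik_from_stats, update_latent_params,
                    update_obs_params)
from .observation import ObsParamsBOLD, ObsParamsGaussian

__all__ = ["TrainingConfig", "FitResult", "init_random", "train_annealed",
           "train_random", "train_lds", "train"]


class TrainingError(RuntimeError):
    """Non-finite likelihood or unrecoverable numerical failure during EM."""


@dataclass
class TrainingConfig:
    M: int = 10
    anneal_sigma_levels: tuple = (1.0, 1e-1, 1e-2, 1e-3)
    fix_obs_from_step: int = 3         # annealing rounds freeze B (Algorithm step 3)
    fmri_mode: bool = False            # additionally freeze Gamma (and J)
    em_max_iter: int = 50
    em_tol: float = 1e-4
    lambda_reg: float = 0.0
    seed: int = 0
    protocol: str = "anneal"           # anneal | random | lds
    obs_model: str = "gaussian"        # gaussian | bold
    hrf_kernel: np.ndarray | None = None
    convolve_activation: bool = False
    random_sigma: float = 1e-3         # fixed Sigma for the random protocol
    stability_T: int = 10000
    divergence_threshold: float = 1e10

    def __post_init__(self):
        lv = tuple(self.anneal_sigma_levels)
        if any(b >= a for a, b in zip(lv, lv[1:])):
            raise ValueError("anneal sigma levels must be strictly decreasing")
        if self.em_tol <= 0:
            raise ValueError("em_tol must be > 0")


@dataclass
class FitResult:
    params: PLRNNParams
    obs_params: object
    posterior: LatentPosterior
    loglik_trace: list = field(default_factory=list)   # per step: list of ELBOs
    step_names: list = field(default_factory=list)
    step_snapshots: list = field(default_factory=list)  # per step: {"B","Gamma"}
    stability_flag: bool = False                        # True = globally unstable
    config: TrainingConfig | None = None
    seed: int = 0
    final_loglik: float = float("nan")

    @property
    def n_steps(self) -> int:
        return len(self.loglik_trace)


def init_random(M: int, N: int, K: int = 0, P: int = 0, seed: int = 0,
                obs_model: str = "gaussian", hrf_kernel=None,
                convolve_activation: bool = False,
                linear: bool = False):
    """Random initialization biased toward stable latent dynamics.

    A is uniform(0.5, 0.99) on the diagonal, W off-diagonal N(0, 0.01/M);
    the pair is rescaled until max|eig(A + W)| < 1.  B has random orthonormal
    rows (or columns, whichever fits); Sigma = Gamma = I.
    """
    rng = np.random.default_rng(seed)
    A = rng.uniform(0.5, 0.99, size=M)
    W = rng.normal(0.0, np.sqrt(0.01 / M), size=(M, M))
    np.fill_diagonal(W, 0.0)
    for _ in range(100):
        lam = np.max(np.abs(np.linalg.eigvals(np.diag(A) + W)))
        if lam < 1.0:
            break
        A = A * (0.95 / lam)
        W = W * (0.95 / lam)
    h = rng.normal(0.0, 0.1, size=M)
    C = rng.normal(0.0, 0.1, size=(M, K)) if K > 0 else np.zeros((M, 0))
    mu0 = rng.normal(0.0, 0.1, size=M)
    params = PLRNNParams(mu0=mu0, A=A, W=W, C=C, h=h, Sigma=np.ones(M),
                         linear=linear)
    Q = np.linalg.qr(rng.standard_normal((max(M, N), max(M, N))))[0]
    B = Q[:N, :M]
    if obs_model == "bold":
        kernel = np.ones(1) if hrf_kernel is None else np.asarray(hrf_kernel)
        obs = ObsParamsBOLD(B=B, J=np.zeros((N, P)), Gamma=np.ones(N),
                            hrf=kernel, convolve_activation=convolve_activation)
    else:
        obs = ObsParamsGaussian(B=B, Gamma=np.ones(N), linear=linear)
    return params, obs


def _clone_obs(obs, B=None, J=None, Gamma=None, linear=None):
    obs = copy.deepcopy(obs)
    if B is not None:
        obs.B = np.asarray(B, dtype=float)
    if Gamma is not None:
        obs.Gamma = np.asarray(Gamma, dtype=float)
    if isinstance(obs, ObsParamsGaussian):
        if linear is not None:
            obs.linear = bool(linear)
    elif J is not None:
        obs.J = np.asarray(J, dtype=float)
    return obs


def _with(params: PLRNNParams, Sigma=None, linear=None) -> PLRNNParams:
    return PLRNNParams(
        mu0=params.mu0, A=params.A, W=params.W, C=params.C, h=params.h,
        Sigma=params.Sigma if Sigma is None else np.broadcast_to(
            np.asarray(Sigma, dtype=float), (params.M,)).copy(),
        linear=params.linear if linear is None else bool(linear))


def _em_round(data: TrajectoryData, params: PLRNNParams, obs, cfg: TrainingConfig,
              sigma_fixed: np.ndarray, update_b: bool, update_gamma: bool,
              z_warm: np.ndarray | None):
    """One EM round with Sigma held fixed; returns updated state and ELBO trace."""
    trace = []
    best = (params, obs, z_warm)
    post = None
    prev_ll = -np.inf
    for it in range(cfg.em_max_iter):
        qf = assemble_quadratic(params, obs, data)
        post = compute_posterior(qf, z_warm)
        z_warm = post.z_map
        stats = accumulate_stats(post, data, params, obs)
        ll = expected_joint_loglik_from_stats(params, obs, stats) + post.entropy()
        if not np.isfinite(ll):
            raise TrainingError(f"non-finite likelihood at EM iteration {it}")
        trace.append(ll)
        scale = max(abs(prev_ll), 1.0)
        if ll < prev_ll - 1e-2 * scale and it > 0:
            # drop beyond Laplace tolerance: keep previous estimate, stop round
            params, obs, z_warm = best
            break
        best = (params, obs, z_warm)
        if it > 0 and abs(ll - prev_ll) < cfg.em_tol * scale:
            prev_ll = ll
            break
        prev_ll = ll
        # --- M-step ---
        if update_b:
            B, J, Gamma = update_obs_params(stats)
            obs = _clone_obs(obs, B=B, J=J if stats.P > 0 else None,
                             Gamma=Gamma if update_gamma else None)
        elif update_gamma:
            obs = _clone_obs(obs, Gamma=_gamma_given_B(stats, obs))
        params = update_latent_params(
            stats, lambda_reg=cfg.lambda_reg, update_sigma=False,
            linear=params.linear, sigma_fixed=sigma_fixed)
    return params, obs, z_warm, post, trace


def _gamma_given_B(stats: SufficientStats, obs) -> np.ndarray:
    """Gamma from the expected residual expression with B (and J) held fixed."""
    B = obs.B
    Q = stats.F2 - stats.H1 @ B.T - B @ stats.H1.T + B @ stats.H3 @ B.T
    if stats.P > 0:
        J = obs.J
        Q = (Q - stats.F7 @ J.T - J @ stats.F7.T + B @ stats.H2.T @ J.T
             + J @ stats.H2 @ B.T + J @ stats.F8 @ J.T)
    return np.maximum(np.diag(Q) / stats.T, 1e-8)


def _finalize(data, params, obs, z_warm, cfg, traces, names, seed,
              snapshots=None) -> FitResult:
    # Algorithm step 4: re-estimate state covariance with Sigma = I
    qf = assemble_quadratic(params, obs, data)
    post = compute_posterior(qf, z_warm, cov_params=_with(params, Sigma=1.0))
    stats = accumulate_stats(post, data, params, obs)
    final_ll = expected_joint_loglik_from_stats(params, obs, stats)
    Z, unstable = generate(params, cfg.stability_T, seed=seed, noise=True)
    return FitResult(params=params, obs_params=obs, posterior=post,
                     loglik_trace=traces, step_names=names,
                     step_snapshots=snapshots or [],
                     stability_flag=bool(unstable), config=cfg, seed=seed,
                     final_loglik=final_ll)


def _snap(obs) -> dict:
    snap = {"B": obs.B.copy(), "Gamma": obs.Gamma.copy()}
    if isinstance(obs, ObsParamsBOLD):
        snap["J"] = obs.J.copy()
    return snap


def train_annealed(data: TrajectoryData, config: TrainingConfig) -> FitResult:
    cfg = config
    params, obs = init_random(cfg.M, data.N, data.K, data.P, seed=cfg.seed,
                              obs_model=cfg.obs_model, hrf_kernel=cfg.hrf_kernel,
                              convolve_activation=cfg.convolve_activation)
    lds_params = _with(params, Sigma=1.0, linear=True)
    lds_obs = _clone_obs(obs, linear=True)
    traces, names, snaps = [], [], []
    z_warm = None

    # step 1: LDS initialization, Sigma = I
    lds_params, lds_obs, z_warm, _, tr = _em_round(
        data, lds_params, lds_obs, cfg, sigma_fixed=np.ones(cfg.M),
        update_b=True, update_gamma=True, z_warm=z_warm)
    traces.append(tr)
    names.append("1:lds")
    snaps.append(_snap(lds_obs))

    # step 2: PLRNN, Sigma = I
    params = _with(lds_params, linear=False)
    obs = _clone_obs(lds_obs, linear=False)
    params, obs, z_warm, _, tr = _em_round(
        data, params, obs, cfg, sigma_fixed=np.ones(cfg.M),
        update_b=True, update_gamma=True, z_warm=z_warm)
    traces.append(tr)
    names.append("2:plrnn")
    snaps.append(_snap(obs))
    B2 = obs.B.copy()
    Gamma2 = obs.Gamma.copy()

    # step 3: anneal Sigma down with B frozen
    for i, level in enumerate(cfg.anneal_sigma_levels[1:], start=1):
        params = _with(params, Sigma=level)
        update_gamma = not cfg.fmri_mode
        params, obs, z_warm, _, tr = _em_round(
            data, params, obs, cfg, sigma_fixed=np.full(cfg.M, level),
            update_b=False, update_gamma=update_gamma, z_warm=z_warm)
        traces.append(tr)
        names.append(f"3_{i}:anneal@{level:g}")
        snaps.append(_snap(obs))
    return _finalize(data, params, obs, z_warm, cfg, traces, names, cfg.seed,
                     snaps)


def train_random(data: TrajectoryData, config: TrainingConfig) -> FitResult:
    cfg = config
    params, obs = init_random(cfg.M, data.N, data.K, data.P, seed=cfg.seed,
                              obs_model=cfg.obs_model, hrf_kernel=cfg.hrf_kernel,
                              convolve_activation=cfg.convolve_activation)
    params = _with(params, Sigma=cfg.random_sigma)
    params, obs, z_warm, _, tr = _em_round(
        data, params, obs, cfg, sigma_fixed=np.full(cfg.M, cfg.random_sigma),
        update_b=True, update_gamma=True, z_warm=None)
    return _finalize(data, params, obs, z_warm, cfg, [tr], ["1:random"],
                     cfg.seed, [_snap(obs)])


def train_lds(data: TrajectoryData, config: TrainingConfig) -> FitResult:
    cfg = config
    params, obs = init_random(cfg.M, data.N, data.K, data.P, seed=cfg.seed,
                              obs_model=cfg.obs_model, hrf_kernel=cfg.hrf_kernel,
                              convolve_activation=cfg.convolve_activation,
                              linear=True)
    traces, names, snaps = [], [], []
    z_warm = None
    params = _with(params, Sigma=1.0, linear=True)
    params, obs, z_warm, _, tr = _em_round(
        data, params, obs, cfg, sigma_fixed=np.ones(cfg.M),
        update_b=True, update_gamma=True, z_warm=z_warm)
    traces.append(tr)
    names.append("1:lds")
    snaps.append(_snap(obs))
    params, obs, z_warm, _, tr = _em_round(
        data, params, obs, cfg, sigma_fixed=np.ones(cfg.M),
        update_b=True, update_gamma=True, z_warm=z_warm)
    traces.append(tr)
    names.append("2:lds")
    snaps.append(_snap(obs))
    for i, level in enumerate(cfg.anneal_sigma_levels[1:], start=1):
        params = _with(params, Sigma=level)
        params, obs, z_warm, _, tr = _em_round(
            data, params, obs, cfg, sigma_fixed=np.full(cfg.M, level),
            update_b=False, update_gamma=not cfg.fmri_mode, z_warm=z_warm)
        traces.append(tr)
        names.append(f"3_{i}:anneal@{level:g}")
        snaps.append(_snap(obs))
    return _finalize(data, params, obs, z_warm, cfg, traces, names, cfg.seed,
                     snaps)


def train(data: TrajectoryData, config: TrainingConfig) -> FitResult:
    fn = {"anneal": train_annealed, "random": train_random, "lds": train_lds}
    try:
        return fn[config.protocol](data, config)
    except KeyError:
        raise ValueError(f"unknown protocol {config.protocol!r}") from None
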