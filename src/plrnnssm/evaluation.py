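"""Reconstruction-quality measures defined across state space.

KL_x compares binned occupancy of observation space between true and
freely generated trajectories (attractor geometry, not time-series error);
KL_z compares the data-constrained posterior state mixture against the
free-running prior state mixture, either by Monte-Carlo sampling or by a
deterministic variational bound over pairwise Gaussian KLs.  Both are
normalized to [0, 1].  Also: n-step-ahead prediction MSE and power-spectrum
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import welch
from scipy.special import logsumexp

from .data import TrajectoryData
from .model import PLRNNParams, generate, latent_step
from .observation import emit

__all__ = [
    "HistogramSpec",
    "GaussianMixtureOverTime",
    "histogram_states",
    "kl_x",
    "klx_between_point_sets",
    "kl_z_mc",
    "kl_z_variational",
    "kl_z_normalized",
    "n_step_mse",
    "spectrum_correlation",
    "block_cycle_frequency",
    "inferred_mixture",
    "generated_mixture",
    "generated_observations",
]

#: normalized-KL success threshold for benchmark reconstruction
KLX_SUCCESS_THRESHOLD = 0.4


@dataclass(frozen=True)
class HistogramSpec:
    """Binned state-space occupancy grid with Laplace smoothing."""

    dim: int
    bin_width: float = 1.0
    low: float = -4.0
    high: float = 4.0
    alpha: float = 1e-6

    def __post_init__(self):
        if self.bin_width <= 0 or self.alpha <= 0 or self.high <= self.low:
            raise ValueError("invalid histogram spec")

    @property
    def n_per_dim(self) -> int:
        return int(round((self.high - self.low) / self.bin_width))

    @property
    def K(self) -> int:
        return self.n_per_dim ** self.dim

    @property
    def edges(self) -> np.ndarray:
        return self.low + self.bin_width * np.arange(self.n_per_dim + 1)


def histogram_states(points: np.ndarray, spec: HistogramSpec,
                     alpha: float | None = None):
    """Laplace-smoothed occupancy probabilities over the K-bin grid.

    Out-of-range points are clipped to the edge bins so both distributions
    stay normalized over the same support.  Returns (probs, T).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    points = points[np.all(np.isfinite(points), axis=1)]
    if points.shape[0] == 0:
        raise ValueError("empty point set")
    if points.shape[1] != spec.dim:
        raise ValueError("dimension mismatch with histogram spec")
    a = spec.alpha if alpha is None else alpha
    n = spec.n_per_dim
    idxf = np.floor((points - spec.low) / spec.bin_width)
    idx = np.clip(idxf, 0, n - 1).astype(int)
    flat = np.ravel_multi_index(idx.T, (n,) * spec.dim)
    counts = np.bincount(flat, minlength=spec.K).astype(float)
    T = points.shape[0]
    probs = (counts + a) / (T + a * spec.K)
    return probs, T


def kl_x(p_true: np.ndarray, p_gen: np.ndarray, spec: HistogramSpec,
         T_gen: int, normalizer: str = "uniform") -> tuple[float, float]:
    """Raw binned KL (nats) and its normalized version in [0, 1].

    Two readings of the "expected maximum deviation" normalizer KL_max:

    * ``uniform`` (default): divergence of the truth from a structureless
      (uniform-occupancy) generated distribution, sum p_true log(p_true K).
      A generated system carrying no spatial information scores ~1; mass
      fully disjoint from the truth exceeds KL_max and is clipped to 1.
    * ``disjoint``: divergence attained when the generated mass shares no
      occupied bin with the truth, sum p_true log(p_true / p_floor) with
      p_floor = alpha / (T_gen + alpha K).  A much larger constant; only
      fully disjoint geometries approach 1.
    """
    if p_true.shape != p_gen.shape:
        raise ValueError("mismatched histogram specs")
    mask = p_true > 0
    raw = float(np.sum(p_true[mask] * np.log(p_true[mask] / p_gen[mask])))
    if normalizer == "disjoint":
        p_floor = spec.alpha / (T_gen + spec.alpha * spec.K)
        kl_max = float(np.sum(p_true[mask] * np.log(p_true[mask] / p_floor)))
    else:
        kl_max = float(np.sum(p_true[mask] * np.log(p_true[mask] * spec.K)))
    norm = float(np.clip(raw / kl_max, 0.0, 1.0)) if kl_max > 0 else 0.0
    return raw, norm


def klx_between_point_sets(true_points: np.ndarray, gen_points: np.ndarray,
                           spec: HistogramSpec | None = None,
                           normalizer: str = "uniform"):
    """Convenience: histogram both point sets and return (raw, normalized)."""
    if spec is None:
        spec = HistogramSpec(dim=true_points.shape[1])
    p_true, _ = histogram_states(true_points, spec)
    p_gen, T_gen = histogram_states(gen_points, spec)
    return kl_x(p_true, p_gen, spec, T_gen, normalizer=normalizer)


def generated_observations(fit, T_gen: int = 100_000, seed: int = 0,
                           noise: bool = False) -> tuple[np.ndarray, bool]:
    """Free-run a fitted model and emit observations for geometry measures.

    The run is noise-free by default (the occupancy measure characterizes
    the learned *deterministic* flow; process noise would smear degenerate
    dynamics over state space) and starts from the last inferred state, i.e.
    on the learned attractor.  Nuisance channels are recording artifacts, so
    the generated signal uses zero nuisance input.
    """
    z1 = fit.posterior.z_map[-1]
    Z, unstable = generate(fit.params, T_gen, seed=seed, noise=noise, z1=z1)
    obs = fit.obs_params
    R = np.zeros((T_gen, obs.P)) if getattr(obs, "P", 0) > 0 else None
    X = emit(obs, Z, R=R, noise=None)
    return X, unstable


@dataclass
class GaussianMixtureOverTime:
    """Equal-weight Gaussian mixture with one component per time point."""

    means: np.ndarray        # (T, M)
    covs: np.ndarray         # (T, M, M) or (M, M) shared
    side: str = "inferred"

    @property
    def n(self) -> int:
        return self.means.shape[0]

    @property
    def M(self) -> int:
        return self.means.shape[1]

    def cov_at(self, i: int) -> np.ndarray:
        return self.covs if self.covs.ndim == 2 else self.covs[i]


def inferred_mixture(fit, var_floor: float = 1.0) -> GaussianMixtureOverTime:
    """Posterior state mixture p_inf(z|x): one component per time point.

    Marginal covariances come from the Sigma = I re-estimated posterior with
    diagonal elements floored at ``var_floor``.
    """
    post = fit.posterior
    covs = post.cov[0].copy()
    ii = np.arange(post.M)
    covs[:, ii, ii] = np.maximum(covs[:, ii, ii], var_floor)
    return GaussianMixtureOverTime(means=post.z_map.copy(), covs=covs,
                                   side="inferred")


def generated_mixture(fit, L: int | None = None,
                      seed: int = 0) -> GaussianMixtureOverTime:
    """Prior state mixture p_gen(z): components p(z_t | z_{t-1}) along a
    free-running trajectory.

    Component covariance is the model's process-noise matrix Sigma, i.e.
    exactly Var(z_t | z_{t-1}) of the generative model.
    """
    params = fit.params
    L = fit.posterior.T if L is None else L
    Z, _ = generate(params, L + 1, seed=seed, noise=True,
                    z1=fit.posterior.z_map[-1])
    means = latent_step(params, Z[:-1])  # deterministic one-step map
    covs = np.diag(params.Sigma)
    return GaussianMixtureOverTime(means=means, covs=covs, side="generated")


def _chol_cache(mix: GaussianMixtureOverTime):
    if mix.covs.ndim == 2:
        c = np.linalg.cholesky(mix.covs)
        return c[None, ...], True
    return np.linalg.cholesky(mix.covs), False


def _mixture_logpdf(points: np.ndarray, mix: GaussianMixtureOverTime,
                    chunk: int = 2000) -> np.ndarray:
    """log of mixture density at each point, (n_points,)."""
    n, M = points.shape
    chols, shared = _chol_cache(mix)
    T = mix.n
    const = -0.5 * M * np.log(2 * np.pi)
    out = np.empty(n)
    with np.errstate(over="ignore"):
        if shared:
            c = chols[0]
            ld = np.sum(np.log(np.diag(c)))
            cinv = np.linalg.inv(c)
            for s in range(0, n, chunk):
                pts = points[s:s + chunk]
                diff = pts[None, :, :] - mix.means[:, None, :]  # (T, nc, M)
                sol = np.einsum("ab,tnb->tna", cinv, diff)
                maha = np.sum(sol ** 2, axis=2)
                out[s:s + chunk] = logsumexp(const - ld - 0.5 * maha,
                                             axis=0) - np.log(T)
            return out
        lds = np.array([np.sum(np.log(np.diag(chols[t]))) for t in range(T)])
        cinvs = np.linalg.inv(chols)
        for s in range(0, n, chunk):
            pts = points[s:s + chunk]
            diff = pts[None, :, :] - mix.means[:, None, :]      # (T, nc, M)
            sol = np.einsum("tab,tnb->tna", cinvs, diff)
            maha = np.sum(sol ** 2, axis=2)
            out[s:s + chunk] = logsumexp(
                const - lds[:, None] - 0.5 * maha, axis=0) - np.log(T)
    return out


def kl_z_mc(p_inf: GaussianMixtureOverTime, p_gen: GaussianMixtureOverTime,
            n_samples: int = 500_000, seed: int = 0) -> float:
    """Monte-Carlo KL(p_inf || p_gen): samples drawn from p_inf."""
    rng = np.random.default_rng(seed)
    T, M = p_inf.n, p_inf.M
    comp = rng.integers(0, T, size=n_samples)
    chols, shared = _chol_cache(p_inf)
    eps = rng.standard_normal((n_samples, M))
    if shared:
        pts = p_inf.means[comp] + eps @ chols[0].T
    else:
        pts = p_inf.means[comp] + np.einsum("nij,nj->ni", chols[comp], eps)
    return float(np.mean(_mixture_logpdf(pts, p_inf) - _mixture_logpdf(pts, p_gen)))


def _pairwise_gauss_kl(mix_a: GaussianMixtureOverTime,
                       mix_b: GaussianMixtureOverTime) -> np.ndarray:
    """KL(N_i^a || N_j^b) for all component pairs, (n_a, n_b)."""
    M = mix_a.M
    na, nb = mix_a.n, mix_b.n
    covs_a = mix_a.covs if mix_a.covs.ndim == 3 else mix_a.covs[None, ...]
    covs_b = mix_b.covs if mix_b.covs.ndim == 3 else mix_b.covs[None, ...]
    inv_b = np.linalg.inv(covs_b)
    _, ld_a = np.linalg.slogdet(covs_a)
    _, ld_b = np.linalg.slogdet(covs_b)
    ld_a = np.broadcast_to(ld_a, (na,)) if ld_a.size == 1 else ld_a
    ld_b = np.broadcast_to(ld_b, (nb,)) if ld_b.size == 1 else ld_b
    # trace(inv_b @ cov_a) for all pairs
    tr = np.einsum("jab,iab->ij", inv_b, covs_a)
    tr = np.broadcast_to(tr, (na, nb)) if tr.shape != (na, nb) else tr
    diff = mix_a.means[:, None, :] - mix_b.means[None, :, :]   # (na, nb, M)
    if inv_b.shape[0] == 1:
        maha = np.einsum("ija,ab,ijb->ij", diff, inv_b[0], diff)
    else:
        maha = np.einsum("ija,jab,ijb->ij", diff, inv_b, diff)
    return 0.5 * (tr + maha - M + ld_b[None, :] - ld_a[:, None])


def kl_z_variational(p_inf: GaussianMixtureOverTime,
                     p_gen: GaussianMixtureOverTime) -> float:
    """Deterministic variational approximation of KL(p_inf || p_gen)."""
    kl_ii = _pairwise_gauss_kl(p_inf, p_inf)
    kl_ig = _pairwise_gauss_kl(p_inf, p_gen)
    num = logsumexp(-kl_ii, axis=1) - np.log(p_inf.n)
    den = logsumexp(-kl_ig, axis=1) - np.log(p_gen.n)
    return float(np.mean(num - den))


def _reference_gaussian(p_gen: GaussianMixtureOverTime) -> GaussianMixtureOverTime:
    """Single Gaussian with the time-averaged generated mean and total variance."""
    mu = p_gen.means.mean(axis=0)
    covs = p_gen.covs if p_gen.covs.ndim == 3 else p_gen.covs[None, ...]
    within = covs.mean(axis=0)
    between = np.cov(p_gen.means.T, bias=True)
    between = np.atleast_2d(between)
    return GaussianMixtureOverTime(means=mu[None, :], covs=within + between,
                                   side="reference")


def kl_z_normalized(p_inf: GaussianMixtureOverTime,
                    p_gen: GaussianMixtureOverTime,
                    estimator: str = "variational",
                    n_samples: int = 500_000, seed: int = 0) -> float:
    """KL(p_inf || p_gen) divided by KL(p_inf || p_ref), clipped to [0, 1]."""
    p_ref = _reference_gaussian(p_gen)
    if estimator == "mc":
        num = kl_z_mc(p_inf, p_gen, n_samples=n_samples, seed=seed)
        den = kl_z_mc(p_inf, p_ref, n_samples=n_samples, seed=seed + 1)
    else:
        num = kl_z_variational(p_inf, p_gen)
        den = kl_z_variational(p_inf, p_ref)
    if abs(den) < 1e-12:
        raise ValueError("degenerate reference KL; normalized measure undefined")
    return float(np.clip(num / den, 0.0, 1.0))


def n_step_mse(fit, data: TrajectoryData, horizon: int) -> np.ndarray:
    """Mean squared n-step-ahead prediction error of observations.

    From each origin t the latent model is run deterministically ``horizon``
    steps from the inferred state and emitted through the observation model;
    errors are averaged over origins and channels per step.
    """
    from .observation import ObsParamsBOLD
    T = data.T
    if horizon >= T:
        raise ValueError("horizon must be < T")
    params = fit.params
    z_inf = fit.posterior.z_map
    n_origin = T - horizon
    z = z_inf[:n_origin].copy()                       # state at each origin t0
    preds = []                                        # predicted states per step
    for step in range(1, horizon + 1):
        s_t = data.S[step:step + n_origin] if data.K > 0 else None
        z = latent_step(params, z, s_t)
        preds.append(z.copy())
    obs = fit.obs_params
    bold = isinstance(obs, ObsParamsBOLD)
    kernel = obs.kernel if bold else np.ones(1)
    sq = np.zeros(horizon)
    origins = np.arange(n_origin)                     # origin t0 (0-based)
    for step in range(1, horizon + 1):
        if bold:
            # convolve predicted future with the inferred past at each origin
            conv = np.zeros((n_origin, params.M))
            for lag, k in enumerate(kernel):
                rel = step - lag                      # time t0+rel relative to origin
                if rel >= 1:
                    src = preds[rel - 1]
                elif rel <= 0:
                    tidx = origins + rel
                    valid = tidx >= 0
                    src = np.zeros((n_origin, params.M))
                    src[valid] = z_inf[tidx[valid]]
                if obs.convolve_activation:
                    src = np.maximum(src, 0.0)
                conv += k * src
            X_hat = conv @ obs.B.T
            if obs.P > 0 and data.P > 0:
                X_hat = X_hat + data.R[step:step + n_origin] @ obs.J.T
        else:
            X_hat = emit(obs, preds[step - 1], R=None, noise=None)
        resid = data.X[step:step + n_origin] - X_hat
        sq[step - 1] = np.mean(resid ** 2)
    return sq


def spectrum_correlation(traj_a: np.ndarray, traj_b: np.ndarray,
                         fs: float = 1.0) -> float:
    """Average Pearson correlation of Welch power spectra across dimensions."""
    a = np.atleast_2d(np.asarray(traj_a, dtype=float))
    b = np.atleast_2d(np.asarray(traj_b, dtype=float))
    if a.shape[0] < 64 or b.shape[0] < 64:
        raise ValueError("need at least 64 samples for spectral comparison")
    if a.shape[1] != b.shape[1]:
        raise ValueError("dimension mismatch")
    nseg = min(256, a.shape[0], b.shape[0])
    rs = []
    for d in range(a.shape[1]):
        _, pa = welch(a[:, d] - a[:, d].mean(), fs=fs, nperseg=nseg)
        _, pb = welch(b[:, d] - b[:, d].mean(), fs=fs, nperseg=nseg)
        if pa.std() == 0 or pb.std() == 0:
            rs.append(0.0)
            continue
        rs.append(float(np.corrcoef(pa, pb)[0, 1]))
    return float(np.mean(rs))


def block_cycle_frequency(*durations_s: float, decimals: int = 4) -> float:
    """Reciprocal of the summed block durations (Hz), rounded."""
    period = float(np.sum(durations_s))
    if period <= 0:
        raise ValueError("period must be positive")
    return round(1.0 / period, decimals)
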