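"""Latent piecewise-linear RNN process model and dynamical-systems analysis.

The latent dynamics are

    z_t = A z_{t-1} + W phi(z_{t-1}) + h + C s_t + eps_t,   eps_t ~ N(0, Sigma)
    z_1 ~ N(mu0 + C s_1, Sigma)

with A diagonal, W zero-diagonal and phi the elementwise ReLU (identity for
the linear/LDS variant).  Because the map is piecewise affine, fixed points
can be enumerated exactly over the 2^M linear regions, and attractors are
characterized by free-running simulation plus a log-distance Lyapunov slope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "PLRNNParams",
    "FixedPoint",
    "DynamicalObjectReport",
    "relu",
    "latent_step",
    "generate",
    "enumerate_fixed_points",
    "classify_attractors",
    "lyapunov_exponent",
]

#: |z| beyond this marks a free-running trajectory as globally unstable
DIVERGENCE_THRESHOLD = 1e10


@dataclass
class PLRNNParams:
    """Latent-model parameters {mu0, A, W, C, h, Sigma} (+ linear flag)."""

    mu0: np.ndarray          # (M,)
    A: np.ndarray            # (M,) diagonal auto-regression weights
    W: np.ndarray            # (M, M), zero diagonal
    C: np.ndarray            # (M, K); K may be 0
    h: np.ndarray            # (M,)
    Sigma: np.ndarray        # (M,) diagonal process-noise variances
    linear: bool = False     # phi = identity (LDS variant) when True

    def __post_init__(self):
        self.mu0 = np.atleast_1d(np.asarray(self.mu0, dtype=float))
        self.A = np.atleast_1d(np.asarray(self.A, dtype=float))
        self.W = np.atleast_2d(np.asarray(self.W, dtype=float))
        self.C = np.asarray(self.C, dtype=float).reshape(self.M, -1)
        self.h = np.atleast_1d(np.asarray(self.h, dtype=float))
        self.Sigma = np.atleast_1d(np.asarray(self.Sigma, dtype=float))
        self.validate()

    @property
    def M(self) -> int:
        return self.A.shape[0]

    @property
    def K(self) -> int:
        return self.C.shape[1]

    def validate(self):
        M = self.M
        if self.W.shape != (M, M):
            raise ValueError("W must be (M, M)")
        if np.any(np.diag(self.W) != 0.0):
            raise ValueError("diag(W) must be exactly zero")
        for name in ("mu0", "h", "Sigma"):
            if getattr(self, name).shape != (M,):
                raise ValueError(f"{name} must have shape (M,)")
        if np.any(self.Sigma <= 0):
            raise ValueError("Sigma must be positive elementwise")

    def phi(self, z: np.ndarray) -> np.ndarray:
        return z if self.linear else np.maximum(z, 0.0)

    def to_dict(self) -> dict:
        return {
            "mu0": self.mu0.tolist(), "A": self.A.tolist(),
            "W": self.W.tolist(), "C": self.C.tolist(),
            "h": self.h.tolist(), "Sigma": self.Sigma.tolist(),
            "linear": self.linear,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PLRNNParams":
        return cls(mu0=np.array(d["mu0"]), A=np.array(d["A"]),
                   W=np.array(d["W"]), C=np.array(d["C"]),
                   h=np.array(d["h"]), Sigma=np.array(d["Sigma"]),
                   linear=bool(d.get("linear", False)))

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "PLRNNParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def relu(z: np.ndarray, linear: bool = False) -> np.ndarray:
    """Elementwise max(z, 0); identity in the linear (LDS) variant."""
    z = np.asarray(z, dtype=float)
    return z if linear else np.maximum(z, 0.0)


def latent_step(params: PLRNNParams, z_prev: np.ndarray,
                s_t: np.ndarray | None = None,
                noise: np.ndarray | None = None) -> np.ndarray:
    """One step of the latent map.  Supports batched z_prev (..., M)."""
    z_prev = np.asarray(z_prev, dtype=float)
    out = params.A * z_prev + params.phi(z_prev) @ params.W.T + params.h
    if s_t is not None and params.K > 0:
        out = out + np.asarray(s_t, dtype=float) @ params.C.T
    if noise is not None:
        out = out + noise
    return out


def generate(params: PLRNNParams, T: int, inputs: np.ndarray | None = None,
             seed: int | None = None, z1: np.ndarray | None = None,
             noise: bool = True) -> tuple[np.ndarray, bool]:
    """Free-running generation of a (T, M) latent trajectory.

    Returns ``(Z, unstable)`` where ``unstable`` flags any |z| exceeding the
    divergence threshold (the run is retained).  With ``noise=False`` (or
    Sigma treated as zero) and a supplied ``z1`` the output is deterministic.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    M = params.M
    rng = np.random.default_rng(seed)
    sd = np.sqrt(params.Sigma) if noise else np.zeros(M)
    S = None
    if inputs is not None and params.K > 0:
        S = np.asarray(inputs, dtype=float).reshape(T, params.K)
    if z1 is None:
        z = params.mu0.copy()
        if S is not None:
            z = z + params.C @ S[0]
        z = z + sd * rng.standard_normal(M)
    else:
        z = np.asarray(z1, dtype=float).copy()
    Z = np.empty((T, M))
    Z[0] = z
    unstable = False
    with np.errstate(over="ignore", invalid="ignore"):
        for t in range(1, T):
            eps = sd * rng.standard_normal(M) if noise else None
            s_t = S[t] if S is not None else None
            z = latent_step(params, z, s_t, eps)
            if not np.all(np.isfinite(z)):
                z = np.nan_to_num(z, nan=0.0, posinf=DIVERGENCE_THRESHOLD,
                                  neginf=-DIVERGENCE_THRESHOLD)
                unstable = True
            Z[t] = z
    if np.nanmax(np.abs(Z)) > DIVERGENCE_THRESHOLD:
        unstable = True
    return Z, unstable


def _generate_batch(params: PLRNNParams, z0: np.ndarray, T: int) -> np.ndarray:
    """Deterministic batched generation from (n, M) initial states -> (T, n, M)."""
    n, M = z0.shape
    Z = np.empty((T, n, M))
    z = z0.astype(float)
    Z[0] = z
    with np.errstate(over="ignore", invalid="ignore"):
        for t in range(1, T):
            z = latent_step(params, z, None, None)
            z = np.nan_to_num(z, nan=np.inf, posinf=np.inf, neginf=-np.inf)
            z = np.clip(z, -1e15, 1e15)
            Z[t] = z
    return Z


@dataclass
class FixedPoint:
    location: np.ndarray
    region: np.ndarray       # boolean active-region indicator d (z > 0)
    stable: bool
    max_abs_eig: float


@dataclass
class DynamicalObjectReport:
    fixed_points: list = field(default_factory=list)
    n_stable_fp: int = 0
    n_unstable_fp: int = 0
    n_limit_cycles: int = 0
    n_chaotic: int = 0
    n_unstable_runs: int = 0
    lyapunov_estimates: list = field(default_factory=list)
    skipped_regions: int = 0

    def to_dict(self) -> dict:
        return {
            "fixed_points": [
                {"location": fp.location.tolist(), "region": fp.region.astype(int).tolist(),
                 "stable": bool(fp.stable), "max_abs_eig": float(fp.max_abs_eig)}
                for fp in self.fixed_points
            ],
            "n_stable_fp": self.n_stable_fp,
            "n_unstable_fp": self.n_unstable_fp,
            "n_limit_cycles": self.n_limit_cycles,
            "n_chaotic": self.n_chaotic,
            "n_unstable_runs": self.n_unstable_runs,
            "lyapunov_estimates": [float(x) for x in self.lyapunov_estimates],
            "skipped_regions": self.skipped_regions,
        }


def enumerate_fixed_points(params: PLRNNParams, tol: float = 1e-9) -> DynamicalObjectReport:
    """Exact fixed-point census: solve z* = (I - A - W D)^-1 h per region.

    A candidate is accepted iff its sign pattern matches the region that
    produced it (strict ``z > 0`` defines the active region).  Stability via
    max |eig(A + W D)| < 1.  Duplicates on region boundaries are merged.
    """
    M = params.M
    if M > 20:
        raise ValueError("fixed-point enumeration guarded at M <= 20")
    report = DynamicalObjectReport()
    A = np.diag(params.A)
    I = np.eye(M)
    regions = [np.ones(M, dtype=bool)] if params.linear else [
        np.array([(i >> m) & 1 for m in range(M)], dtype=bool)
        for i in range(2 ** M)
    ]
    seen: list[np.ndarray] = []
    for d in regions:
        D = np.diag(d.astype(float))
        J = A + params.W @ D
        try:
            z = np.linalg.solve(I - J, params.h)
        except np.linalg.LinAlgError:
            report.skipped_regions += 1
            continue
        if not np.all(np.isfinite(z)):
            report.skipped_regions += 1
            continue
        if not params.linear:
            ok = np.all((z > 0) == d) or np.all(
                np.where(np.abs(z) < tol, True, (z > 0) == d))
            if not ok:
                continue
        if any(np.allclose(z, p, atol=10 * tol) for p in seen):
            continue
        seen.append(z)
        eigs = np.abs(np.linalg.eigvals(J))
        stable = bool(eigs.max() <= 1.0)
        report.fixed_points.append(FixedPoint(z, d.copy(), stable, float(eigs.max())))
    report.n_stable_fp = sum(fp.stable for fp in report.fixed_points)
    report.n_unstable_fp = len(report.fixed_points) - report.n_stable_fp
    return report


def _attractor_point_set(Z: np.ndarray, n_tail: int | None = None) -> np.ndarray:
    n_tail = min(500, len(Z) // 4) if n_tail is None else n_tail
    tail = Z[-max(n_tail, 2):]
    return tail[np.all(np.isfinite(tail), axis=1) & (np.abs(tail).max(axis=1) < 1e9)]


def _same_attractor(a: np.ndarray, b: np.ndarray, tol: float = 0.1) -> bool:
    """Nearest-neighbour proximity of late-time point sets (merge rule).

    Subsampled points of each set are matched against the *full* other set so
    the rule is insensitive to sampling phase along a cycle.
    """
    if len(a) == 0 or len(b) == 0:
        return len(a) == len(b)
    sub_a = a[:: max(1, len(a) // 100)]
    sub_b = b[:: max(1, len(b) // 100)]
    d_a = np.sqrt(((sub_a[:, None, :] - b[None, :, :]) ** 2).sum(-1)).min(1)
    d_b = np.sqrt(((sub_b[:, None, :] - a[None, :, :]) ** 2).sum(-1)).min(1)
    return float(max(d_a.max(), d_b.max())) < tol


def lyapunov_exponent(step_fn: Callable[[np.ndarray], np.ndarray],
                      z_refs: np.ndarray, d0: float = 1e-12,
                      T_max: int = 2000, dt: float = 1.0,
                      plateau_frac: float = 0.9) -> tuple[float, dict]:
    """Maximal Lyapunov exponent from log-distance growth of close pairs.

    ``step_fn`` maps a batch (n, D) of states one step forward; ``z_refs``
    is an (n_pairs, D) array of on-attractor reference points, each perturbed
    by ``d0`` in a random direction.  The averaged log-distance curve is fit
    by linear regression over the pre-plateau segment (up to where the curve
    first reaches ``plateau_frac`` of its asymptotic median).  The returned
    slope is per unit time (per step divided by ``dt``).
    """
    z_refs = np.atleast_2d(np.asarray(z_refs, dtype=float))
    n, D = z_refs.shape
    rng = np.random.default_rng(0)
    direc = rng.standard_normal((n, D))
    direc /= np.linalg.norm(direc, axis=1, keepdims=True)
    a = z_refs.copy()
    b = z_refs + d0 * direc
    logd = np.empty((T_max, n))
    logd[0] = np.log(np.linalg.norm(a - b, axis=1))
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        for t in range(1, T_max):
            a = step_fn(a)
            b = step_fn(b)
            logd[t] = np.log(np.linalg.norm(a - b, axis=1))
    logd = np.where(np.isfinite(logd), logd, np.nan)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        curve = np.nanmean(logd, axis=1)
    valid = np.isfinite(curve)
    if valid.sum() < 10:
        return 0.0, {"converged": False, "low_confidence": True, "n_fit": 0}
    curve = curve[valid]
    # plateau level from the last quarter of the curve
    plateau = np.nanmedian(curve[3 * len(curve) // 4:])
    span = plateau - curve[0]
    low_conf = False
    if span <= 0:
        # no growth: fit whole curve, report (likely negative) slope
        cutoff = len(curve)
        low_conf = True
    else:
        target = curve[0] + plateau_frac * span
        above = np.nonzero(curve >= target)[0]
        cutoff = int(above[0]) + 1 if len(above) else len(curve)
        cutoff = max(cutoff, 5)
    lags = np.arange(cutoff)
    slope = float(np.polyfit(lags, curve[:cutoff], 1)[0]) / dt
    if slope <= 0:
        low_conf = True
    return slope, {"converged": True, "low_confidence": low_conf,
                   "n_fit": int(cutoff), "plateau": float(plateau)}


def classify_attractors(params: PLRNNParams, n_init: int = 100,
                        T_run: int = 5000, seed: int = 0,
                        init_scale: float = 5.0,
                        merge_tol: float = 0.1,
                        chaos_threshold: float = 3e-3) -> DynamicalObjectReport:
    """Free-running attractor census from random initial conditions.

    Noise-free generation from ``n_init`` random starts for ``T_run`` steps;
    converged non-fixed-point recurrent patterns are classified chaotic if
    their log-distance slope is positive, limit cycle otherwise.  Distinct
    attractors are merged by late-time point-set proximity; diverging runs
    are counted separately.
    """
    report = enumerate_fixed_points(params) if params.M <= 20 else DynamicalObjectReport()
    rng = np.random.default_rng(seed)
    z0 = rng.uniform(-init_scale, init_scale, size=(n_init, params.M))
    Z = _generate_batch(params, z0, T_run)            # (T, n, M)
    fp_locs = [fp.location for fp in report.fixed_points if fp.stable]
    attractor_sets: list[np.ndarray] = []
    attractor_reps: list[np.ndarray] = []
    for i in range(n_init):
        traj = Z[:, i, :]
        if np.abs(traj[-1]).max() > DIVERGENCE_THRESHOLD or not np.all(
                np.isfinite(traj[-1])):
            report.n_unstable_runs += 1
            continue
        tail = _attractor_point_set(traj)
        if len(tail) == 0:
            report.n_unstable_runs += 1
            continue
        extent = tail.max(axis=0) - tail.min(axis=0)
        if np.all(extent < 1e-6):
            continue  # converged to a fixed point (already censused exactly)
        if any(_same_attractor(tail, s, merge_tol) for s in attractor_sets):
            continue
        attractor_sets.append(tail)
        attractor_reps.append(traj[-1])
    for rep, tail in zip(attractor_reps, attractor_sets):
        refs = tail[rng.choice(len(tail), size=min(20, len(tail)), replace=False)]
        slope, diag = lyapunov_exponent(
            lambda zz: latent_step(params, zz), refs, d0=1e-12,
            T_max=min(T_run, 1000))
        report.lyapunov_estimates.append(slope)
        if slope > chaos_threshold and not diag["low_confidence"]:
            report.n_chaotic += 1
        else:
            report.n_limit_cycles += 1
    # unused variable kept out; fp census already exact
    del fp_locs
    return report
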