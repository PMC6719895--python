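"""Observation (decoder) models mapping latent states to measurements.

Two variants:

* Gaussian-linear:      x_t = B phi(z_t) + eta_t
* BOLD (HRF-convolved): x_t = B (hrf * z)_t + J r_t + eta_t

The BOLD variant convolves the *raw* latent states with a causal HRF kernel
(zero-padded before t=1); a config switch allows convolving phi(z) instead.
The stacked convolution operator H is strictly causal and lower block-banded
with bandwidth equal to the kernel length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gamma as gamma_dist

__all__ = [
    "ObsParamsGaussian",
    "ObsParamsBOLD",
    "HRFConvolutionOperator",
    "canonical_hrf",
    "build_hrf_operator",
    "emit",
]


@dataclass
class ObsParamsGaussian:
    """Gaussian-linear observation parameters {B, Gamma}."""

    B: np.ndarray        # (N, M)
    Gamma: np.ndarray    # (N,) diagonal observation-noise variances
    linear: bool = False  # x = B z instead of B phi(z) (LDS variant)

    def __post_init__(self):
        self.B = np.atleast_2d(np.asarray(self.B, dtype=float))
        self.Gamma = np.atleast_1d(np.asarray(self.Gamma, dtype=float))
        if np.any(self.Gamma <= 0):
            raise ValueError("Gamma must be positive elementwise")
        if self.Gamma.shape[0] != self.B.shape[0]:
            raise ValueError("Gamma length must match rows of B")

    @property
    def N(self) -> int:
        return self.B.shape[0]

    @property
    def M(self) -> int:
        return self.B.shape[1]

    @property
    def kernel(self) -> np.ndarray:
        return np.ones(1)  # delta kernel: identity convolution

    def to_dict(self) -> dict:
        return {"kind": "gaussian", "B": self.B.tolist(),
                "Gamma": self.Gamma.tolist(), "linear": self.linear}


@dataclass
class ObsParamsBOLD:
    """HRF-convolved observation parameters {B, J, Gamma, hrf kernel}."""

    B: np.ndarray            # (N, M)
    J: np.ndarray            # (N, P); P may be 0
    Gamma: np.ndarray        # (N,)
    hrf: np.ndarray          # (L,) causal kernel, hrf[0] applies to z_t
    convolve_activation: bool = False  # convolve phi(z) instead of raw z

    def __post_init__(self):
        self.B = np.atleast_2d(np.asarray(self.B, dtype=float))
        self.J = np.asarray(self.J, dtype=float).reshape(self.B.shape[0], -1)
        self.Gamma = np.atleast_1d(np.asarray(self.Gamma, dtype=float))
        self.hrf = np.atleast_1d(np.asarray(self.hrf, dtype=float))
        if np.any(self.Gamma <= 0):
            raise ValueError("Gamma must be positive elementwise")
        if self.hrf.size < 1 or not np.all(np.isfinite(self.hrf)):
            raise ValueError("kernel must be finite with length >= 1")

    @property
    def N(self) -> int:
        return self.B.shape[0]

    @property
    def M(self) -> int:
        return self.B.shape[1]

    @property
    def P(self) -> int:
        return self.J.shape[1]

    @property
    def kernel(self) -> np.ndarray:
        return self.hrf

    def to_dict(self) -> dict:
        return {"kind": "bold", "B": self.B.tolist(), "J": self.J.tolist(),
                "Gamma": self.Gamma.tolist(), "hrf": self.hrf.tolist(),
                "convolve_activation": self.convolve_activation}


def obs_params_from_dict(d: dict):
    if d["kind"] == "gaussian":
        return ObsParamsGaussian(B=np.array(d["B"]), Gamma=np.array(d["Gamma"]),
                                 linear=bool(d.get("linear", False)))
    return ObsParamsBOLD(B=np.array(d["B"]), J=np.array(d["J"]),
                         Gamma=np.array(d["Gamma"]), hrf=np.array(d["hrf"]),
                         convolve_activation=bool(d.get("convolve_activation", False)))


def canonical_hrf(sampling_interval: float, duration: float = 32.0,
                  peak_delay: float = 6.0, undershoot_delay: float = 16.0,
                  peak_disp: float = 1.0, undershoot_disp: float = 1.0,
                  ratio: float = 6.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at ``sampling_interval`` seconds.

    Peak around 5 s, undershoot around 15 s, peak/undershoot ratio 6 (SPM
    convention); peak-normalized to 1.  ``duration`` equal to one sample
    yields the delta kernel [1].
    """
    if sampling_interval <= 0 or duration <= 0:
        raise ValueError("sampling_interval and duration must be > 0")
    L = max(1, int(round(duration / sampling_interval)))
    if L == 1:
        return np.ones(1)
    t = np.arange(L) * sampling_interval
    k = (gamma_dist.pdf(t, peak_delay / peak_disp, scale=peak_disp)
         - gamma_dist.pdf(t, undershoot_delay / undershoot_disp,
                          scale=undershoot_disp) / ratio)
    peak = np.max(np.abs(k))
    if peak <= 0:
        raise ValueError("degenerate HRF kernel")
    return k / np.max(k)


class HRFConvolutionOperator:
    """Causal per-dimension convolution of stacked latent states.

    Represents the block-banded linear map H acting on the stacked vector
    z = (z_11..z_M1, ..., z_1T..z_MT); stored implicitly through the kernel.
    ``apply`` performs the truncated (zero-padded before t=1) convolution on
    a (T, M) array; ``apply_adjoint`` applies H^T (anti-causal correlate).
    """

    def __init__(self, T: int, M: int, kernel: np.ndarray):
        self.T = int(T)
        self.M = int(M)
        self.kernel = np.atleast_1d(np.asarray(kernel, dtype=float))
        self.L = self.kernel.size

    @property
    def is_identity(self) -> bool:
        return self.L == 1 and self.kernel[0] == 1.0

    def apply(self, Z: np.ndarray) -> np.ndarray:
        Z = np.asarray(Z, dtype=float)
        if self.is_identity:
            return Z.copy()
        out = np.zeros_like(Z)
        for lag in range(min(self.L, self.T)):
            if lag == 0:
                out += self.kernel[0] * Z
            else:
                out[lag:] += self.kernel[lag] * Z[:-lag]
        return out

    def apply_adjoint(self, Y: np.ndarray) -> np.ndarray:
        Y = np.asarray(Y, dtype=float)
        if self.is_identity:
            return Y.copy()
        out = np.zeros_like(Y)
        for lag in range(min(self.L, self.T)):
            if lag == 0:
                out += self.kernel[0] * Y
            else:
                out[:-lag] += self.kernel[lag] * Y[lag:]
        return out

    def dense(self) -> np.ndarray:
        """Full MT x MT matrix (small-T verification only)."""
        T, M, L = self.T, self.M, self.L
        H = np.zeros((T * M, T * M))
        for t in range(T):
            for lag in range(min(L, t + 1)):
                H[t * M:(t + 1) * M, (t - lag) * M:(t - lag + 1) * M] = (
                    self.kernel[lag] * np.eye(M))
        return H


def build_hrf_operator(T: int, M: int, kernel: np.ndarray) -> HRFConvolutionOperator:
    return HRFConvolutionOperator(T, M, kernel)


def emit(obs_params, Z: np.ndarray, R: np.ndarray | None = None,
         noise: np.ndarray | None = None, rng=None) -> np.ndarray:
    """Map a latent trajectory (T, M) to observations (T, N).

    For the Gaussian variant x_t = B phi(z_t); for the BOLD variant
    x_t = B (hrf * z)_t + J r_t.  ``noise=True`` samples observation noise
    from N(0, Gamma) using ``rng``; an array adds it directly.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    T = Z.shape[0]
    if isinstance(obs_params, ObsParamsGaussian):
        feat = Z if obs_params.linear else np.maximum(Z, 0.0)
        X = feat @ obs_params.B.T
    else:
        op = build_hrf_operator(T, obs_params.M, obs_params.kernel)
        base = np.maximum(Z, 0.0) if obs_params.convolve_activation else Z
        X = op.apply(base) @ obs_params.B.T
        if obs_params.P > 0:
            if R is None:
                raise ValueError("BOLD variant with P > 0 requires nuisance matrix R")
            X = X + np.asarray(R, dtype=float).reshape(T, obs_params.P) @ obs_params.J.T
    if noise is True:
        rng = np.random.default_rng() if rng is None else rng
        X = X + np.sqrt(obs_params.Gamma) * rng.standard_normal(X.shape)
    elif noise is not None and noise is not False:
        X = X + np.asarray(noise, dtype=float)
    return X
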