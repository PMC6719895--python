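"""Ground-truth benchmark systems and noisy training-trajectory sampling.

The two benchmark flows (Lorenz, van der Pol) are integrated with classical
RK4 at a fixed step ``dt`` (default 0.01) and recorded every ``sample_every``
steps (default 10, i.e. a sampling interval of 0.1 time units).
Process noise is injected Euler-Maruyama style: after each RK4 drift step a
Gaussian perturbation with per-state variance ``noise_var * dt`` is added.
Initial conditions are drawn uniformly inside a loose attractor bounding box
and a transient is discarded before recording, so recorded samples start on
(or very near) the attractor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

__all__ = [
    "GroundTruthSpec",
    "Trajectory",
    "IntegrationError",
    "DegenerateInputError",
    "lorenz_rhs",
    "vdp_rhs",
    "simulate_lorenz",
    "simulate_vdp",
    "simulate",
    "standardize",
    "sample_benchmark_set",
]

#: transient steps discarded before recording (declared convention)
DEFAULT_TRANSIENT = 1000

# loose on-attractor bounding boxes used to draw random initial conditions
_INIT_BOX = {
    "lorenz": (np.array([-15.0, -20.0, 5.0]), np.array([15.0, 20.0, 40.0])),
    "vdp": (np.array([-2.0, -2.0]), np.array([2.0, 2.0])),
}


class IntegrationError(RuntimeError):
    """Non-finite state encountered during numerical integration."""

    def __init__(self, step: int):
        self.step = step
        super().__init__(f"non-finite state at integration step {step}")


class DegenerateInputError(ValueError):
    """Zero-variance column passed to standardize."""


@dataclass(frozen=True)
class GroundTruthSpec:
    """Specification of a ground-truth sampling run."""

    system_id: str
    parameters: dict = field(default_factory=dict)
    dt: float = 0.01
    process_noise_var: float = 0.0
    T: int = 1000
    seed: int = 0
    transient: int = DEFAULT_TRANSIENT
    #: record every k-th integration step (sampling interval = k * dt)
    sample_every: int = 10

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.T < 2:
            raise ValueError("T must be >= 2")
        if self.process_noise_var < 0:
            raise ValueError("process noise variance must be >= 0")
        if self.sample_every < 1:
            raise ValueError("sample_every must be >= 1")


@dataclass
class Trajectory:
    """A (T, D) state trajectory with its sampling interval."""

    states: np.ndarray
    dt: float
    standardized: bool = False
    #: (mean, sd) per column of the transform applied, if standardized
    transform: tuple | None = None

    @property
    def T(self) -> int:
        return self.states.shape[0]

    @property
    def D(self) -> int:
        return self.states.shape[1]


def lorenz_rhs(state: np.ndarray, s: float = 10.0, r: float = 28.0,
               b: float = 8.0 / 3.0) -> np.ndarray:
    x, y, z = state[..., 0], state[..., 1], state[..., 2]
    return np.stack([s * (y - x), x * (r - z) - y, x * y - b * z], axis=-1)


def vdp_rhs(state: np.ndarray, mu: float = 2.0, omega: float = 1.0) -> np.ndarray:
    x, y = state[..., 0], state[..., 1]
    return np.stack([y, mu * (1.0 - x * x) * y - omega * omega * x], axis=-1)


def _rk4_step(f: Callable, state: np.ndarray, dt: float) -> np.ndarray:
    k1 = f(state)
    k2 = f(state + 0.5 * dt * k1)
    k3 = f(state + 0.5 * dt * k2)
    k4 = f(state + dt * k3)
    return state + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def _integrate(f: Callable, x0: np.ndarray, dt: float, T: int, noise_var: float,
               transient: int, rng: np.random.Generator,
               sample_every: int = 1) -> np.ndarray:
    D = x0.shape[0]
    sd = np.sqrt(noise_var * dt)
    state = x0.astype(float)
    out = np.empty((T, D))
    total = transient + T * sample_every
    for i in range(total):
        state = _rk4_step(f, state, dt)
        if sd > 0:
            state = state + sd * rng.standard_normal(D)
        if not np.all(np.isfinite(state)):
            raise IntegrationError(i)
        j = i - transient
        if j >= 0 and (j + 1) % sample_every == 0:
            out[(j + 1) // sample_every - 1] = state
    return out


def simulate_lorenz(spec: GroundTruthSpec) -> Trajectory:
    """Sample one noisy Lorenz trajectory (dx=s(y-x), dy=x(r-z)-y, dz=xy-bz)."""
    if spec.system_id != "lorenz":
        raise ValueError("spec.system_id must be 'lorenz'")
    p = {"s": 10.0, "r": 28.0, "b": 8.0 / 3.0, **spec.parameters}
    rng = np.random.default_rng(spec.seed)
    lo, hi = _INIT_BOX["lorenz"]
    x0 = rng.uniform(lo, hi)
    f = lambda st: lorenz_rhs(st, p["s"], p["r"], p["b"])  # noqa: E731
    states = _integrate(f, x0, spec.dt, spec.T, spec.process_noise_var,
                        spec.transient, rng, spec.sample_every)
    return Trajectory(states, spec.dt * spec.sample_every)


def simulate_vdp(spec: GroundTruthSpec) -> Trajectory:
    """Sample one noisy van der Pol trajectory (x'' - mu(1-x^2)x' + w^2 x = 0)."""
    if spec.system_id != "vdp":
        raise ValueError("spec.system_id must be 'vdp'")
    p = {"mu": 2.0, "omega": 1.0, **spec.parameters}
    rng = np.random.default_rng(spec.seed)
    lo, hi = _INIT_BOX["vdp"]
    x0 = rng.uniform(lo, hi)
    f = lambda st: vdp_rhs(st, p["mu"], p["omega"])  # noqa: E731
    states = _integrate(f, x0, spec.dt, spec.T, spec.process_noise_var,
                        spec.transient, rng, spec.sample_every)
    return Trajectory(states, spec.dt * spec.sample_every)


_SIMULATORS = {"lorenz": simulate_lorenz, "vdp": simulate_vdp}


def simulate(spec: GroundTruthSpec) -> Trajectory:
    try:
        return _SIMULATORS[spec.system_id](spec)
    except KeyError:
        raise ValueError(f"unknown system_id {spec.system_id!r}") from None


def standardize(traj: Trajectory) -> Trajectory:
    """Z-score each column by the trajectory's own mean/SD (idempotent)."""
    if traj.T < 2:
        raise ValueError("need T >= 2 to standardize")
    if traj.standardized:
        return traj
    mean = traj.states.mean(axis=0)
    sd = traj.states.std(axis=0)
    if np.any(sd <= 0):
        raise DegenerateInputError("zero-variance column")
    states = (traj.states - mean) / sd
    return Trajectory(states, traj.dt, standardized=True, transform=(mean, sd))


def sample_benchmark_set(spec: GroundTruthSpec, n_samples: int,
                         standardized: bool = True) -> list[Trajectory]:
    """Draw independent trajectories with per-sample seeds spawned from spec.seed."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    out = []
    for i in range(n_samples):
        sub = replace(spec, seed=spec.seed if n_samples == 1
                      else int(np.random.SeedSequence([spec.seed, i]).generate_state(1)[0]))
        traj = simulate(sub)
        out.append(standardize(traj) if standardized else traj)
    return out
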