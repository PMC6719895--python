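"""Container for observed multivariate time series and aligned side inputs."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TrajectoryData"]


@dataclass
class TrajectoryData:
    """Observations X (T, N) with optional inputs S (T, K) and nuisance R (T, P)."""

    X: np.ndarray
    S: np.ndarray | None = None
    R: np.ndarray | None = None
    dt: float = 1.0

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains non-finite values")
        T = self.X.shape[0]
        for name in ("S", "R"):
            v = getattr(self, name)
            if v is not None:
                v = np.atleast_2d(np.asarray(v, dtype=float))
                if v.shape[0] != T:
                    raise ValueError(f"{name} row count {v.shape[0]} != T {T}")
                if not np.all(np.isfinite(v)):
                    raise ValueError(f"{name} contains non-finite values")
                setattr(self, name, v)

    @property
    def T(self) -> int:
        return self.X.shape[0]

    @property
    def N(self) -> int:
        return self.X.shape[1]

    @property
    def K(self) -> int:
        return 0 if self.S is None else self.S.shape[1]

    @property
    def P(self) -> int:
        return 0 if self.R is None else self.R.shape[1]
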