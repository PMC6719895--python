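import numpy as np
import pytest

from plrnnssm.model import PLRNNParams
from plrnnssm.observation import ObsParamsGaussian


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_plrnn(M, K=0, seed=0, linear=False, coupling=0.4, sigma=(0.2, 1.0)):
    r = np.random.default_rng(seed)
    A = r.uniform(0.2, 0.9, M)
    W = r.normal(0.0, coupling / np.sqrt(M), (M, M))
    np.fill_diagonal(W, 0.0)
    return PLRNNParams(mu0=r.normal(0, 1, M), A=A, W=W,
                       C=r.normal(0, 0.3, (M, K)), h=r.normal(0, 0.5, M),
                       Sigma=r.uniform(*sigma, M), linear=linear)


def random_gaussian_obs(N, M, seed=0, linear=False):
    r = np.random.default_rng(seed + 1000)
    return ObsParamsGaussian(B=r.normal(0, 1, (N, M)),
                             Gamma=r.uniform(0.3, 1.0, N), linear=linear)


def limit_cycle_teacher(sigma=1e-3):
    """M=3 PLRNN with a single global stable limit cycle (fixed construction)."""
    r = np.random.default_rng(162)
    A = r.uniform(0.5, 0.95, 3)
    W = r.normal(0.0, 0.8, (3, 3))
    np.fill_diagonal(W, 0.0)
    h = r.normal(0.0, 0.5, 3)
    return PLRNNParams(mu0=np.zeros(3), A=A, W=W, C=np.zeros((3, 0)), h=h,
                       Sigma=sigma * np.ones(3))
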