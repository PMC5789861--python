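import numpy as np
import pytest

from eghr.priors import gen_gaussian_prior, uniform_surrogate_prior
from eghr.sources import SourceSpec, make_mixing, make_rotation, sample_sources


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def mixed_batch(rng):
    """A fixed 200-sample batch of 3-dimensional mixed inputs."""
    specs = [SourceSpec("gaussian"), SourceSpec("uniform"), SourceSpec("laplace")]
    S = sample_sources(specs, 200, 7)
    A = rng.normal(size=(3, 3))
    return S @ A.T


@pytest.fixture
def benchmark_instance():
    """The 8-source benchmark: alternating unit Gaussian / unit uniform
    sources with eigenvalues (4, 4, 2, 2, 1, 1, 0.5, 0.5)."""
    specs = [SourceSpec("gaussian") if i % 2 == 0 else SourceSpec("uniform") for i in range(8)]
    mixing = make_mixing(make_rotation(8, 77), [4, 4, 2, 2, 1, 1, 0.5, 0.5])
    return specs, mixing


@pytest.fixture
def quartic_prior():
    return uniform_surrogate_prior()


def finite_difference_gradient(cost, W, h=1e-6):
    """Central finite differences of a scalar cost over matrix entries."""
    G = np.zeros_like(W)
    for i in range(W.shape[0]):
        for j in range(W.shape[1]):
            Wp, Wm = W.copy(), W.copy()
            Wp[i, j] += h
            Wm[i, j] -= h
            G[i, j] = (cost(Wp) - cost(Wm)) / (2 * h)
    return G
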