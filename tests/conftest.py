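import numpy as np
import pytest

from gsvdnmf import ConvergenceConfig, fixture_2x2, nndsvd_init, run_hals


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fixture2x2():
    return fixture_2x2()


def make_low_rank(rng, m, n, r, noise=0.0):
    """Nonnegative matrix of exact (or near) rank r."""
    W = rng.uniform(0, 1, (m, r))
    H = rng.uniform(0, 1, (r, n))
    X = W @ H
    if noise:
        X = np.maximum(X + noise * X.mean() * rng.standard_normal(X.shape), 0)
    return X


def undercomplete_hals(X, r0, eps=1e-5, max_iter=500):
    """A converged under-complete factorization to feed the recovery step."""
    return run_hals(X, nndsvd_init(X, r0),
                    ConvergenceConfig(eps=eps, max_iter=max_iter))
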