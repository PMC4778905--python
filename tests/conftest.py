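import numpy as np
import pytest

from aislmc import LinearRegressionModel, gen_linear


def fd_grad(f, w, eps=1e-5):
    """Central finite-difference gradient used as the independent oracle."""
    w = np.asarray(w, dtype=float)
    g = np.zeros_like(w)
    for i in range(w.size):
        e = np.zeros_like(w)
        e[i] = eps
        g[i] = (f(w + e) - f(w - e)) / (2 * eps)
    return g


@pytest.fixture(scope="session")
def linear_model():
    """Study-design linear regression instance (7 DCT regressors, N=20, sigma=0.2)."""
    return LinearRegressionModel(gen_linear(seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
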