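import numpy as np
import pytest

from hlrlogit import PenaltySpec, fit


@pytest.fixture(scope="session", autouse=True)
def _warm_numba():
    """Compile the coordinate-descent kernels once up front."""
    rng = np.random.default_rng(0)
    X = rng.standard_normal((20, 4))
    y = (rng.random(20) < 0.5).astype(float)
    y[0], y[1] = 0.0, 1.0
    fit(X, y, PenaltySpec("hlr", 0.5, 0.5))


@pytest.fixture()
def toy_logistic():
    """Small well-conditioned binary problem with known coefficients."""
    rng = np.random.default_rng(42)
    n, p = 200, 5
    X = rng.standard_normal((n, p))
    beta = np.array([1.0, -2.0, 0.5, 0.0, 1.5])
    eta = 0.3 + X @ beta
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    return X, y, beta
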