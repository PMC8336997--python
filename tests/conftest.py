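import numpy as np
import pytest

from stackenet import fit_stacked_elastic_net


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)


def make_gaussian(rng, n=40, p=8, sparse=True, noise=0.5):
    X = rng.normal(size=(n, p))
    beta = np.zeros(p)
    beta[: max(2, p // 4) if sparse else p] = 1.0
    y = X @ beta + rng.normal(size=n) * noise * np.std(X @ beta)
    return X, beta, y


@pytest.fixture(scope="session")
def small_stacked_model():
    """One modest gaussian stacked fit shared across read-only tests."""
    rng = np.random.default_rng(7)
    n, p = 60, 20
    X = rng.normal(size=(n, p))
    beta = np.zeros(p)
    beta[:4] = (1.5, -1.0, 0.8, 0.5)
    y = X @ beta + rng.normal(size=n) * 0.5
    model = fit_stacked_elastic_net(X, y, "gaussian", m=6, K=5, seed=11)
    return X, y, model
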