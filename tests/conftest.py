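import numpy as np
import pytest

from repsieve import Dataset, SimConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240719)


@pytest.fixture(scope="session")
def small_binary():
    """Tiny planted-signal binary dataset: 1 strong predictor + noise."""
    rng = np.random.default_rng(7)
    n, m = 200, 50
    X = rng.standard_normal((n, m))
    eta = 2.0 * X[:, 0]
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    return Dataset(X=X, feature_ids=[f"g{j:02d}" for j in range(m)], y=y)


@pytest.fixture(scope="session")
def small_survival():
    """Tiny planted-signal survival dataset with ~25% censoring."""
    rng = np.random.default_rng(11)
    n, m = 200, 40
    X = rng.standard_normal((n, m))
    lam = 0.1 * np.exp(0.9 * X[:, 0] - 0.9 * X[:, 1])
    T = rng.exponential(1.0, n) / lam
    C = rng.uniform(0, 40, n)
    return Dataset(
        X=X,
        feature_ids=[f"g{j:02d}" for j in range(m)],
        time=np.minimum(T, C),
        event=(T <= C).astype(int),
    )


@pytest.fixture(scope="session")
def binary_replicate():
    """One moderate replicate of the simulated binary study (reduced m)."""
    ds, truth = simulate_dataset(
        SimConfig(family="binary", n=400, m=400, seed=42)
    )
    return ds, truth
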