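import numpy as np
import pandas as pd
import pytest

from srscape.covariates import extract_at_points
from srscape.synthetic import SimConfig, generate_world


@pytest.fixture(scope="session")
def small_world():
    """A modest synthetic landscape shared by read-only tests."""
    cfg = SimConfig(width=60, height=60, n_geology_units=8, n_sites=200, seed=1)
    return generate_world(cfg)


@pytest.fixture(scope="session")
def small_matrix(small_world):
    return extract_at_points(small_world.covariates, small_world.samples)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_regression_task(seed: int, n: int = 400, p_noise: int = 20):
    """3 informative + p_noise pure-noise standard-normal predictors."""
    r = np.random.default_rng(seed)
    X = r.standard_normal((n, 3 + p_noise))
    y = 0.710 + 0.004 * X[:, 0] + 0.003 * X[:, 1] + 0.002 * X[:, 2] + r.normal(0, 0.001, n)
    cols = ["inf_0", "inf_1", "inf_2"] + [f"noise_{i}" for i in range(p_noise)]
    return pd.DataFrame(X, columns=cols), y
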