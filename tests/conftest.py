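import numpy as np
import pytest

from dishare.core import CohortPair


def random_pair(
    seed,
    n_G=12,
    n_C=12,
    p=6,
    beta_scale=1.0,
    delta_scale=0.5,
    noise_sd=0.5,
    delta_zero=False,
):
    """Small random two-cohort instance with known truth."""
    rng = np.random.default_rng(seed)
    X_G = rng.standard_normal((n_G, p))
    X_C = rng.standard_normal((n_C, p))
    beta = rng.standard_normal(p) * beta_scale
    delta = np.zeros(p) if delta_zero else rng.standard_normal(p) * delta_scale
    y_G = X_G @ beta + rng.standard_normal(n_G) * noise_sd
    y_C = X_C @ (beta + delta) + rng.standard_normal(n_C) * noise_sd
    return CohortPair(X_G, y_G, X_C, y_C), beta, delta


@pytest.fixture
def small_pair():
    pair, _, _ = random_pair(0)
    return pair


@pytest.fixture(scope="session", autouse=True)
def _warm_numba():
    """Compile the coordinate-descent kernel once, outside timed tests."""
    from dishare.core import solve_weighted_enet

    Z = np.array([[1.0, 0.0], [0.0, 1.0]])
    solve_weighted_enet(
        Z, np.array([1.0, 2.0]), np.ones(2), np.ones(2), lambda1=0.1, lambda2=0.1
    )
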