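import numpy as np
import pytest

from cariescea import default_config, run_suite
from cariescea.model_core import N_STATES


@pytest.fixture(scope="session")
def core():
    """Packaged base-case configuration with calibrated synthetic inputs."""
    return default_config()


@pytest.fixture(scope="session")
def suite_results(core):
    """Full six-scenario suite on the calibrated base case (shared)."""
    return run_suite(core)


@pytest.fixture
def identity_matrix():
    return np.eye(N_STATES)


def random_stochastic_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random row-stochastic matrix (rows normalised uniforms)."""
    m = rng.random((n, n)) + 1e-3
    return m / m.sum(axis=1, keepdims=True)


def random_distribution(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.random(n) + 1e-3
    return v / v.sum()
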