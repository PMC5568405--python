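import numpy as np
import pytest

from toposwarm import ModelParams, SwarmState


@pytest.fixture(scope="session")
def default_params():
    """Reference parameter set at a small workable (N, K)."""
    return ModelParams(N=16, K=7)


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


def random_state(rng, n, dims=3, scale=30.0, step=0):
    return SwarmState(rng.uniform(0.0, scale, size=(n, dims)), step=step)


@pytest.fixture
def make_state(rng):
    def _make(n, dims=3, scale=30.0):
        return random_state(rng, n, dims, scale)

    return _make
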