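import numpy as np
import pytest

from ssmkit.synthetic_shapes import default_family, fixture_suite, sample_family


@pytest.fixture(scope="session")
def fixture_family():
    """Deterministic noiseless rank-4 family: 8 specimens, ~300 vertices."""
    shape_set, scores, _paths = fixture_suite(seed=11)
    return shape_set, scores


@pytest.fixture(scope="session")
def noisy_family():
    """Small noisy family with rigid jitter, as LOO-style inputs."""
    spec = default_family(
        "pelvislike", n_specimens=12, n_modes=4, noise_sd=0.3, seed=5,
        n_vertices=300,
    )
    return sample_family(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
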