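import numpy as np
import pytest

from funnelmorph import LandmarkConfiguration, LandmarkDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def triangle_names():
    return ("apex", "left", "right")


@pytest.fixture
def small_dataset(rng, triangle_names):
    """Five random 3-landmark 2D configurations with metadata ids."""
    configs = [
        LandmarkConfiguration(f"s{i}", rng.normal(size=(3, 2)), triangle_names)
        for i in range(5)
    ]
    return LandmarkDataset(configs)


def random_rotation(rng, d):
    """Proper random rotation via QR with positive-diagonal convention."""
    Q, R = np.linalg.qr(rng.normal(size=(d, d)))
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
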