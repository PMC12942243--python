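import numpy as np
import pytest

from geospine import phantom
from geospine.geometry import LandmarkSet


@pytest.fixture
def straight_landmarks() -> LandmarkSet:
    """Straight vertical chain, symmetric discs, equal SI distances: all indices 0."""
    n = 5
    centroids = np.stack([np.full(n, 64.0), 20.0 + 20.0 * np.arange(n)], axis=1)
    return LandmarkSet(centroids, np.full(n, 30.0), np.full((n - 1, 2), 8.0),
                       np.array([3.0, 3.0]))


@pytest.fixture(scope="session")
def small_samples():
    """Two dozen phantoms, all six classes, fixed seed (session-wide reuse)."""
    return phantom.generate_samples(n=24, class_mix=None, seed=42)


@pytest.fixture(scope="session")
def config_rng_configs():
    """Feasible class-conditional configs drawn from every diagnostic class."""
    rng = np.random.default_rng(7)
    return [phantom.sample_config(phantom.CLASSES[i % 6], rng) for i in range(30)]
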