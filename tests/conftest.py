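import numpy as np
import pytest

from fleagm.shape_core import ShapeDataset
from fleagm.synthetic import ShapeSimSpec, simulate_landmark_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20220929)


@pytest.fixture(scope="session")
def default_dataset() -> ShapeDataset:
    """The default simulated 165-specimen, 13-landmark, 2x2 dataset."""
    dataset, _ = simulate_landmark_dataset(ShapeSimSpec(seed=42))
    return dataset


def random_configuration(rng: np.random.Generator, p: int = 6) -> np.ndarray:
    """A generic (non-degenerate) random 2-D configuration."""
    return rng.normal(size=(p, 2))


def random_similarity(rng: np.random.Generator, pts: np.ndarray) -> np.ndarray:
    """Apply a random rotation, positive scale and translation."""
    theta = rng.uniform(-np.pi, np.pi)
    c, s = np.cos(theta), np.sin(theta)
    R = np.array([[c, -s], [s, c]])
    return rng.uniform(0.2, 5.0) * pts @ R.T + rng.uniform(-10, 10, size=2)
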