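import numpy as np
import pytest

from wingmorph import generalized_procrustes, shape_pca, simulate_reference_dataset
from wingmorph.synthetic_data import study_design_spec


@pytest.fixture(scope="session")
def study_dataset():
    """Full four-group study design (n = 50/50/20/20), one fixed seed."""
    return simulate_reference_dataset(study_design_spec(seed=1))


@pytest.fixture(scope="session")
def study_aligned(study_dataset):
    return generalized_procrustes(study_dataset)


@pytest.fixture(scope="session")
def study_pca(study_aligned):
    return shape_pca(study_aligned)


@pytest.fixture(scope="session")
def small_dataset():
    """Reduced design (30 % group sizes) for quicker structural tests."""
    return simulate_reference_dataset(study_design_spec(seed=2, n_scale=0.3))


@pytest.fixture(scope="session")
def small_aligned(small_dataset):
    return generalized_procrustes(small_dataset)


def random_similarity(rng: np.random.Generator, coords: np.ndarray) -> np.ndarray:
    """Apply a random rotation, positive scaling, and translation."""
    theta = rng.uniform(0, 2 * np.pi)
    scale = rng.uniform(0.3, 4.0)
    c, s = np.cos(theta), np.sin(theta)
    return (coords @ np.array([[c, s], [-s, c]])) * scale + rng.uniform(-30, 30, size=2)
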