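import numpy as np
import pytest
from hypothesis import settings

from arpcm.curves import DEFAULT_GRID, DoseResponseCurve

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_curve(activations, mutant="m", drug="d", grid=DEFAULT_GRID):
    return DoseResponseCurve(mutant, drug, tuple(grid), tuple(activations))


@pytest.fixture
def example_curves():
    """The four canonical example curves, one per phenotype."""
    return {
        "non-responsive": make_curve([2.0] * 11),
        "antagonist": make_curve([100, 95, 90, 80, 60, 40, 25, 15, 10, 8, 5]),
        "mixed-response": make_curve([100, 90, 70, 50, 30, 20, 15, 18, 25, 32, 40]),
        "agonist": make_curve([100, 100, 101, 103, 105, 110, 115, 120, 125, 130, 140]),
    }


@pytest.fixture
def imbalanced_2d():
    """2-D labelled matrix with class counts {0: 10, 1: 30, 2: 2, 3: 6}.

    Classes sit in separated clusters so nearest-neighbour structure is
    unambiguous for the resampling tests.
    """
    rng = np.random.default_rng(0)
    centers = {0: (0.0, 0.0), 1: (10.0, 0.0), 2: (0.0, 10.0), 3: (10.0, 10.0)}
    counts = {0: 10, 1: 30, 2: 2, 3: 6}
    X, y = [], []
    for cls, n in counts.items():
        X.append(rng.normal(centers[cls], 1.0, size=(n, 2)))
        y.extend([cls] * n)
    return np.vstack(X), np.asarray(y)


@pytest.fixture(scope="session")
def blobs_4class():
    """Linearly separable 4-class blobs (200 points, fixed seed)."""
    from sklearn.datasets import make_blobs

    X, y = make_blobs(
        n_samples=200, centers=4, n_features=6, cluster_std=1.0, random_state=11
    )
    return X, y


@pytest.fixture(scope="session")
def coupled_dataset():
    """Simulated dataset whose phenotypes are learnable from the features."""
    from arpcm.simulate import simulate_dataset

    return simulate_dataset(12, seed=5, couple_features=True)
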