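import numpy as np
import pytest

from dce import DataMatrix, MixtureSpec, simulate_mixture


@pytest.fixture
def tiny_matrix():
    """3 samples x 2 features, exact values for closed-form checks."""
    return DataMatrix(
        np.array([[0.0, 0.0], [3.0, 4.0], [1.0, 1.0]]),
        ["a", "b", "c"],
        ["f1", "f2"],
    )


@pytest.fixture
def three_blobs():
    """Well-separated 3-blob fixture (n=60, p=5, 10-sd separation)."""
    return simulate_mixture(MixtureSpec(n_per_cluster=(20, 20, 20), n_features=5, separation=10.0, seed=11))


@pytest.fixture
def two_blobs():
    return simulate_mixture(MixtureSpec(n_per_cluster=(25, 25), n_features=4, separation=10.0, seed=5))
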