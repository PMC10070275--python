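import numpy as np
import pytest

from twocell import GeneScoreMatrix, LabelVector, SyntheticConfig, generate


@pytest.fixture(scope="session")
def small_dataset():
    """A small but separable reference/target pair (fast to fit)."""
    return generate(SyntheticConfig(
        n_genes=300, n_ref=240, n_target=200, n_types=3,
        markers_per_type=12, seed=11,
    ))


@pytest.fixture
def tiny_matrix():
    values = np.array([[5.0, 0.0], [0.0, 0.0], [0.0, 2.5]])
    return GeneScoreMatrix(values, ["g1", "g2", "g3"], ["c1", "c2"])


@pytest.fixture
def blobs():
    """Two well-separated Gaussian blobs: linearly separable by construction."""
    from sklearn.datasets import make_blobs

    X, y = make_blobs(n_samples=200, n_features=10, centers=2,
                      cluster_std=1.0, center_box=(-8, 8), random_state=0)
    return X, np.array([f"class{v}" for v in y], dtype=object)


def labels_from(barcodes, labels):
    return LabelVector(np.asarray(barcodes, dtype=object), np.asarray(labels, dtype=object))
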