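import numpy as np
import pytest

from urfclust import FeatureMatrix, ForestParams, fit_forest


@pytest.fixture
def two_blob_matrix():
    """Two tight, well-separated 1-D blobs of 5 points each."""
    rng = np.random.default_rng(7)
    x = np.concatenate([rng.normal(0.0, 0.01, 5), rng.normal(10.0, 0.01, 5)])
    return FeatureMatrix(x[:, None]), np.repeat([0, 1], 5)


@pytest.fixture
def three_blob_data():
    """Three 2-D Gaussian blobs (30 points each), labels attached."""
    rng = np.random.default_rng(11)
    centers = [(0.0, 0.0), (4.0, 0.0), (0.0, 4.0)]
    pts = np.vstack([rng.normal(c, 0.2, (30, 2)) for c in centers])
    return FeatureMatrix(pts), np.repeat(np.arange(3), 30)


@pytest.fixture
def small_forest(three_blob_data):
    X, _ = three_blob_data
    return fit_forest(X, ForestParams(n_trees=30, min_leaf_size=5, mtry=1, seed=5)), X
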