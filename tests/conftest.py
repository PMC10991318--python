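import numpy as np
import pytest

from cardioml.data import Dataset, Schema


@pytest.fixture
def tiny_schema():
    return Schema(
        column_names=("x1", "x2", "x3", "label"),
        column_kinds=("continuous", "continuous", "binary", "binary"),
        label_name="label",
    )


@pytest.fixture
def tiny_dataset(tiny_schema):
    X = np.array([[0.5, -1.25, 1.0],
                  [2.0, 3.5, 0.0],
                  [-1.0, 0.0, 1.0]])
    y = np.array([1, 0, 1])
    return Dataset(X, y, tiny_schema)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def three_blobs_with_outliers(seed: int = 0, n_per_blob: int = 150,
                              n_outliers: int = 25):
    """Planted-cluster fixture: three separated Gaussian blobs plus a small,
    tight outlier cluster displaced far from all of them.

    Returns (X, outlier_indices).  The outlier cluster occupies a k-means
    center that the real three-cluster structure needs, so removing it should
    raise the silhouette of a refit.
    """
    rng = np.random.default_rng(seed)
    centers = np.array([[0.0, 0.0], [8.0, 0.0], [4.0, 7.0]])
    parts = [c + rng.normal(scale=1.0, size=(n_per_blob, 2)) for c in centers]
    outliers = np.array([40.0, 40.0]) + rng.normal(scale=0.3, size=(n_outliers, 2))
    X = np.vstack(parts + [outliers])
    out_idx = np.arange(3 * n_per_blob, 3 * n_per_blob + n_outliers)
    perm = rng.permutation(X.shape[0])
    inv = np.empty_like(perm)
    inv[perm] = np.arange(perm.size)
    return X[perm], np.sort(inv[out_idx])
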