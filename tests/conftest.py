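import numpy as np
import pytest

from cba import ExpressionBatch, FeatureMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_batch(counts, tag="b1", labels=None):
    counts = np.asarray(counts, dtype=float)
    n, g = counts.shape
    return ExpressionBatch(
        counts=counts,
        gene_ids=[f"g{j}" for j in range(g)],
        cell_ids=[f"{tag}_c{i}" for i in range(n)],
        batch_tag=tag,
        provided_labels=labels,
    )


@pytest.fixture
def two_blob_features(rng):
    """Two well-separated Gaussian blobs in one FeatureMatrix."""
    a = rng.normal(loc=0.0, scale=0.5, size=(100, 5))
    b = rng.normal(loc=10.0, scale=0.5, size=(100, 5))
    truth = np.array([0] * 100 + [1] * 100)
    return FeatureMatrix(np.vstack([a, b]), "blobs"), truth
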