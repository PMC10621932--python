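import numpy as np
import pytest

from hmlfsm import ExpressionDataset


@pytest.fixture
def make_dataset():
    """Factory for small in-memory expression datasets."""

    def _make(matrix, labels, gene_ids=None, provenance="test"):
        matrix = np.asarray(matrix, dtype=float)
        if gene_ids is None:
            gene_ids = [f"g{j}" for j in range(matrix.shape[1])]
        return ExpressionDataset(matrix, gene_ids, labels, provenance)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def separable_dataset(make_dataset, rng):
    """One perfectly separating gene among pure-noise genes."""
    n = 30
    labels = np.repeat([0, 1], n // 2)
    matrix = rng.normal(size=(n, 8))
    matrix[:, 3] = labels * 10.0 + rng.normal(scale=0.1, size=n)
    return make_dataset(matrix, labels), 3
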