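import numpy as np
import pytest

from slicer import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20160523)


@pytest.fixture
def small_matrix(rng):
    """Random 10 x 20 raw expression matrix."""
    vals = rng.uniform(0, 50, size=(10, 20))
    return ExpressionMatrix(
        vals,
        cell_ids=[f"c{i}" for i in range(10)],
        gene_ids=[f"g{j}" for j in range(20)],
    )


@pytest.fixture
def two_clusters():
    """10 points: two tight clusters of 5, far apart (coords only)."""
    rng = np.random.default_rng(7)
    a = rng.normal(0, 0.1, size=(5, 3))
    b = rng.normal(0, 0.1, size=(5, 3)) + 100.0
    return np.vstack([a, b])
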