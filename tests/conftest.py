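import numpy as np
import pytest
import scipy.sparse as sp

from streetgreen.spatial_stats import SpatialWeights, row_standardize


@pytest.fixture
def path4_weights() -> SpatialWeights:
    """Row-standardised weights of the 4-node path graph 0-1-2-3."""
    adj = np.array(
        [[0, 1, 0, 0], [1, 0, 1, 0], [0, 1, 0, 1], [0, 0, 1, 0]], dtype=float
    )
    return row_standardize(SpatialWeights(sp.csr_matrix(adj)))


def random_weights(rng: np.random.Generator, n: int, standardized: bool) -> SpatialWeights:
    """Random symmetric binary weights on n units, island-free.

    Island-free so the naive oracles (which use the full n) agree with the
    implementation's convention; island handling has dedicated tests.
    """
    adj = rng.random((n, n)) < 0.3
    adj = np.triu(adj, k=1)
    adj = adj | adj.T
    for i in np.flatnonzero(~adj.any(axis=1)):  # connect isolated units
        j = (i + 1) % n
        adj[i, j] = adj[j, i] = True
    w = SpatialWeights(sp.csr_matrix(adj.astype(float)))
    return row_standardize(w) if standardized else w
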