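import numpy as np
import pytest

from rsvnet import WeightedNetwork


@pytest.fixture
def star4() -> WeightedNetwork:
    """Unit-weight star: hub R1 connected to three leaves."""
    W = np.zeros((4, 4))
    W[0, 1:] = W[1:, 0] = 1.0
    return WeightedNetwork.from_matrix(W)


@pytest.fixture
def k4() -> WeightedNetwork:
    """Complete unit-weight graph on 4 nodes (regular, homogeneous)."""
    return WeightedNetwork.from_matrix(np.ones((4, 4)) - np.eye(4))


@pytest.fixture
def weighted_triangle() -> WeightedNetwork:
    """Triangle with weights W_AB=1, W_BC=2, W_AC=3 (strengths 4, 3, 5)."""
    W = np.array([[0.0, 1.0, 3.0], [1.0, 0.0, 2.0], [3.0, 2.0, 0.0]])
    return WeightedNetwork.from_matrix(W, node_labels=("A", "B", "C"))


def random_connected_network(rng: np.random.Generator, n_min: int = 4,
                             n_max: int = 7, min_degree: int = 2) -> WeightedNetwork:
    """Random connected integer-weighted network with a degree floor."""
    from scipy.sparse.csgraph import connected_components
    from scipy.sparse import csr_array

    while True:
        n = int(rng.integers(n_min, n_max))
        W = np.zeros((n, n))
        ii, jj = np.triu_indices(n, k=1)
        present = rng.random(ii.size) < 0.6
        W[ii[present], jj[present]] = rng.integers(1, 4, size=int(present.sum()))
        W += W.T
        if (W > 0).sum(axis=1).min() >= min_degree:
            ncomp, _ = connected_components(csr_array(W), directed=False)
            if ncomp == 1:
                return WeightedNetwork.from_matrix(W)
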