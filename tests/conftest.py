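import numpy as np
import pytest

import specguide as sg


@pytest.fixture(scope="session")
def triangle():
    """3-node all-to-all unit-weight graph."""
    A = np.ones((3, 3)) - np.eye(3)
    return sg.Graph(node_ids=["1", "2", "3"], A_raw=A)


@pytest.fixture(scope="session")
def fixture_graph():
    """Seeded three-class planted-partition graph (modular, connected)."""
    return sg.synth_fixture((20, 20, 20), p_within=0.35, p_between=0.06, seed=7)


@pytest.fixture(scope="session")
def fixture_ops(fixture_graph):
    return sg.normalize(fixture_graph)


@pytest.fixture(scope="session")
def fixture_basis(fixture_ops):
    return sg.eigendecompose(fixture_ops)


@pytest.fixture(scope="session")
def fixture_sqrtL(fixture_basis):
    return sg.sqrt_laplacian_exact(fixture_basis)


def random_weighted_graph(n, seed, density=0.4):
    """Connected random weighted graph: ring backbone + random weighted edges."""
    rng = np.random.default_rng(seed)
    A = np.zeros((n, n))
    idx = np.arange(n)
    A[idx, (idx + 1) % n] = rng.uniform(0.5, 2.0, n)
    mask = np.triu(rng.random((n, n)) < density, k=1)
    W = rng.uniform(0.1, 3.0, (n, n))
    A[mask] = W[mask]
    A = np.triu(A, 1)
    A = A + A.T
    return sg.Graph(node_ids=[str(i) for i in range(n)], A_raw=A)
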