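import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import conncrit as cc

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

# Reference parameter sets used across the suite: the strength-scale fits of
# the bounded and truncated models, and a typical scale-free exponent.
RESTRICTED_REF = dict(gamma=2.22, x_min=0.546, x_max=33.5)
TRUNCATED_REF = dict(alpha=2.17, x_c=5.67, x_min=0.5)
POWERLAW_REF = dict(alpha=2.5, x_min=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_matrix():
    """3 regions with |w| = 0.7, 0.3, 0.65 on the three pairs."""
    w = np.array(
        [
            [0.0, 0.7, -0.3],
            [0.7, 0.0, 0.65],
            [-0.3, 0.65, 0.0],
        ]
    )
    return cc.ConnectivityMatrix(weights=w)


def adjacency_from_edges(n, edges):
    a = np.zeros((n, n), dtype=int)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return cc.BinaryNetwork(adjacency=a, threshold=0.5)


@pytest.fixture
def path3():
    """Path graph 1-2-3."""
    return adjacency_from_edges(3, [(0, 1), (1, 2)])


def random_network(rng, max_nodes=20):
    n = int(rng.integers(2, max_nodes + 1))
    p = rng.uniform(0.05, 0.9)
    a = (rng.random((n, n)) < p).astype(int)
    a = np.triu(a, k=1)
    a = a + a.T
    return cc.BinaryNetwork(adjacency=a, threshold=0.5)


# ---------------------------------------------------------------------------
# Brute-force graph oracles (independent of the implementation paths)
# ---------------------------------------------------------------------------

def bf_transitivity(net):
    a = net.adjacency
    n = a.shape[0]
    triangles = 0
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                if a[i, j] and a[j, k] and a[i, k]:
                    triangles += 1
    triples = 0
    for i in range(n):
        k = int(a[i].sum())
        triples += k * (k - 1) // 2
    return 3.0 * triangles / triples if triples else 0.0


def bf_distances(net):
    """Floyd-Warshall hop counts; inf for unreachable pairs."""
    a = net.adjacency
    n = a.shape[0]
    d = np.where(a > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def bf_avg_path_length(net):
    n = net.n_nodes
    d = bf_distances(net)
    d = np.where(np.isinf(d), float(n), d)
    np.fill_diagonal(d, 0.0)
    return d.sum() / (n * (n - 1))


def bf_global_efficiency(net):
    n = net.n_nodes
    d = bf_distances(net)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[np.isinf(d)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv.sum() / (n * (n - 1))
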