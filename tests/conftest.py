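import numpy as np
import pytest

from hiercomplex import BinaryNetwork


def net_from_edges(edges, n):
    a = np.zeros((n, n), dtype=int)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return BinaryNetwork(a)


@pytest.fixture
def g5():
    """Toy graph: edges a-b, a-c, b-c, c-d, d-e; degrees (2,2,3,2,1)."""
    return net_from_edges([(0, 1), (0, 2), (1, 2), (2, 3), (3, 4)], 5)


@pytest.fixture
def p4():
    """Path on four nodes."""
    return net_from_edges([(0, 1), (1, 2), (2, 3)], 4)


def random_net(n, p, rng):
    a = (rng.random((n, n)) < p).astype(int)
    a = np.triu(a, 1)
    return BinaryNetwork(a + a.T)


def brute_force_R(a, scaled=True):
    """Independent oracle: hierarchical complexity by explicit enumeration.

    Plain Python loops over degree classes, sequence positions and nodes;
    no shared code with the implementation under test.
    """
    n = len(a)
    deg = [int(sum(a[i])) for i in range(n)]
    distinct = sorted(set(deg))
    D = len(distinct)
    total = 0.0
    for p in distinct:
        nodes = [i for i in range(n) if deg[i] == p]
        if p == 0 or len(nodes) < 2:
            continue
        seqs = [sorted(deg[j] for j in range(n) if a[i][j]) for i in nodes]
        ss = 0.0
        for j in range(p):
            mu = sum(s[j] for s in seqs) / len(seqs)
            for s in seqs:
                ss += (s[j] - mu) ** 2
        term = ss / (p * (len(nodes) - 1))
        if scaled:
            term /= p * len(nodes)
        total += term
    return total / D if D else 0.0
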