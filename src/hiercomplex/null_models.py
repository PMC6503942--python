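"""Node- and edge-matched random graph ensembles.

Three null models, each matched to a reference network's node count n and
edge count m:

* Erdős–Rényi: uniform simple graph with exactly m edges (the baseline
  with no built-in structure).
* 3D random geometric graph: n points uniform in the unit cube, edges the
  m closest pairs (distance-driven clustering, no degree heterogeneity).
* Configuration rewiring: degree-preserving double-edge-swap randomisation
  of a given network (controls for degree heterogeneity exactly).

All generators take an explicit integer seed and are reproducible.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.distance import pdist

from .graph_core import BinaryNetwork

__all__ = ["er_random", "rgg_3d", "configuration_rewire"]


def _check_m(n: int, m: int) -> None:
    mmax = n * (n - 1) // 2
    if not 0 <= m <= mmax:
        raise ValueError(f"edge count m={m} outside [0, {mmax}] for n={n}")


def _pairs(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def _from_pair_index(n: int, idx: np.ndarray) -> np.ndarray:
    iu, ju = _pairs(n)
    a = np.zeros((n, n), dtype=np.int8)
    a[iu[idx], ju[idx]] = 1
    return a + a.T


def er_random(n: int, m: int, seed: int) -> BinaryNetwork:
    """Uniform random simple graph with exactly m edges.

    Equivalent to drawing a uniform weight per node pair and keeping the m
    largest: a uniform sample of m unordered pairs without replacement.
    """
    _check_m(n, m)
    rng = np.random.default_rng(seed)
    idx = rng.choice(n * (n - 1) // 2, size=m, replace=False)
    return BinaryNetwork(_from_pair_index(n, idx))


def rgg_3d(n: int, m: int, seed: int, coords: np.ndarray | None = None
           ) -> tuple[BinaryNetwork, np.ndarray]:
    """3D random geometric graph: edges are the m closest point pairs.

    Points are uniform in the unit cube unless ``coords`` is supplied
    (n x 3).  Only the ordering of pairwise distances matters, so the
    absolute scale of the domain is irrelevant.  Exact distance ties (a
    measure-zero event for random points) are broken by an RNG-shuffled
    pair order under a stable sort.  Returns the network together with the
    coordinates used.
    """
    _check_m(n, m)
    rng = np.random.default_rng(seed)
    if coords is None:
        coords = rng.random((n, 3))
    coords = np.asarray(coords, dtype=float)
    d = pdist(coords)
    order = rng.permutation(len(d))
    idx = order[np.argsort(d[order], kind="stable")[:m]]
    return BinaryNetwork(_from_pair_index(n, idx)), coords


def configuration_rewire(net: BinaryNetwork, seed: int,
                         swaps_per_edge: int = 10) -> BinaryNetwork:
    """Degree-preserving randomisation by double-edge swaps.

    Attempts ``swaps_per_edge * m`` swaps; each picks two distinct edges
    (a, b), (c, d) and proposes (a, d), (c, b), rejecting any swap that
    would create a self-loop or parallel edge.  The degree sequence of the
    output is identical to the input's, so degree variance is conserved
    exactly.  Realising the configuration model by swap MCMC (rather than
    stub matching) guarantees the result stays a simple graph.
    """
    if swaps_per_edge < 1:
        raise ValueError("swaps_per_edge must be >= 1")
    m = net.m
    if m < 2:
        warnings.warn("fewer than 2 edges; returning the network unchanged")
        return BinaryNetwork(net.a.copy(), list(net.labels), net.hemis)
    rng = np.random.default_rng(seed)
    a = net.a.copy()
    edges = net.edge_list()
    attempts = swaps_per_edge * m
    choices = rng.integers(0, m, size=(attempts, 2))
    flips = rng.integers(0, 2, size=attempts)
    for t in range(attempts):
        e1, e2 = choices[t]
        if e1 == e2:
            continue
        u, v = edges[e1]
        x, y = edges[e2]
        if flips[t]:
            x, y = y, x
        # propose (u, y), (x, v)
        if u == y or x == v:
            continue
        if a[u, y] or a[x, v]:
            continue
        a[u, v] = a[v, u] = 0
        a[x, y] = a[y, x] = 0
        a[u, y] = a[y, u] = 1
        a[x, v] = a[v, x] = 1
        edges[e1] = (u, y)
        edges[e2] = (x, v)
    return BinaryNetwork(a, list(net.labels), net.hemis)
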