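"""Scalar network indices: hierarchical complexity and comparison measures.

Hierarchical complexity R quantifies how variable the connectivity
patterns of hierarchically equivalent nodes (nodes sharing a degree) are.
For each degree class K_p (the nodes of degree p) with at least two
members, stack the ascending neighbourhood degree sequences s_i and take
the sample variance of each of the p positions; the class's mean
positional variance

    W_p = (1/p) * sum_j [ (1/(|K_p|-1)) * sum_{i in K_p} (s_i(j) - mu_p(j))^2 ]

measures how heterogeneous the class's connectivity patterns are.  R
averages these terms over the D distinct degrees of the network
(singleton classes count towards D even though they contribute nothing):

    R = (1/D) * sum over p with |K_p| > 1 of W_p / (p * |K_p|)   [scaled]
    R = (1/D) * sum over p with |K_p| > 1 of W_p                 [raw]

The scaled form divides each class term by its number of neighbour slots
(degree x class size), putting classes of different degree and size on a
common per-slot scale; it is the form whose ensemble values match the
connectome literature's reported magnitudes and is the default
throughout.  The raw mean-positional-variance form is retained as
``scaled=False``.

The comparison measures (degree variance V, assortativity r, global
clustering C with its density-normalised form gamma, characteristic path
length L and the mean rich-club coefficient) are standard; they are
included because R is interpreted against them.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict
from typing import Iterable

import networkx as nx
import numpy as np

from .graph_core import BinaryNetwork, degree_structure

__all__ = [
    "IndexReport",
    "hierarchical_complexity",
    "degree_range_complexity",
    "degree_variance",
    "assortativity",
    "clustering_and_density",
    "characteristic_path_length",
    "mean_rich_club",
    "compute_index_report",
]


def _class_term(seqs: np.ndarray, p: int, scaled: bool) -> float:
    """Positional-variance term of one degree class.

    `seqs` stacks the |K_p| ascending neighbourhood degree sequences of the
    class as rows.  The raw term is the mean over the p positions of the
    positional sample variance; the scaled term divides it further by the
    class's neighbour-slot count p * |K_p|.
    """
    c = seqs.shape[0]
    dev = seqs - seqs.mean(axis=0)
    w = float((dev * dev).sum()) / (p * (c - 1))
    return w / (p * c) if scaled else w


def hierarchical_complexity(net: BinaryNetwork, scaled: bool = True) -> float:
    """Hierarchical complexity R of a binary network.

    Returns 0 when no degree class has two or more members (every class
    then has a single, trivially homogeneous connectivity pattern).
    ``scaled`` selects the per-neighbour-slot normalisation of the class
    terms (the default, on the scale of reported connectome values) or the
    raw mean-positional-variance form.
    """
    if net.n == 0:
        warnings.warn("hierarchical complexity of an empty graph defined as 0")
        return 0.0
    ds = degree_structure(net)
    total = 0.0
    for p, nodes in ds.classes.items():
        if p > 0 and len(nodes) > 1:
            total += _class_term(np.vstack([ds.seqs[i] for i in nodes]), p, scaled)
    return total / ds.D


def degree_range_complexity(net: BinaryNetwork, degrees: Iterable[int],
                            scaled: bool = True) -> float:
    """Degree-specific hierarchical complexity over a set of degree values.

    The mean of the per-class positional-variance terms over the degrees in
    ``degrees`` that occur in the network with class size >= 2.  NaN when no
    such degree exists (undefined rather than zero: there is nothing to
    average).
    """
    wanted = set(int(d) for d in degrees)
    if not wanted:
        raise ValueError("degrees must be nonempty")
    ds = degree_structure(net)
    terms = [
        _class_term(np.vstack([ds.seqs[i] for i in nodes]), p, scaled)
        for p, nodes in ds.classes.items()
        if p in wanted and p > 0 and len(nodes) > 1
    ]
    return float(np.mean(terms)) if terms else math.nan


def degree_variance(net: BinaryNetwork) -> float:
    """Sample variance (denominator n-1) of the degree sequence."""
    if net.n < 2:
        return math.nan
    return float(np.var(net.degrees(), ddof=1))


def assortativity(net: BinaryNetwork) -> float:
    """Degree assortativity: Pearson correlation of degrees over edge ends.

    Each edge contributes both orientations, making the measure symmetric.
    NaN when the endpoint degrees have zero variance (e.g. regular graphs).
    """
    edges = net.edge_list()
    if len(edges) == 0:
        return math.nan
    k = net.degrees()
    x = np.concatenate([k[edges[:, 0]], k[edges[:, 1]]]).astype(float)
    y = np.concatenate([k[edges[:, 1]], k[edges[:, 0]]]).astype(float)
    sx = x.std()
    if sx == 0:
        return math.nan
    # both ends have the same marginal, so sx == sy
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sx))


def clustering_and_density(net: BinaryNetwork) -> tuple[float, float, float]:
    """Global clustering C, density-normalised clustering gamma, density P.

    C is the transitivity ratio 3*(#triangles)/(#triples) with
    #triples = sum_i k_i (k_i - 1) / 2; P = 2m / (n (n-1)); gamma = C / P.
    """
    n = net.n
    if n < 2:
        return math.nan, math.nan, math.nan
    P = 2.0 * net.m / (n * (n - 1))
    k = net.degrees()
    triples = float((k * (k - 1)).sum()) / 2.0
    if triples == 0:
        C = 0.0
    else:
        a = net.a.astype(np.int64)
        triangles = np.trace(a @ a @ a) / 6.0
        C = 3.0 * triangles / triples
    gamma = C / P if P > 0 else math.nan
    return float(C), float(gamma), float(P)


def characteristic_path_length(net: BinaryNetwork) -> float:
    """Mean shortest-path length over all unordered node pairs.

    Disconnected graphs are restricted to their largest connected component
    with a warning; connectomes at ~36% density are connected, null-model
    replicates occasionally are not.
    """
    if net.n < 2:
        return math.nan
    g = nx.from_numpy_array(net.a)
    if not nx.is_connected(g):
        warnings.warn("graph disconnected; path length restricted to largest component")
        g = g.subgraph(max(nx.connected_components(g), key=len))
        if g.number_of_nodes() < 2:
            return math.nan
    return float(nx.average_shortest_path_length(g))


def mean_rich_club(net: BinaryNetwork) -> float:
    """Mean of the (unnormalised) rich-club coefficient over degree levels.

    phi(k) = 2 E_{>k} / (N_{>k} (N_{>k} - 1)) where N_{>k} counts nodes of
    degree > k and E_{>k} the edges among them; averaged over
    k = 1 .. k_max - 1 restricted to levels with N_{>k} >= 2.  NaN when no
    level is eligible.  No randomised-graph normalisation is applied; the
    raw coefficient is reported.
    """
    if net.n == 0:
        return math.nan
    k = net.degrees()
    kmax = int(k.max(initial=0))
    phis = []
    for level in range(1, kmax):
        rich = k > level
        nr = int(rich.sum())
        if nr < 2:
            continue
        er = int(net.a[np.ix_(rich, rich)].sum()) // 2
        phis.append(2.0 * er / (nr * (nr - 1)))
    return float(np.mean(phis)) if phis else math.nan


@dataclass
class IndexReport:
    """All scalar indices of one network, in the report key order."""

    R: float
    V: float
    r: float
    C: float
    gamma: float
    P: float
    L: float
    rc_mean: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def compute_index_report(net: BinaryNetwork, paths: bool = True) -> IndexReport:
    """Compute every index for one binary network.

    ``paths=False`` skips the path-based indices (L, rich-club mean) and
    reports NaN for them, which is convenient for large null ensembles
    where only the closed-form indices are needed.
    """
    C, gamma, P = clustering_and_density(net)
    return IndexReport(
        R=hierarchical_complexity(net),
        V=degree_variance(net),
        r=assortativity(net),
        C=C,
        gamma=gamma,
        P=P,
        L=characteristic_path_length(net) if paths else math.nan,
        rc_mean=mean_rich_club(net) if paths else math.nan,
    )
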