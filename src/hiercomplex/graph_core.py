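"""Graph containers, degree machinery and cohort-level network construction.

Networks are stored as dense symmetric adjacency matrices with per-node
region-of-interest (ROI) labels, which is the natural representation for
connectomes of ~100 nodes at ~36% density.  The degree machinery exposes
the ordered neighbourhood degree sequences on which the hierarchical
complexity statistic is built.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WeightedNetwork",
    "BinaryNetwork",
    "DegreeStructure",
    "Cohort",
    "degree_structure",
    "group_threshold",
]


def _default_labels(n: int) -> list[str]:
    return [f"roi{i:03d}" for i in range(n)]


def _check_square_symmetric(a: np.ndarray, name: str) -> None:
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"{name} must be a square matrix, got shape {a.shape}")
    bad = np.argwhere(~np.isclose(a, a.T))
    if bad.size:
        i, j = bad[0]
        raise ValueError(f"{name} not symmetric: entry ({i},{j}) != ({j},{i})")
    if np.any(np.diagonal(a) != 0):
        raise ValueError(f"{name} has nonzero diagonal (self-connections)")


@dataclass
class WeightedNetwork:
    """Weighted undirected network with edge weights in [0, 1].

    Weights are fractional-anisotropy-like: symmetric, zero diagonal,
    bounded in the unit interval.  `hemis` optionally tags each node with
    a hemisphere ('L', 'R' or 'midline').
    """

    w: np.ndarray
    labels: list[str] = field(default_factory=list)
    hemis: list[str] | None = None

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        _check_square_symmetric(self.w, "weight matrix")
        if np.any(self.w < 0) or np.any(self.w > 1):
            raise ValueError("edge weights must lie in [0, 1]")
        if not self.labels:
            self.labels = _default_labels(self.n)
        if len(self.labels) != self.n:
            raise ValueError("label count does not match node count")

    @property
    def n(self) -> int:
        return self.w.shape[0]

    def binarise(self) -> "BinaryNetwork":
        """Binary topology: every strictly positive weight becomes an edge."""
        return BinaryNetwork((self.w > 0).astype(np.int8), list(self.labels), self.hemis)


@dataclass
class BinaryNetwork:
    """Simple undirected graph as a symmetric 0/1 adjacency matrix."""

    a: np.ndarray
    labels: list[str] = field(default_factory=list)
    hemis: list[str] | None = None

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a)
        _check_square_symmetric(self.a, "adjacency matrix")
        if not np.isin(self.a, (0, 1)).all():
            raise ValueError("adjacency must be binary")
        self.a = self.a.astype(np.int8)
        if not self.labels:
            self.labels = _default_labels(self.n)
        if len(self.labels) != self.n:
            raise ValueError("label count does not match node count")

    @property
    def n(self) -> int:
        return self.a.shape[0]

    @property
    def m(self) -> int:
        """Number of edges (unordered pairs)."""
        return int(self.a.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.a.sum(axis=1).astype(np.int64)

    def edge_list(self) -> np.ndarray:
        """(m, 2) array of unordered edges with i < j, lexicographic."""
        return np.argwhere(np.triu(self.a, k=1)).astype(np.int64)


@dataclass
class DegreeStructure:
    """Degrees, degree classes and ordered neighbourhood degree sequences.

    For each node i of degree p the neighbourhood degree sequence ``seqs[i]``
    lists the degrees of i's neighbours sorted ascending.  ``posmeans[p][j]``
    is the mean of the (j+1)-th entries over all nodes of degree p (the
    positional mean mu_p of the degree class).
    """

    K: np.ndarray
    distinct: np.ndarray
    D: int
    classes: dict[int, list[int]]
    seqs: dict[int, np.ndarray]
    posmeans: dict[int, np.ndarray]


def degree_structure(net: BinaryNetwork) -> DegreeStructure:
    """Compute the full degree structure of a binary network.

    Sequences are sorted ascending; any fixed consistent order yields the
    same positional variances, ascending is the convention used throughout.
    """
    k = net.degrees()
    distinct = np.unique(k)
    classes: dict[int, list[int]] = {
        int(p): np.flatnonzero(k == p).tolist() for p in distinct
    }
    seqs = {
        int(i): np.sort(k[net.a[i].astype(bool)]) for i in range(net.n)
    }
    posmeans: dict[int, np.ndarray] = {}
    for p, nodes in classes.items():
        if p > 0:
            posmeans[p] = np.mean([seqs[i] for i in nodes], axis=0)
    return DegreeStructure(
        K=k, distinct=distinct, D=len(distinct), classes=classes,
        seqs=seqs, posmeans=posmeans,
    )


@dataclass
class Cohort:
    """Ordered list of networks sharing node count and label order."""

    subjects: list
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.ids:
            self.ids = [f"sub-{i + 1:03d}" for i in range(len(self.subjects))]
        if len(self.ids) != len(self.subjects):
            raise ValueError("subject id count does not match subject count")
        if self.subjects:
            ref = self.subjects[0].labels
            for s, sid in zip(self.subjects, self.ids):
                if s.labels != ref:
                    raise ValueError(f"subject {sid} has inconsistent node labels")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    @property
    def labels(self) -> list[str]:
        return self.subjects[0].labels if self.subjects else []


def group_threshold(cohort: Cohort, fraction: float = 2.0 / 3.0) -> Cohort:
    """Group-consistency thresholding and binarisation of a weighted cohort.

    An unordered pair (i, j) survives in subject s iff the subject itself
    has a positive weight there AND the pair carries a positive weight in
    at least ``fraction`` of all subjects (inclusive comparison, reading
    "at least two-thirds" literally).  The output networks are binary with
    the diagonal removed.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    support = np.sum([s.w > 0 for s in cohort.subjects], axis=0)
    keep = support >= fraction * len(cohort)
    np.fill_diagonal(keep, False)
    subs = [
        BinaryNetwork(((s.w > 0) & keep).astype(np.int8), list(s.labels), s.hemis)
        for s in cohort.subjects
    ]
    return Cohort(subs, list(cohort.ids))


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=3)
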