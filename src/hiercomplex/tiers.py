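"""Degree-based tier decomposition and neighbourhood/tier profiling.

Each network is split into T tiers (4 or 8) of decreasing degree
magnitude: Tier 1 holds the highest-degree (hub) nodes, the last tier the
most peripheral.  Two readings of "top 100/T%" exist and both are
implemented behind a mode switch:

* ``mode="degree"`` (default): the distinct degree VALUES are sorted
  descending and partitioned into T contiguous blocks of round(D/T)
  values (the last block absorbs the remainder); a node's tier is its
  degree's block.
* ``mode="node"``: the nodes themselves, sorted by degree descending, are
  partitioned into T blocks of round(n/T) nodes; same-degree nodes may
  straddle a boundary and are assigned by stable rank order.

Tiers are per-subject constructs: degree magnitudes differ across
subjects, so a regional consistency analysis (modal tier in more than a
threshold fraction of subjects) maps them back to named ROIs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graph_core import BinaryNetwork, degree_structure
from .indices import degree_range_complexity

__all__ = [
    "TierAssignment",
    "TierProfile",
    "ConsistencyTable",
    "assign_tiers",
    "tier_hierarchical_complexity",
    "region_tier_consistency",
    "neighbourhood_degree_variance",
    "tier_connectivity_profile",
]


@dataclass
class TierAssignment:
    """Partition of a network's nodes into degree tiers.

    ``boundaries[t]`` is the set of distinct degree values in tier t+1
    (descending blocks); ``node_tier[i]`` the 1-based tier of node i;
    ``Nk[t]`` the node count of tier t+1.  ``mode`` records which reading
    of the tier definition produced the assignment.
    """

    T: int
    boundaries: list[list[int]]
    node_tier: np.ndarray
    Nk: np.ndarray
    mode: str

    @property
    def n_tiers(self) -> int:
        return len(self.boundaries)


def _block_sizes(total: int, T: int) -> list[int]:
    """T contiguous block sizes: round(total/T) each, last takes the rest."""
    size = int(math.floor(total / T + 0.5))
    sizes = []
    left = total
    for t in range(T):
        if t == T - 1 or left <= size:
            sizes.append(left)
            left = 0
            break
        sizes.append(size)
        left -= size
    return [s for s in sizes if s > 0]


def assign_tiers(net: BinaryNetwork, T: int = 4, mode: str = "degree") -> TierAssignment:
    """Split a network into T degree tiers (Tier 1 = highest degrees).

    With fewer distinct degrees than tiers (degree mode) the partition
    degenerates to fewer, possibly singleton, blocks with a warning.  When
    the number of distinct degrees is divisible by 2T, the 2T-tier blocks
    nest pairwise inside the T-tier blocks.
    """
    if T not in (4, 8):
        raise ValueError("T must be 4 or 8")
    if net.n == 0:
        raise ValueError("empty network")
    k = net.degrees()
    if mode == "degree":
        distinct = np.unique(k)[::-1]  # descending
        D = len(distinct)
        if D < T:
            warnings.warn(f"only {D} distinct degrees for {T} tiers; "
                          "partition degenerates to singleton blocks")
        sizes = _block_sizes(D, T)
        boundaries, start = [], 0
        for s in sizes:
            boundaries.append([int(d) for d in distinct[start:start + s]])
            start += s
        node_tier = np.empty(net.n, dtype=np.int64)
        for t, block in enumerate(boundaries, start=1):
            node_tier[np.isin(k, block)] = t
    elif mode == "node":
        order = np.lexsort((np.arange(net.n), -k))  # degree desc, stable
        sizes = _block_sizes(net.n, T)
        node_tier = np.empty(net.n, dtype=np.int64)
        start = 0
        for t, s in enumerate(sizes, start=1):
            node_tier[order[start:start + s]] = t
            start += s
        boundaries = [
            sorted({int(d) for d in k[node_tier == t]}, reverse=True)
            for t in range(1, len(sizes) + 1)
        ]
    else:
        raise ValueError(f"unknown tier mode {mode!r}")
    Nk = np.bincount(node_tier, minlength=len(boundaries) + 1)[1:]
    return TierAssignment(T=T, boundaries=boundaries, node_tier=node_tier,
                          Nk=Nk, mode=mode)


def tier_hierarchical_complexity(net: BinaryNetwork,
                                 assignment: TierAssignment) -> np.ndarray:
    """Per-tier degree-specific hierarchical complexity.

    Entry t-1 is the mean positional-variance term over the degree values
    of tier t; NaN where no degree class in the tier has two members.
    """
    out = np.empty(assignment.n_tiers)
    for t, block in enumerate(assignment.boundaries):
        out[t] = degree_range_complexity(net, block) if block else math.nan
    return out


@dataclass
class ConsistencyTable:
    """Per-ROI modal tier across subjects and strict-majority assignment."""

    table: pd.DataFrame  # columns: roi, hemisphere, modal_tier, fraction, assigned_tier

    def assigned(self) -> pd.DataFrame:
        return self.table[self.table.assigned_tier != "unclassified"]


def region_tier_consistency(assignments: list[TierAssignment],
                            labels: list[str],
                            hemis: list[str] | None = None,
                            threshold: float = 2.0 / 3.0) -> ConsistencyTable:
    """Assign each ROI to the tier it occupies in > threshold of subjects.

    The comparison is strict ("more than two thirds"): with 3 subjects an
    ROI in Tier 1 twice is NOT assigned (2 > 2 is false).  ROIs meeting
    the bar in no tier are reported as unclassified.
    """
    if not assignments:
        raise ValueError("empty cohort of tier assignments")
    S = len(assignments)
    tiers = np.vstack([a.node_tier for a in assignments])  # S x n
    rows = []
    for i, roi in enumerate(labels):
        counts = np.bincount(tiers[:, i])
        modal = int(counts.argmax())
        frac = counts[modal] / S
        assigned = f"Tier {modal}" if counts[modal] > threshold * S else "unclassified"
        rows.append({
            "roi": roi,
            "hemisphere": hemis[i] if hemis else "",
            "modal_tier": modal,
            "fraction": frac,
            "assigned_tier": assigned,
        })
    return ConsistencyTable(pd.DataFrame(rows))


def neighbourhood_degree_variance(net: BinaryNetwork, node: int) -> float:
    """Sample variance of the degrees of a node's neighbours.

    NaN for nodes of degree < 2 (variance of fewer than two values is
    undefined).
    """
    nbrs = net.a[node].astype(bool)
    if nbrs.sum() < 2:
        return math.nan
    return float(np.var(net.degrees()[nbrs], ddof=1))


@dataclass
class TierProfile:
    """Observed vs expected tier composition of one node's neighbourhood."""

    node: str
    si: np.ndarray
    Vi: float
    nik: np.ndarray
    observed: np.ndarray
    expected: np.ndarray


def tier_connectivity_profile(net: BinaryNetwork, assignment: TierAssignment,
                              node: int) -> TierProfile:
    """Fraction of a node's neighbours in each tier vs the whole-network mix.

    observed[t] = n_ik / sum_k n_ik counts the node's neighbours (self
    excluded) in tier t+1; expected[t] = N_k / sum_k N_k is the network-wide
    tier composition, identical for every node of the same network.
    Isolated nodes yield an all-NaN observed vector with a warning.
    """
    ds = degree_structure(net)
    nbrs = np.flatnonzero(net.a[node])
    ntiers = assignment.n_tiers
    nik = np.bincount(assignment.node_tier[nbrs], minlength=ntiers + 1)[1:].astype(float)
    if nik.sum() == 0:
        warnings.warn(f"node {node} is isolated; observed fractions undefined")
        observed = np.full(ntiers, math.nan)
    else:
        observed = nik / nik.sum()
    expected = assignment.Nk / assignment.Nk.sum()
    return TierProfile(
        node=net.labels[node],
        si=ds.seqs[node],
        Vi=neighbourhood_degree_variance(net, node),
        nik=nik,
        observed=observed,
        expected=expected,
    )
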