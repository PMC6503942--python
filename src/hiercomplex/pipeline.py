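"""End-to-end analysis pipeline over a connectome cohort.

Runs the full sequence: group thresholding and binarisation, per-subject
index reports, matched null ensembles (Erdős–Rényi, 3D random geometric,
configuration rewiring) with their reports, 4- and 8-tier decomposition
with per-tier complexity and cohort effect sizes, regional tier
consistency, neighbourhood degree variance and tier connectivity
profiles, and cohort-level group comparisons and index correlations.
Every stochastic step derives its seed from the run seed; repeated runs
with identical configuration produce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .graph_core import BinaryNetwork, Cohort, group_threshold
from .indices import compute_index_report
from .io import reports_frame, write_manifest
from .null_models import configuration_rewire, er_random, rgg_3d
from .stats import compare_groups, index_correlations
from .synthetic import SyntheticParams, simulate_cohort
from .tiers import (assign_tiers, neighbourhood_degree_variance,
                    region_tier_consistency, tier_connectivity_profile,
                    tier_hierarchical_complexity)

__all__ = ["RunConfig", "run_analysis", "null_ensemble_reports"]

log = logging.getLogger("hiercomplex")

NULL_KINDS = ("er", "rgg", "config")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``simulate`` supplies synthetic-cohort parameters or the caller
    passes a loaded cohort to :func:`run_analysis` directly.  The seed
    governs every stochastic stage (cohort generation and null models).
    """

    seed: int = 0
    out: str | Path | None = None
    simulate: SyntheticParams | None = None
    consistency_threshold: float = 2.0 / 3.0
    group_fraction: float = 2.0 / 3.0
    tier_counts: tuple[int, ...] = (4, 8)
    tier_mode: str = "degree"
    null_kinds: tuple[str, ...] = NULL_KINDS
    swaps_per_edge: int = 10
    paths: bool = True  # compute L and rich-club (slower) per network

    def digest(self) -> str:
        payload = {k: (asdict(v) if isinstance(v, SyntheticParams) else str(v))
                   for k, v in asdict(self).items()}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def null_ensemble_reports(binaries: list[BinaryNetwork], kind: str, seed: int,
                          swaps_per_edge: int = 10, paths: bool = True):
    """Matched null networks and their index reports, one per input network."""
    nets, reports = [], []
    for i, net in enumerate(binaries):
        s = seed + i
        if kind == "er":
            null = er_random(net.n, net.m, seed=s)
        elif kind == "rgg":
            null, _ = rgg_3d(net.n, net.m, seed=s)
        elif kind == "config":
            null = configuration_rewire(net, seed=s, swaps_per_edge=swaps_per_edge)
        else:
            raise ValueError(f"unknown null kind {kind!r}")
        nets.append(null)
        reports.append(compute_index_report(null, paths=paths))
    return nets, reports


def _stage(name: str, start: float) -> None:
    log.info("stage=%s wall=%.2fs", name, time.perf_counter() - start)


def _padded_tier_R(net, assignment, T: int) -> np.ndarray:
    """Per-tier complexity padded with NaN to length T (degenerate splits
    of small or regular networks can yield fewer blocks)."""
    vals = tier_hierarchical_complexity(net, assignment)
    out = np.full(T, np.nan)
    out[: len(vals)] = vals
    return out


def run_analysis(config: RunConfig, cohort: Cohort | None = None) -> dict:
    """Execute the full pipeline; returns the result bundle as a dict.

    With ``config.out`` set, every table is also written as CSV plus a
    JSON manifest carrying the seed and a configuration hash.
    """
    t0 = time.perf_counter()
    if cohort is None:
        if config.simulate is None:
            raise ValueError("need either a cohort or simulate parameters")
        params = config.simulate
        params.seed = config.seed
        cohort = simulate_cohort(params)
    _stage("cohort", t0)

    binary = group_threshold(cohort, config.group_fraction)
    _stage("group_threshold", t0)

    reports = [compute_index_report(b, paths=config.paths) for b in binary]
    _stage("indices", t0)

    nulls: dict[str, list[BinaryNetwork]] = {}
    null_reports: dict[str, list] = {}
    for j, kind in enumerate(config.null_kinds):
        nulls[kind], null_reports[kind] = null_ensemble_reports(
            binary.subjects, kind, seed=config.seed + 10_000 * (j + 1),
            swaps_per_edge=config.swaps_per_edge, paths=config.paths)
        _stage(f"nulls:{kind}", t0)

    # per-tier complexity of cohort and config rewirings, with effect sizes
    tier_tables: dict[int, pd.DataFrame] = {}
    consistency = {}
    for T in config.tier_counts:
        assigns = [assign_tiers(b, T, mode=config.tier_mode) for b in binary]
        tier_R = np.vstack([_padded_tier_R(b, a, T)
                            for b, a in zip(binary, assigns)])
        rows = []
        if "config" in nulls:
            cfg_assigns = [assign_tiers(g, T, mode=config.tier_mode)
                           for g in nulls["config"]]
            cfg_R = np.vstack([_padded_tier_R(g, a, T)
                               for g, a in zip(nulls["config"], cfg_assigns)])
            for t in range(tier_R.shape[1]):
                x = tier_R[:, t][~np.isnan(tier_R[:, t])]
                y = cfg_R[:, t][~np.isnan(cfg_R[:, t])]
                if len(x) >= 2 and len(y) >= 2:
                    gc = compare_groups(x, y)
                    rows.append({"tier": t + 1, "mean_cohort": x.mean(),
                                 "mean_config": y.mean(), "t": gc.t, "p": gc.p,
                                 "d": gc.d, "n1": gc.n1, "n2": gc.n2})
                else:
                    rows.append({"tier": t + 1, "mean_cohort": np.nan,
                                 "mean_config": np.nan, "t": np.nan,
                                 "p": np.nan, "d": np.nan,
                                 "n1": len(x), "n2": len(y)})
        tier_tables[T] = pd.DataFrame(rows)
        consistency[T] = region_tier_consistency(
            assigns, binary.labels, binary.subjects[0].hemis,
            config.consistency_threshold)
        _stage(f"tiers:{T}", t0)

    # neighbourhood degree variance and tier profiles (4-tier assignment)
    assigns4 = [assign_tiers(b, 4, mode=config.tier_mode) for b in binary]
    vi = np.vstack([[neighbourhood_degree_variance(b, i) for i in range(b.n)]
                    for b in binary])
    profiles = []
    for b, a, sid in zip(binary, assigns4, binary.ids):
        for i in range(b.n):
            pr = tier_connectivity_profile(b, a, i)
            row = {"subject": sid, "roi": pr.node, "Vi": pr.Vi}
            for t in range(len(pr.observed)):
                row[f"obs_t{t + 1}"] = pr.observed[t]
                row[f"exp_t{t + 1}"] = pr.expected[t]
            profiles.append(row)
    profile_df = pd.DataFrame(profiles)
    _stage("profiles", t0)

    # cohort vs null comparisons per index, and index correlations
    comp_rows = []
    frame = reports_frame(reports)
    for kind in config.null_kinds:
        nf = reports_frame(null_reports[kind])
        for col in frame.columns:
            x, y = frame[col].dropna(), nf[col].dropna()
            if len(x) >= 2 and len(y) >= 2 and (x.std() > 0 or y.std() > 0):
                gc = compare_groups(x, y)
                comp_rows.append({"index": col, "group1": "cohort",
                                  "group2": kind, "t": gc.t, "p": gc.p,
                                  "d": gc.d, "n1": gc.n1, "n2": gc.n2})
    comparisons = pd.DataFrame(comp_rows)
    correlations = index_correlations(reports) if len(reports) >= 3 else None
    _stage("stats", t0)

    bundle = {
        "binary": binary,
        "reports": frame,
        "null_reports": {k: reports_frame(v) for k, v in null_reports.items()},
        "tier_effects": tier_tables,
        "consistency": consistency,
        "neighbourhood_variance": pd.DataFrame(
            vi, index=binary.ids, columns=binary.labels),
        "profiles": profile_df,
        "comparisons": comparisons,
        "correlations": correlations,
    }

    if config.out is not None:
        out = Path(config.out)
        out.mkdir(parents=True, exist_ok=True)
        frame.assign(subject=binary.ids).to_csv(out / "indices_cohort.csv", index=False)
        for k, df in bundle["null_reports"].items():
            df.to_csv(out / f"indices_null_{k}.csv", index=False)
        for T, df in tier_tables.items():
            df.to_csv(out / f"tier_effects_{T}.csv", index=False)
            consistency[T].table.to_csv(out / f"consistency_{T}.csv", index=False)
        bundle["neighbourhood_variance"].to_csv(out / "neighbourhood_variance.csv")
        profile_df.to_csv(out / "tier_profiles.csv", index=False)
        comparisons.to_csv(out / "comparisons.csv", index=False)
        if correlations is not None:
            correlations.to_csv(out / "index_correlations.csv")
        write_manifest(out / "manifest.json", seed=config.seed,
                       config_hash=config.digest(),
                       tier_mode=config.tier_mode,
                       null_kinds=list(config.null_kinds),
                       subjects=len(binary), n=binary.subjects[0].n,
                       rich_club="unnormalised mean over eligible k")
    _stage("done", t0)
    return bundle
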