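"""File I/O: delimited adjacency matrices, label sidecars, cohorts, reports.

The interchange format is plain delimited text: one n x n symmetric
matrix per subject (comma- or tab-separated, optional single header row
of ROI labels) plus a two-column label sidecar (label, hemisphere).
Validation failures name the offending file and matrix entry.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .graph_core import Cohort, WeightedNetwork
from .indices import IndexReport

__all__ = [
    "read_matrix", "write_matrix", "read_labels", "write_labels",
    "load_cohort", "save_cohort", "reports_frame", "write_manifest",
]


def _sniff_delimiter(path: Path) -> str:
    first = path.read_text().splitlines()[0]
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str] | None]:
    """Read a delimited square matrix; returns (matrix, header labels or None).

    Accepts comma- and tab-separated files; a non-numeric first row is
    treated as the ROI label header.
    """
    path = Path(path)
    sep = _sniff_delimiter(path)
    first = path.read_text().splitlines()[0].split(sep)
    try:
        [float(x) for x in first]
        header = None
    except ValueError:
        header = 0
    df = pd.read_csv(path, sep=sep, header=header)
    labels = [str(c) for c in df.columns] if header == 0 else None
    mat = df.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{path.name}: matrix is {mat.shape[0]}x{mat.shape[1]}, not square")
    return mat, labels


def write_matrix(path: str | Path, w: np.ndarray, labels: list[str] | None = None,
                 sep: str = ",") -> None:
    df = pd.DataFrame(w, columns=labels if labels else None)
    df.to_csv(path, sep=sep, index=False, header=labels is not None,
              float_format="%.6g")


def read_labels(path: str | Path) -> tuple[list[str], list[str]]:
    """Two-column sidecar: label, hemisphere in {L, R, midline}."""
    df = pd.read_csv(path, sep=None, engine="python", header=None,
                     names=["label", "hemisphere"])
    hemis = [str(h) for h in df.hemisphere]
    bad = set(hemis) - {"L", "R", "midline"}
    if bad:
        raise ValueError(f"{Path(path).name}: unknown hemisphere tags {sorted(bad)}")
    return [str(x) for x in df.label], hemis


def write_labels(path: str | Path, labels: list[str], hemis: list[str]) -> None:
    pd.DataFrame({"label": labels, "hemisphere": hemis}).to_csv(
        path, index=False, header=False)


def load_cohort(directory: str | Path, pattern: str = "*.csv") -> Cohort:
    """Load every matrix file in a directory as one weighted cohort.

    Files are taken in sorted name order; a `labels.txt`/`labels.tsv`
    sidecar, if present, supplies ROI labels and hemisphere tags.
    Symmetry, zero diagonals and the [0, 1] weight range are validated
    per file, and errors are reported with the filename.
    """
    directory = Path(directory)
    sidecar = None
    for cand in ("labels.txt", "labels.tsv", "labels.csv"):
        if (directory / cand).exists():
            sidecar = read_labels(directory / cand)
            break
    files = sorted(p for p in directory.glob(pattern)
                   if not p.name.startswith("labels"))
    if not files:
        raise FileNotFoundError(f"no matrix files matching {pattern} in {directory}")
    subjects, ids = [], []
    for f in files:
        mat, header = read_matrix(f)
        labels = header or (sidecar[0] if sidecar else [])
        hemis = sidecar[1] if sidecar else None
        try:
            subjects.append(WeightedNetwork(mat, list(labels), hemis))
        except ValueError as e:
            raise ValueError(f"{f.name}: {e}") from e
        ids.append(f.stem)
    return Cohort(subjects, ids)


def save_cohort(directory: str | Path, cohort: Cohort,
                hemis: list[str] | None = None) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for sid, net in zip(cohort.ids, cohort.subjects):
        w = net.w if isinstance(net, WeightedNetwork) else net.a
        write_matrix(directory / f"{sid}.csv", w, net.labels)
    hemis = hemis or getattr(cohort.subjects[0], "hemis", None)
    if hemis:
        write_labels(directory / "labels.txt", cohort.labels, hemis)


def reports_frame(reports: list[IndexReport], ids: list[str] | None = None
                  ) -> pd.DataFrame:
    """One row per network, keys exactly R, V, r, C, gamma, P, L, rc_mean."""
    df = pd.DataFrame([r.as_dict() for r in reports])
    if ids is not None:
        df.insert(0, "subject", ids)
    return df


def write_manifest(path: str | Path, **entries) -> None:
    """JSON manifest recording seeds and configuration alongside outputs."""
    Path(path).write_text(json.dumps(entries, indent=2, default=str) + "\n")
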