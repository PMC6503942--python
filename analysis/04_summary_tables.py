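"""Assemble the headline summary tables from the pipeline outputs.

Reads the per-network index tables written by 02/03 and produces (i) the
index table analogue — mean +- SD of each index for the synthetic cohort
and the three null models — and (ii) the correlation ranking showing how
correlated each index is with the others across the cohort.

Run after 02 and 03:  python analysis/04_summary_tables.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    cohort = pd.read_csv(RESULTS / "pipeline" / "indices_cohort.csv")
    nulls = {k: pd.read_csv(RESULTS / "pipeline" / f"indices_null_{k}.csv")
             for k in ("config", "rgg", "er")}

    rows = []
    for name, df in [("cohort", cohort), *nulls.items()]:
        for col in ("R", "V", "r", "C", "gamma", "L", "rc_mean"):
            rows.append({"group": name, "index": col,
                         "mean": df[col].mean(), "sd": df[col].std()})
    table = pd.DataFrame(rows).pivot(index="index", columns="group",
                                     values=["mean", "sd"])
    table.to_csv(RESULTS / "index_table.csv")

    print("index table (mean +- SD):")
    for idx in ("R", "V", "r", "C", "gamma"):
        line = f"  {idx:7s}"
        for grp in ("cohort", "config", "rgg", "er"):
            line += f"  {grp}={table.loc[idx, ('mean', grp)]:8.3f}+-{table.loc[idx, ('sd', grp)]:.3f}"
        print(line)

    corr = pd.read_csv(RESULTS / "pipeline" / "index_correlations.csv",
                       index_col=0)
    mean_abs = corr.abs().where(~np.eye(len(corr), dtype=bool)).mean(axis=1)
    ranking = mean_abs.sort_values()
    ranking.rename("mean_abs_corr").to_csv(RESULTS / "correlation_ranking.csv")
    print("\nmean |correlation| with the other indices (ascending):")
    for name, val in ranking.items():
        print(f"  {name:8s} {val:.3f}")
    print(f"least correlated index: {ranking.index[0]}")


if __name__ == "__main__":
    main()
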