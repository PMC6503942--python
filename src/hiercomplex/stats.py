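"""Cohort-level inferential statistics.

Two-sample comparisons of network-index distributions (Student t-test
with pooled variance, Cohen's d) and the Pearson correlation structure of
the indices across a cohort.  p-values are reported raw, without
multiple-testing correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .indices import IndexReport

__all__ = ["GroupComparison", "compare_groups", "index_correlations",
           "CORRELATION_INDICES"]

CORRELATION_INDICES = ["R", "V", "r", "C", "gamma", "L", "rc_mean"]


@dataclass
class GroupComparison:
    t: float
    p: float
    d: float
    n1: int
    n2: int


def compare_groups(x, y, welch: bool = False) -> GroupComparison:
    """Two-sample t-test and Cohen's d for two samples of index values.

    The default is the pooled-variance Student t-test, consistent with
    Cohen's d whose denominator is the pooled standard deviation
    sqrt(((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2)).  ``welch=True`` switches
    the test (not d) to the unequal-variance form.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("both samples need at least two observations")
    t, p = sps.ttest_ind(x, y, equal_var=not welch)
    pooled = math.sqrt(((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1))
                       / (n1 + n2 - 2))
    d = (x.mean() - y.mean()) / pooled if pooled > 0 else math.nan
    return GroupComparison(t=float(t), p=float(p), d=d, n1=n1, n2=n2)


def index_correlations(reports: list[IndexReport],
                       indices: list[str] | None = None) -> pd.DataFrame:
    """Pearson correlation matrix of index values across a cohort.

    Rows/columns follow ``indices`` (default: R, V, r, C, gamma, L,
    rc_mean).  An index constant across the cohort yields NaN in its row
    and column; the diagonal is 1 for non-constant indices.
    """
    if len(reports) < 3:
        raise ValueError("need at least three networks to correlate indices")
    cols = indices or CORRELATION_INDICES
    df = pd.DataFrame([r.as_dict() for r in reports])[cols]
    corr = df.corr()
    np.fill_diagonal(corr.values, np.where(df.std().values > 0, 1.0, np.nan))
    return corr
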