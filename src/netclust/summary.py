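"""Cohort-description utilities: group tests computable from summary statistics.

Descriptive conveniences for demographic tables (group n/mean/sd rows and 2x2
categorical counts); they are not part of the cluster statistic's claims.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def welch_t_from_summary(
    n1: int, mean1: float, sd1: float,
    n2: int, mean2: float, sd2: float,
) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sample t-test from group summaries.

    Returns (t, Welch-Satterthwaite df, two-sided p).  With both sds zero and
    equal means, t = 0 and p = 1 by convention (df is NaN: undefined).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    v1, v2 = sd1 ** 2 / n1, sd2 ** 2 / n2
    se2 = v1 + v2
    if se2 == 0:
        if mean1 == mean2:
            return 0.0, float("nan"), 1.0
        raise ValueError("zero variance with unequal means: t undefined")
    t = (mean1 - mean2) / np.sqrt(se2)
    df = se2 ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def yates_chi2(table) -> tuple[float, float]:
    """Continuity-corrected chi-square test on a 2x2 count table.

    Statistic: sum over cells of (max(|O - E| - 0.5, 0))^2 / E, referred to a
    chi-square with 1 df.  The truncation at zero makes perfectly proportional
    tables score exactly 0.  Invariant under transposition and row/column
    swaps.
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if (table < 0).any() or not np.allclose(table, np.round(table)):
        raise ValueError("counts must be non-negative integers")
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    total = table.sum()
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero row or column margin")
    expected = np.outer(row, col) / total
    d = np.maximum(np.abs(table - expected) - 0.5, 0.0)
    chi2 = float((d ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p
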