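"""Statistical pipeline for the spatiotemporal DF-stability study.

Per geometry ("patient"), the windows x sections table of % High DF Area is
tested for spatial consistency with a Friedman rank test (sections as
treatments, windows as blocks).  Temporal instability per section is the
coefficient of variation of its % High DF Area across windows; sections are
compared with Kruskal-Wallis, and the PV/appendage/peri-mitral group is
compared against the remaining walls with a Welch t-test.  Ablation outcomes
(maintained vs changed-or-terminated, by ablation extent) are compared with
a Pearson chi-square test.  Standard tests are delegated to scipy.stats;
every operation is checked against an independent formula or permutation
oracle in the test suite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "temporal_cov", "friedman_consistency", "kruskal_regions",
    "grouped_cov_ttest", "chi_square_outcomes",
    "GROUP_UNSTABLE", "GROUP_STABLE",
]

#: Sections grouped in the t-test: PVs (R7-R10), appendage (R3),
#: peri-mitral (R4) vs the remaining walls.
GROUP_UNSTABLE = (3, 4, 7, 8, 9, 10)
GROUP_STABLE = (1, 2, 5, 6)


def temporal_cov(series) -> float:
    """Temporal coefficient of variation: 100 * sample SD / mean (%).

    Returns NaN (flagged undefined) when the mean is zero; such series are
    excluded from downstream tests.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 values for a CoV")
    m = x.mean()
    if m == 0:
        return float("nan")
    return float(100.0 * x.std(ddof=1) / m)


def friedman_consistency(table) -> tuple[float, float]:
    """Friedman rank test of spatial consistency for one geometry.

    ``table``: windows x regions array (rows = blocks, columns = treatments).
    Returns (chi-square statistic with average-rank tie correction, p).
    A table whose rows rank identically in no direction (all values equal)
    returns (0.0, 1.0).
    """
    arr = np.asarray(table, dtype=float)
    if isinstance(table, pd.DataFrame):
        arr = table.to_numpy(dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 3:
        raise ValueError("need a complete windows x regions table (>= 3 regions)")
    if np.allclose(arr, arr[:, :1]):
        return 0.0, 1.0
    try:
        res = sps.friedmanchisquare(*[arr[:, j] for j in range(arr.shape[1])])
        stat, p = float(res.statistic), float(res.pvalue)
    except ValueError:
        return 0.0, 1.0
    if not np.isfinite(stat):
        return 0.0, 1.0
    return stat, p


def kruskal_regions(groups) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) across per-region CoV samples.

    ``groups``: sequence of 1-D samples (one per region).  Identical data in
    every group returns (0.0, 1.0).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    groups = [g[np.isfinite(g)] for g in groups]
    groups = [g for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    res = sps.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def grouped_cov_ttest(cov_table,
                      group_a=GROUP_UNSTABLE,
                      group_b=GROUP_STABLE) -> dict:
    """Welch t-test comparing pooled per-geometry-per-region CoVs.

    ``cov_table``: DataFrame (geometries x regions, columns "R1".."R10") or
    array with 10 columns.  Group A defaults to the PV, appendage and
    peri-mitral sections.  Returns means +- SD per group, t and p.
    """
    if isinstance(cov_table, pd.DataFrame):
        arr = cov_table.to_numpy(dtype=float)
    else:
        arr = np.asarray(cov_table, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    a = arr[:, [r - 1 for r in group_a]].ravel()
    b = arr[:, [r - 1 for r in group_b]].ravel()
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        # degenerate variance: identical constants are indistinguishable
        t, p = (0.0, 1.0) if a[0] == b[0] else (float("inf"), 0.0)
    else:
        res = sps.ttest_ind(a, b, equal_var=False)
        t, p = float(res.statistic), float(res.pvalue)
    return {
        "mean_a": float(a.mean()), "sd_a": float(a.std(ddof=1)) if len(a) > 1 else 0.0,
        "mean_b": float(b.mean()), "sd_b": float(b.std(ddof=1)) if len(b) > 1 else 0.0,
        "t": t, "p": p, "n_a": int(len(a)), "n_b": int(len(b)),
    }


def chi_square_outcomes(table) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on an outcomes table.

    ``table``: fractions x {maintained, changed-or-terminated} counts,
    e.g. shape (3, 2).  Equal rows give (0.0, 1.0).
    """
    arr = np.asarray(table, dtype=float)
    if arr.size == 0 or arr.ndim != 2:
        raise ValueError("need a 2-D contingency table")
    if np.any(arr < 0) or np.any(arr.sum(axis=1) <= 0):
        raise ValueError("counts must be >= 0 with positive row sums")
    # drop all-zero columns (chi2_contingency rejects zero expected counts)
    arr = arr[:, arr.sum(axis=0) > 0]
    if arr.shape[1] < 2:
        return 0.0, 1.0
    res = sps.chi2_contingency(arr, correction=False)
    return float(res.statistic), float(res.pvalue)
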