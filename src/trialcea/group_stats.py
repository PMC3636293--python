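"""Baseline-comparability statistics: Pearson chi-square and one-way ANOVA.

Arm comparability of proportions uses the uncorrected Pearson
chi-square on the arm-by-outcome contingency table; comparability of
means uses the one-way ANOVA F statistic.  Both are computed from their
sums-of-squares definitions (and cross-checked against scipy in the
test suite).
"""

from __future__ import annotations

import numpy as np


def chi_square(table) -> tuple[float, int]:
    """Pearson chi-square statistic and df of a contingency table.

    Expected counts come from the product of row and column margins over
    the grand total; no continuity correction is applied.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    if (row == 0).any() or (col == 0).any() or total == 0:
        raise ValueError("zero margin in contingency table")
    expected = row @ col / total
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return stat, df


def abstinence_table(counts, sizes) -> np.ndarray:
    """k x 2 table (abstinent, not abstinent) from per-arm counts and sizes."""
    counts = np.asarray(counts, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    if (counts > sizes).any():
        raise ValueError("abstinent counts cannot exceed arm sizes")
    return np.column_stack([counts, sizes - counts])


def anova_f(groups) -> tuple[float, int, int]:
    """One-way ANOVA F statistic with between/within degrees of freedom.

    F = MS_between / MS_within.  When both mean squares are zero (all
    values identical) the statistic is undefined and NaN is returned.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least two groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("every group needs at least two values")
    ns = np.array([len(a) for a in arrays])
    means = np.array([a.mean() for a in arrays])
    grand = np.concatenate(arrays).mean()
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(sum(((a - m) ** 2).sum() for a, m in zip(arrays, means)))
    df_between = len(arrays) - 1
    df_within = int(ns.sum()) - len(arrays)
    if ss_within == 0.0:
        f = np.nan if ss_between == 0.0 else np.inf
    else:
        f = (ss_between / df_between) / (ss_within / df_within)
    return float(f), df_between, df_within
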