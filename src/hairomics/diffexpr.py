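"""Group-wise differential expression on spectral counts.

Per protein: a log2 ratio of group mean counts (girls/boys,
mothers/children, ...), a Kruskal-Wallis rank test across groups, and
Benjamini-Hochberg adjustment across the tested proteins.  Spectral
counts contain many zeros, so ratios use a pseudocount (default 0.5);
a pseudocount of 0 is allowed and yields signed infinities, which are
flagged rather than hidden.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import SpectralCountMatrix

__all__ = ["log2_group_ratio", "kruskal_wallis_bh", "rank_sum_group_comparison"]


def log2_group_ratio(
    matrix: SpectralCountMatrix,
    group_a_subjects: Sequence[str],
    group_b_subjects: Sequence[str],
    pseudocount: float = 0.5,
) -> pd.Series:
    """Per-protein log2 of (group A mean / group B mean) spectral counts.

    Positive values mean higher expression in group A.  With
    ``pseudocount=0`` a group mean of zero produces +/-inf (or NaN for
    0/0); a warning counts such proteins.
    """
    a = list(group_a_subjects)
    b = list(group_b_subjects)
    overlap = set(a) & set(b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)[:5]}")
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    mean_a = matrix.counts[a].mean(axis=1)
    mean_b = matrix.counts[b].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    n_bad = int((~np.isfinite(ratio)).sum())
    if n_bad:
        warnings.warn(
            f"{n_bad} protein(s) have non-finite log ratios (zero group means "
            "with pseudocount=0)",
            stacklevel=2,
        )
    return ratio.rename("expr_log_ratio")


def kruskal_wallis_bh(
    matrix: SpectralCountMatrix,
    group_labels: pd.Series | Sequence,
    pseudocount: float = 0.5,
    group_order: Optional[Sequence] = None,
) -> pd.DataFrame:
    """Per-protein Kruskal-Wallis test with Benjamini-Hochberg correction.

    ``group_labels`` assigns each subject (matrix column) to a group;
    every group needs at least 2 subjects.  Returns a DataFrame with the
    group mean columns, ``expr_log_ratio`` (first vs second group, only
    when there are exactly two groups), tie-corrected ``raw_p``,
    step-up-adjusted ``adjusted_p``, and a ``constant`` flag for
    proteins identical across all subjects (assigned p = 1 by
    convention).
    """
    labels = pd.Series(np.asarray(group_labels), index=matrix.counts.columns)
    groups = list(group_order) if group_order is not None else sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    members = {g: list(labels.index[labels == g]) for g in groups}
    for g, ids in members.items():
        if len(ids) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")

    counts = matrix.counts
    raw_p = np.ones(len(counts))
    constant = np.zeros(len(counts), dtype=bool)
    arrays = [counts[members[g]].to_numpy() for g in groups]
    for i in range(len(counts)):
        samples = [arr[i] for arr in arrays]
        pooled = np.concatenate(samples)
        if np.all(pooled == pooled[0]):
            constant[i] = True
            continue
        raw_p[i] = stats.kruskal(*samples).pvalue
    adjusted = multipletests(raw_p, method="fdr_bh")[1]

    table = pd.DataFrame(index=counts.index)
    for g in groups:
        table[f"mean_{g}"] = counts[members[g]].mean(axis=1)
    if len(groups) == 2:
        table["expr_log_ratio"] = log2_group_ratio(
            matrix, members[groups[0]], members[groups[1]], pseudocount=pseudocount
        )
    table["raw_p"] = raw_p
    table["adjusted_p"] = adjusted
    table["constant"] = constant
    return table


def rank_sum_group_comparison(
    values_a: Sequence[float],
    values_b: Sequence[float],
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Wilcoxon-Mann-Whitney rank-sum test between two samples.

    Exact for small tie-free samples, normal approximation with tie and
    continuity corrections otherwise (scipy's ``method="auto"``).
    Returns ``(U statistic, p)``; all values tied across both samples
    gives p = 1 by convention.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return float(len(a) * len(b) / 2.0), 1.0
    res = stats.mannwhitneyu(a, b, alternative=alternative, method="auto")
    return float(res.statistic), float(res.pvalue)
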