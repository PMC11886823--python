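"""Association between enhancer functionality labels and directionality.

Given an external binary label per enhancer (e.g. significant vs
non-significant reporter-assay activity) and the absolute directionality
score computed from a designated sample's counts, test whether the two
label groups differ in directionality with a two-sided Mann-Whitney
rank-sum comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .io import validate_count_table
from .model import directionality_scores

__all__ = ["AssociationResult", "directionality_vs_label", "labeled_scores"]


@dataclass(frozen=True)
class AssociationResult:
    u_statistic: float
    p_value: float
    n_group_a: int
    n_group_b: int
    median_a: float
    median_b: float
    method: str


def directionality_vs_label(
    abs_scores, labels, exact_max_n: int = 20
) -> AssociationResult:
    """Two-sided Mann-Whitney test of |score| between two label groups.

    Rank-based, so invariant to any monotone transform of the score. The
    exact null distribution is used when both groups have at most
    ``exact_max_n`` observations and there are no ties; otherwise the
    mid-rank normal approximation with tie correction.
    """
    abs_scores = np.asarray(abs_scores, dtype=float)
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"need exactly two label groups, got {len(groups)}")
    a = abs_scores[labels == groups[0]]
    b = abs_scores[labels == groups[1]]
    if a.size == 0 or b.size == 0:
        raise ValueError("both label groups must be non-empty")
    has_ties = len(np.unique(abs_scores)) < abs_scores.size
    if max(a.size, b.size) <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return AssociationResult(
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_group_a=int(a.size),
        n_group_b=int(b.size),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        method=method,
    )


def labeled_scores(
    table: pd.DataFrame, labels: pd.DataFrame, sample_id: str
) -> pd.DataFrame:
    """Join a label table against one sample's absolute directionality scores.

    Only enhancers with at least one tag in the designated sample carry a
    defined score; others are dropped.
    """
    table = validate_count_table(table)
    sample = table[table["sample_id"] == sample_id]
    if sample.empty:
        raise KeyError(f"unknown sample id: {sample_id}")
    scores = directionality_scores(
        sample["forward"].to_numpy(), sample["reverse"].to_numpy()
    )
    df = sample.assign(abs_score=np.abs(scores)).dropna(subset=["abs_score"])
    merged = df.merge(labels, on="enhancer_id", how="inner")
    return merged[["enhancer_id", "abs_score", "label"]].reset_index(drop=True)
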