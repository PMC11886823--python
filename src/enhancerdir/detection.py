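"""Bidirectionality criterion for transcriptome-based enhancer detection.

A widely used screen keeps a candidate enhancer only if its pooled absolute
directionality score is below a threshold (default 0.8, strict) and it shows
bidirectional expression (tags on both strands) in at least one sample.
Because enhancer transcription within a single cell type is predominantly
directional, this filter can discard genuine enhancers; this module labels
each expressed candidate by which policy retains it, making the cost of the
requirement quantifiable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import validate_count_table

__all__ = ["DetectionPolicy", "classify_candidates", "detected_ids"]

PASS_BIDIRECTIONAL = "pass_bidirectional"
PASS_ONLY_WITHOUT_REQUIREMENT = "pass_only_without_requirement"


@dataclass(frozen=True)
class DetectionPolicy:
    """Parameters of the bidirectionality screen.

    ``max_abs_directionality`` is compared strictly (pooled |score| must be
    *below* it). ``min_bidirectional_samples`` counts samples with at least
    one tag on each strand.
    """

    require_bidirectional: bool = True
    max_abs_directionality: float = 0.8
    min_bidirectional_samples: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_abs_directionality <= 1.0:
            raise ValueError("max_abs_directionality must lie in [0, 1]")
        if self.min_bidirectional_samples < 0:
            raise ValueError("min_bidirectional_samples must be non-negative")


def classify_candidates(
    table: pd.DataFrame, policy: DetectionPolicy = DetectionPolicy()
) -> pd.DataFrame:
    """Partition expressed candidates by the bidirectionality criterion.

    Each enhancer with pooled F + R > 0 is labelled either
    ``pass_bidirectional`` (pooled |score| < max_abs_directionality AND at
    least min_bidirectional_samples samples with tags on both strands) or
    ``pass_only_without_requirement``. The two labels partition the
    expressed candidates, so the marginal cost of requiring bidirectional
    transcription is the size of the second group; use
    :func:`detected_ids` to apply a policy's retention rule.
    """
    table = validate_count_table(table)
    if table.empty:
        raise ValueError("count table is empty")
    bidir_per_sample = (table["forward"] > 0) & (table["reverse"] > 0)
    n_bidir = (
        table.assign(bidir=bidir_per_sample)
        .groupby("enhancer_id")["bidir"]
        .sum()
    )
    pooled = table.groupby("enhancer_id")[["forward", "reverse"]].sum()
    total = pooled["forward"] + pooled["reverse"]
    expressed = pooled[total > 0]
    total = total[total > 0]
    with np.errstate(invalid="ignore"):
        abs_score = (
            (expressed["forward"] - expressed["reverse"]).abs() / total
        )
    meets = (abs_score < policy.max_abs_directionality) & (
        n_bidir.reindex(expressed.index).fillna(0) >= policy.min_bidirectional_samples
    )
    label = np.where(meets, PASS_BIDIRECTIONAL, PASS_ONLY_WITHOUT_REQUIREMENT)
    out = pd.DataFrame(
        {
            "enhancer_id": expressed.index,
            "pooled_F": expressed["forward"].to_numpy(),
            "pooled_R": expressed["reverse"].to_numpy(),
            "pooled_abs_score": abs_score.to_numpy(),
            "n_bidirectional_samples": n_bidir.reindex(expressed.index)
            .fillna(0)
            .astype(int)
            .to_numpy(),
            "label": label,
        }
    ).reset_index(drop=True)
    return out


def detected_ids(classified: pd.DataFrame, policy: DetectionPolicy) -> set[str]:
    """Enhancer ids a policy retains from a :func:`classify_candidates` result.

    Requiring bidirectionality keeps only the ``pass_bidirectional`` group;
    dropping the requirement keeps every expressed candidate, so the
    detected set can only grow as the policy is relaxed.
    """
    if policy.require_bidirectional:
        keep = classified["label"] == PASS_BIDIRECTIONAL
        return set(classified.loc[keep, "enhancer_id"])
    return set(classified["enhancer_id"])
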