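"""Dataset-level directionality analyses.

Pooling counts across samples, directionality histograms with a fitted
beta-density overlay, expression-binned shape-parameter estimation,
hypergeometric downsampling of a count table, and the two-tag concordance
statistic used to characterise single-cell data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist
from scipy.stats import binomtest

from .io import validate_count_table
from .model import BetaBinomialFit, NotEstimableError, directionality_scores, fit_alpha

__all__ = [
    "ExpressionBin",
    "Histogram",
    "ConcordantPairResult",
    "pool_samples",
    "pool_by_group",
    "directionality_histogram",
    "binned_alpha",
    "downsample",
    "concordant_pair_count",
]


@dataclass(frozen=True)
class ExpressionBin:
    """One expression bin: enhancers of similar total depth and their fit."""

    bin_index: int
    enhancer_ids: list[str]
    expression_range: tuple[int, int]
    fit: BetaBinomialFit | None
    complete: bool


@dataclass(frozen=True)
class Histogram:
    """Directionality-score histogram plus the fitted beta-density overlay.

    Only enhancers with at least ``min_total`` tags contribute. The overlay
    is the density of d = 2p - 1 for p ~ Beta(alpha, alpha), i.e.
    0.5 * beta_pdf((d + 1)/2; alpha, alpha), scaled to the histogram area.
    """

    min_total: int
    bin_edges: np.ndarray
    counts: np.ndarray
    n_included: int
    overlay_alpha: float | None
    overlay_x: np.ndarray = field(default=None, repr=False)
    overlay_density: np.ndarray = field(default=None, repr=False)


@dataclass(frozen=True)
class ConcordantPairResult:
    """Concordance of the two tags among enhancers with exactly two tags."""

    n_two_tag: int
    n_same_direction: int
    n_split: int
    p_value: float


def pool_samples(table: pd.DataFrame, sample_ids: Sequence[str] | None = None,
                 pooled_id: str = "pooled") -> pd.DataFrame:
    """Sum stranded counts over samples into one pseudo-sample per enhancer.

    With ``sample_ids`` None, all samples are pooled. Total tags are
    conserved exactly; because of the triangle inequality the pooled
    |directionality| of an enhancer never exceeds its tag-weighted
    combination across samples.
    """
    table = validate_count_table(table)
    if sample_ids is not None:
        sample_ids = list(sample_ids)
        if not sample_ids:
            raise ValueError("sample_ids must be non-empty")
        known = set(table["sample_id"])
        unknown = [s for s in sample_ids if s not in known]
        if unknown:
            raise KeyError(f"unknown sample id(s): {', '.join(unknown)}")
        table = table[table["sample_id"].isin(sample_ids)]
    pooled = (
        table.groupby("enhancer_id", as_index=False)[["forward", "reverse"]]
        .sum()
        .assign(sample_id=pooled_id)
    )
    return validate_count_table(pooled)


def pool_by_group(table: pd.DataFrame, mapping: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-cell counts into per-group pseudo-samples.

    ``mapping`` has columns cell_id, group_id; cells absent from the mapping
    are dropped. This is how single cells roll up to clusters and clusters
    to pseudobulk.
    """
    table = validate_count_table(table)
    merged = table.merge(
        mapping.rename(columns={"cell_id": "sample_id"}), on="sample_id", how="inner"
    )
    pooled = (
        merged.groupby(["enhancer_id", "group_id"], as_index=False)[
            ["forward", "reverse"]
        ]
        .sum()
        .rename(columns={"group_id": "sample_id"})
    )
    return validate_count_table(pooled)


def directionality_histogram(
    F,
    R,
    min_total: int = 10,
    bin_edges: Sequence[float] | None = None,
    fit_overlay: bool = True,
    n_overlay_points: int = 201,
) -> Histogram:
    """Histogram of directionality scores for enhancers with >= min_total tags.

    The overlay curve is derived from the beta-binomial fit to the *same*
    included enhancers and scaled so its integral matches the histogram area.
    """
    if min_total < 1:
        raise ValueError("min_total must be at least 1")
    F = np.asarray(F, dtype=np.int64)
    R = np.asarray(R, dtype=np.int64)
    keep = (F + R) >= min_total
    scores = directionality_scores(F[keep], R[keep])
    edges = (
        np.linspace(-1.0, 1.0, 21) if bin_edges is None else np.asarray(bin_edges, float)
    )
    counts, _ = np.histogram(scores, bins=edges)
    overlay_alpha = None
    overlay_x = overlay_density = None
    if fit_overlay and keep.sum() > 0:
        try:
            overlay_alpha = fit_alpha(F[keep], R[keep]).alpha_hat
        except NotEstimableError:
            overlay_alpha = None
    if overlay_alpha is not None:
        overlay_x = np.linspace(-1.0 + 1e-9, 1.0 - 1e-9, n_overlay_points)
        density = 0.5 * beta_dist.pdf((overlay_x + 1.0) / 2.0, overlay_alpha, overlay_alpha)
        bin_widths = np.diff(edges)
        area = float(np.sum(counts * bin_widths))
        overlay_density = density * area
    return Histogram(
        min_total=min_total,
        bin_edges=edges,
        counts=counts,
        n_included=int(keep.sum()),
        overlay_alpha=overlay_alpha,
        overlay_x=overlay_x,
        overlay_density=overlay_density,
    )


def binned_alpha(
    table: pd.DataFrame, bin_size: int = 1000, significance: float = 0.05
) -> list[ExpressionBin]:
    """Fit alpha separately in consecutive expression bins of bin_size enhancers.

    Enhancers (rows of a single-sample count table) are sorted by total tags
    ascending, ties broken by enhancer_id for determinism, then chunked. A
    trailing incomplete chunk is retained and flagged ``complete=False`` so
    that no enhancer is silently dropped.
    """
    if bin_size < 2:
        raise ValueError("bin_size must be at least 2")
    table = validate_count_table(table)
    df = table.assign(total=table["forward"] + table["reverse"]).sort_values(
        ["total", "enhancer_id"], kind="mergesort"
    )
    bins: list[ExpressionBin] = []
    for index, start in enumerate(range(0, len(df), bin_size)):
        chunk = df.iloc[start : start + bin_size]
        try:
            fit = fit_alpha(
                chunk["forward"].to_numpy(),
                chunk["reverse"].to_numpy(),
                significance=significance,
            )
        except NotEstimableError:
            fit = None
        bins.append(
            ExpressionBin(
                bin_index=index,
                enhancer_ids=chunk["enhancer_id"].tolist(),
                expression_range=(int(chunk["total"].min()), int(chunk["total"].max())),
                fit=fit,
                complete=len(chunk) == bin_size,
            )
        )
    return bins


def downsample(table: pd.DataFrame, target_tags: int, seed: int) -> pd.DataFrame:
    """Downsample a count table to exactly ``target_tags`` tags.

    Tags are drawn without replacement from the multiset of individual
    (enhancer, strand) tag instances — a multivariate hypergeometric draw —
    mimicking sequencing a smaller library from the same material.
    """
    table = validate_count_table(table)
    counts = np.concatenate(
        [table["forward"].to_numpy(np.int64), table["reverse"].to_numpy(np.int64)]
    )
    total = int(counts.sum())
    if target_tags > total:
        raise ValueError(f"target_tags {target_tags} exceeds total tags {total}")
    if target_tags < 0:
        raise ValueError("target_tags must be non-negative")
    rng = np.random.default_rng(seed)
    kept = rng.multivariate_hypergeometric(counts, target_tags, method="marginals")
    n = len(table)
    out = table.copy()
    out["forward"] = kept[:n]
    out["reverse"] = kept[n:]
    return out


def concordant_pair_count(F, R) -> ConcordantPairResult:
    """Count same-direction vs split tag pairs among two-tag enhancers.

    Restricts to enhancers with F + R = 2. Under perfectly balanced
    bidirectional transcription (p = 1/2 for every enhancer) a two-tag
    enhancer is split (one tag each way) with probability 1/2, so the
    two-sided binomial test compares the same-direction count against 1/2.
    An excess of same-direction pairs indicates directional transcription.
    """
    F = np.asarray(F, dtype=np.int64)
    R = np.asarray(R, dtype=np.int64)
    two = (F + R) == 2
    n_two = int(two.sum())
    if n_two == 0:
        return ConcordantPairResult(0, 0, 0, 1.0)
    split = int(np.sum(two & (F == 1)))
    same = n_two - split
    p = binomtest(same, n_two, 0.5, alternative="two-sided").pvalue
    return ConcordantPairResult(n_two, same, split, float(p))
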