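"""Cross-sample directionality variation and direction-switching tests.

For each enhancer observed in many samples: a chi-squared homogeneity test
of the forward/reverse split across samples, per-sample binomial tests for
a significant reversal of the pooled majority direction, and a constant-p
null model for the percentage of samples transcribing the enhancer
predominantly forward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom, binomtest, chi2_contingency

from .io import validate_count_table

__all__ = [
    "SwitchTestResult",
    "PoolingProfile",
    "PoolingSummary",
    "chi2_directionality_test",
    "switch_direction_test",
    "pooling_profile",
    "pooling_summary",
    "analyze_table",
]


@dataclass(frozen=True)
class SwitchTestResult:
    """Per-enhancer cross-sample variation and direction-switch calls.

    ``testable`` is False when fewer than two samples pass the tag
    threshold; all other fields are then undefined (NaN / empty).
    ``switch_flag`` is True when at least one qualifying sample transcribes
    significantly in the direction opposite to the pooled majority.
    """

    testable: bool
    n_qualifying_samples: int
    chi2_statistic: float = float("nan")
    chi2_p: float = float("nan")
    varies_flag: bool = False
    per_sample_switch_p: dict = field(default_factory=dict)
    switch_flag: bool = False


@dataclass(frozen=True)
class PoolingProfile:
    """Observed vs expected percentage of forward-majority samples.

    Percentages are taken over samples with a nonzero directionality score
    (ties F = R count neither way). The expected percentage assumes a single
    forward probability p across samples, estimated as the pooled forward
    fraction, with each sample's total fixed at its observed value.
    """

    testable: bool
    n_qualifying_samples: int
    n_nonzero: int = 0
    pct_positive_actual: float = float("nan")
    pct_positive_expected: float = float("nan")


@dataclass(frozen=True)
class PoolingSummary:
    n_profiles: int
    n_mixed_expectation: int
    frac_mixed_expectation: float
    mean_shift_toward_50: float


def _qualifying(F: np.ndarray, R: np.ndarray, min_total: int) -> np.ndarray:
    return (F + R) >= min_total


def chi2_directionality_test(
    F, R, min_total: int = 10, significance: float = 0.05
) -> SwitchTestResult:
    """Pearson chi-squared test of directionality homogeneity across samples.

    Builds the 2 x k contingency table (forward/reverse x qualifying
    samples, k = number of samples with >= min_total tags) and tests with
    k - 1 degrees of freedom, no continuity correction. Fewer than two
    qualifying samples -> not testable.
    """
    F = np.asarray(F, dtype=np.int64)
    R = np.asarray(R, dtype=np.int64)
    keep = _qualifying(F, R, min_total)
    k = int(keep.sum())
    if k < 2:
        return SwitchTestResult(testable=False, n_qualifying_samples=k)
    table = np.vstack([F[keep], R[keep]])
    # A strand with zero tags in every sample makes the table degenerate:
    # the forward fraction is identical everywhere, so homogeneity holds.
    if np.any(table.sum(axis=1) == 0):
        stat, p = 0.0, 1.0
    else:
        stat, p, _, _ = chi2_contingency(table, correction=False)
    return SwitchTestResult(
        testable=True,
        n_qualifying_samples=k,
        chi2_statistic=float(stat),
        chi2_p=float(p),
        varies_flag=bool(p < significance),
    )


def _two_sided_binom_p(k: int, n: int, p_null: float) -> float:
    if p_null <= 0.0:
        return 1.0 if k == 0 else 0.0
    if p_null >= 1.0:
        return 1.0 if k == n else 0.0
    return float(binomtest(k, n, p_null, alternative="two-sided").pvalue)


def switch_direction_test(
    F,
    R,
    sample_ids=None,
    min_total: int = 10,
    level: float = 0.05,
    significance: float = 0.05,
) -> SwitchTestResult:
    """Call samples in which the enhancer's transcription direction flips.

    The majority direction is taken from counts pooled over qualifying
    samples. Each qualifying sample whose own majority opposes it is tested
    with a two-sided binomial test of its (F, R) against the pooled forward
    fraction estimated from the *other* qualifying samples (leave-one-out,
    so the tested sample cannot drag the null toward itself). The
    per-sample threshold is Bonferroni-corrected by the number of
    qualifying samples, keeping the per-enhancer false-call rate at
    ``level`` no matter how many samples an enhancer is seen in.
    """
    F = np.asarray(F, dtype=np.int64)
    R = np.asarray(R, dtype=np.int64)
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(len(F))]
    chi2_res = chi2_directionality_test(F, R, min_total=min_total,
                                        significance=significance)
    if not chi2_res.testable:
        return chi2_res
    keep = _qualifying(F, R, min_total)
    Fq, Rq = F[keep], R[keep]
    ids_q = [s for s, k in zip(sample_ids, keep) if k]
    pooled_fwd = int(Fq.sum())
    pooled_rev = int(Rq.sum())
    majority_forward = pooled_fwd >= pooled_rev
    per_sample_p: dict[str, float] = {}
    switch = False
    for i, (f, r, sid) in enumerate(zip(Fq, Rq, ids_q)):
        sample_forward = f > r
        if f == r or sample_forward == majority_forward:
            continue
        loo_f = pooled_fwd - int(f)
        loo_n = pooled_fwd + pooled_rev - int(f) - int(r)
        p_hat = loo_f / loo_n if loo_n > 0 else 0.5
        p_val = _two_sided_binom_p(int(f), int(f + r), p_hat)
        per_sample_p[sid] = p_val
        if p_val < level / len(Fq):
            switch = True
    return SwitchTestResult(
        testable=True,
        n_qualifying_samples=chi2_res.n_qualifying_samples,
        chi2_statistic=chi2_res.chi2_statistic,
        chi2_p=chi2_res.chi2_p,
        varies_flag=chi2_res.varies_flag,
        per_sample_switch_p=per_sample_p,
        switch_flag=switch,
    )


def pooling_profile(
    F, R, min_total: int = 10, min_samples: int = 10
) -> PoolingProfile:
    """Observed and null-expected percentage of forward-majority samples.

    Null: a single forward probability p-hat = sum(F)/sum(F+R) over
    qualifying samples. The expected percentage is the ratio of
    expectations 100 * sum_s P(F_s > R_s) / sum_s P(F_s != R_s) with each
    sample's total fixed at its observed value — exact per-sample binomial
    sums, no simulation.
    """
    F = np.asarray(F, dtype=np.int64)
    R = np.asarray(R, dtype=np.int64)
    keep = _qualifying(F, R, min_total)
    k = int(keep.sum())
    if k < min_samples:
        return PoolingProfile(testable=False, n_qualifying_samples=k)
    Fq, Rq = F[keep], R[keep]
    n_s = Fq + Rq
    p_hat = float(Fq.sum()) / float(n_s.sum())
    nonzero = Fq != Rq
    n_nonzero = int(nonzero.sum())
    actual = (
        100.0 * float(np.sum(Fq > Rq)) / n_nonzero if n_nonzero else float("nan")
    )
    # P(F_s > R_s) = P(F_s > n_s/2) = sf(floor(n_s/2)); ties possible only
    # for even totals, with probability pmf(n_s/2).
    half = n_s // 2
    p_gt = binom.sf(half, n_s, p_hat)
    p_tie = np.where(n_s % 2 == 0, binom.pmf(half, n_s, p_hat), 0.0)
    p_ne = 1.0 - p_tie
    expected = 100.0 * float(np.sum(p_gt)) / float(np.sum(p_ne))
    return PoolingProfile(
        testable=True,
        n_qualifying_samples=k,
        n_nonzero=n_nonzero,
        pct_positive_actual=actual,
        pct_positive_expected=expected,
    )


def pooling_summary(profiles: list[PoolingProfile]) -> PoolingSummary:
    """Summarise pooling profiles across enhancers.

    Reports how many enhancers have a mixed-sign expectation (expected
    percentage strictly between 0 and 100, i.e. the null itself predicts
    samples of both directions) and the mean shift of the actual percentage
    toward 50% relative to the null expectation: mean(|expected - 50| -
    |actual - 50|). A positive shift means real data cancel more when
    pooled than constant-p sampling noise alone would.
    """
    usable = [p for p in profiles if p.testable]
    if not usable:
        raise ValueError("no testable profiles")
    expected = np.array([p.pct_positive_expected for p in usable])
    actual = np.array([p.pct_positive_actual for p in usable])
    mixed = (expected > 0.0) & (expected < 100.0)
    shift = float(np.nanmean(np.abs(expected - 50.0) - np.abs(actual - 50.0)))
    return PoolingSummary(
        n_profiles=len(usable),
        n_mixed_expectation=int(mixed.sum()),
        frac_mixed_expectation=float(mixed.mean()),
        mean_shift_toward_50=shift,
    )


def analyze_table(
    table: pd.DataFrame,
    min_total: int = 10,
    min_samples_profile: int = 10,
    level: float = 0.05,
    significance: float = 0.05,
) -> pd.DataFrame:
    """Run the per-enhancer switching analyses over a whole count table."""
    table = validate_count_table(table)
    rows = []
    for enhancer_id, grp in table.groupby("enhancer_id", sort=True):
        F = grp["forward"].to_numpy()
        R = grp["reverse"].to_numpy()
        ids = grp["sample_id"].tolist()
        res = switch_direction_test(
            F, R, ids, min_total=min_total, level=level, significance=significance
        )
        prof = pooling_profile(
            F, R, min_total=min_total, min_samples=min_samples_profile
        )
        rows.append(
            {
                "enhancer_id": enhancer_id,
                "n_qualifying": res.n_qualifying_samples,
                "testable": res.testable,
                "chi2": res.chi2_statistic,
                "chi2_p": res.chi2_p,
                "varies_flag": res.varies_flag,
                "switch_flag": res.switch_flag,
                "pct_positive_actual": prof.pct_positive_actual,
                "pct_positive_expected": prof.pct_positive_expected,
            }
        )
    return pd.DataFrame(rows)
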