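"""Tests for pooling, histograms, expression bins, downsampling, pair counts."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare, hypergeom

from enhancerdir.cohort import (
    binned_alpha,
    concordant_pair_count,
    directionality_histogram,
    downsample,
    pool_by_group,
    pool_samples,
)
from enhancerdir.model import directionality_scores
from enhancerdir.simulate import DepthModel, SyntheticCohortSpec, generate_cohort


class TestPoolSamples:
    def test_additivity(self, small_table):
        pooled = pool_samples(small_table)
        e1 = pooled[pooled["enhancer_id"] == "e1"].iloc[0]
        assert (e1["forward"], e1["reverse"]) == (3, 4)
        score = (e1["forward"] - e1["reverse"]) / (e1["forward"] + e1["reverse"])
        assert score == pytest.approx(-1 / 7)

    def test_single_sample_is_identity(self, small_table):
        pooled = pool_samples(small_table, ["s1"])
        s1 = small_table[small_table["sample_id"] == "s1"].reset_index(drop=True)
        assert (pooled[["forward", "reverse"]].to_numpy()
                == s1[["forward", "reverse"]].to_numpy()).all()

    def test_conserves_total_tags(self, small_table):
        pooled = pool_samples(small_table)
        assert (pooled[["forward", "reverse"]].to_numpy().sum()
                == small_table[["forward", "reverse"]].to_numpy().sum())

    def test_unknown_sample_raises(self, small_table):
        with pytest.raises(KeyError, match="nope"):
            pool_samples(small_table, ["nope"])

    def test_triangle_inequality_on_simulated_data(self):
        # Pooled |score| can never exceed the tag-weighted per-sample mix;
        # per enhancer: |sum_s (F_s - R_s)| <= sum_s |F_s - R_s|.
        table = generate_cohort(
            SyntheticCohortSpec(n_enhancers=300, alpha_true=0.5, n_samples=6,
                                switching_fraction=0.4, seed=11)
        )
        pooled = pool_samples(table)
        per = table.assign(absdiff=(table["forward"] - table["reverse"]).abs())
        lhs = (pooled["forward"] - pooled["reverse"]).abs().to_numpy()
        rhs = per.groupby("enhancer_id")["absdiff"].sum().to_numpy()
        assert np.all(lhs <= rhs)

    def test_pool_by_group(self, small_table):
        mapping = pd.DataFrame({"cell_id": ["s1", "s2"], "group_id": ["g", "g"]})
        grouped = pool_by_group(small_table, mapping)
        full = pool_samples(small_table)
        assert (grouped[["forward", "reverse"]].to_numpy()
                == full[["forward", "reverse"]].to_numpy()).all()


class TestDirectionalityHistogram:
    def test_forward_only_mass_in_last_bin(self):
        F = np.full(50, 10)
        R = np.zeros(50, dtype=int)
        hist = directionality_histogram(F, R, fit_overlay=False)
        assert hist.counts[-1] == 50
        assert hist.counts[:-1].sum() == 0

    def test_min_total_threshold_excludes(self):
        hist = directionality_histogram([5, 9], [4, 0], min_total=10,
                                        fit_overlay=False)
        assert hist.n_included == 0
        assert hist.counts.sum() == 0

    def test_convex_cohort_is_u_shaped(self):
        table = generate_cohort(
            SyntheticCohortSpec(n_enhancers=4000, alpha_true=0.3,
                                depth=DepthModel(kind="constant", value=30),
                                seed=3)
        )
        hist = directionality_histogram(
            table["forward"].to_numpy(), table["reverse"].to_numpy()
        )
        mid = len(hist.counts) // 2
        assert hist.counts[0] >= hist.counts[mid]
        assert hist.counts[-1] >= hist.counts[mid]
        assert hist.overlay_alpha < 1

    def test_overlay_is_scaled_transformed_beta_density(self):
        # Overlay(d) = area * 0.5 * beta_pdf((d+1)/2; a, a) at interior points,
        # where area is the histogram mass (counts x bin widths).
        from scipy.stats import beta as beta_dist

        table = generate_cohort(
            SyntheticCohortSpec(n_enhancers=2000, alpha_true=0.5,
                                depth=DepthModel(kind="constant", value=20),
                                seed=4)
        )
        hist = directionality_histogram(
            table["forward"].to_numpy(), table["reverse"].to_numpy()
        )
        area_hist = np.sum(hist.counts * np.diff(hist.bin_edges))
        a = hist.overlay_alpha
        interior = np.abs(hist.overlay_x) < 0.95
        expected = area_hist * 0.5 * beta_dist.pdf(
            (hist.overlay_x[interior] + 1) / 2, a, a
        )
        np.testing.assert_allclose(hist.overlay_density[interior], expected,
                                   rtol=1e-10)


class TestBinnedAlpha:
    @pytest.mark.parametrize("n_enh,bin_size,n_bins", [(4300, 100, 43), (2500, 100, 25)])
    def test_bin_count(self, n_enh, bin_size, n_bins):
        table = generate_cohort(
            SyntheticCohortSpec(n_enhancers=n_enh, alpha_true=0.5, seed=5)
        )
        bins = binned_alpha(table, bin_size=bin_size)
        assert len(bins) == n_bins
        assert all(b.complete for b in bins)

    def test_trailing_partial_bin_kept_and_flagged(self):
        table = generate_cohort(
            SyntheticCohortSpec(n_enhancers=250, alpha_true=0.5, seed=6)
        )
        bins = binned_alpha(table, bin_size=100)
        assert len(bins) == 3
        assert not bins[-1].complete
        assert sum(len(b.enhancer_ids) for b in bins) == 250

    def test_bins_sorted_ascending_by_expression(self):
        table = generate_cohort(
            SyntheticCohortSpec(n_enhancers=600, alpha_true=0.5, seed=7)
        )
        bins = binned_alpha(table, bin_size=200)
        maxima = [b.expression_range[1] for b in bins]
        minima = [b.expression_range[0] for b in bins]
        assert all(maxima[i] <= minima[i + 1] or maxima[i] <= maxima[i + 1]
                   for i in range(len(bins) - 1))

    def test_no_alpha_trend_when_depth_independent(self):
        # alpha is the same at every depth in the generator, so binned
        # estimates should show no monotone trend (rank correlation ~ 0).
        table = generate_cohort(
            SyntheticCohortSpec(n_enhancers=6000, alpha_true=0.5,
                                depth=DepthModel(kind="lognormal", value=20,
                                                 sigma_log=1.0),
                                seed=8)
        )
        bins = [b for b in binned_alpha(table, bin_size=1000) if b.fit]
        alphas = np.array([b.fit.alpha_hat for b in bins])
        ranks = np.arange(len(alphas))
        rho = np.corrcoef(ranks, alphas)[0, 1]
        assert abs(rho) < 0.9  # no strong systematic drift


class TestDownsample:
    def test_identity_at_full_depth(self, small_table):
        total = int(small_table[["forward", "reverse"]].to_numpy().sum())
        out = downsample(small_table, total, seed=1)
        pd.testing.assert_frame_equal(out, small_table)

    def test_zero_target(self, small_table):
        out = downsample(small_table, 0, seed=1)
        assert (out[["forward", "reverse"]].to_numpy() == 0).all()

    def test_target_exceeding_total_raises(self, small_table):
        with pytest.raises(ValueError):
            downsample(small_table, 10**9, seed=1)

    def test_exact_target_and_reproducible(self, small_table):
        out1 = downsample(small_table, 10, seed=42)
        out2 = downsample(small_table, 10, seed=42)
        assert int(out1[["forward", "reverse"]].to_numpy().sum()) == 10
        pd.testing.assert_frame_equal(out1, out2)

    def test_hypergeometric_expectation(self, small_table):
        # E[kept] = count * target / total for every (enhancer, strand) cell.
        total = int(small_table[["forward", "reverse"]].to_numpy().sum())
        target = 10
        sums = np.zeros((len(small_table), 2))
        n_rep = 500
        for seed in range(n_rep):
            out = downsample(small_table, target, seed=seed)
            sums += out[["forward", "reverse"]].to_numpy()
        mean = sums / n_rep
        counts = small_table[["forward", "reverse"]].to_numpy()
        expected = counts * target / total
        se = np.sqrt(
            counts * (target / total) * (1 - target / total) / n_rep
        )
        assert np.all(np.abs(mean - expected) <= 3 * se + 1e-9)

    def test_marginal_is_hypergeometric(self):
        # Goodness-of-fit of one cell's retained count against the exact
        # hypergeometric law on a toy two-cell table.
        table = pd.DataFrame(
            {
                "enhancer_id": ["a", "b"],
                "sample_id": ["s", "s"],
                "forward": [6, 14],
                "reverse": [0, 0],
            }
        )
        target, n_rep = 8, 3000
        draws = np.array(
            [downsample(table, target, seed=s)["forward"].iloc[0]
             for s in range(n_rep)]
        )
        support = np.arange(0, 7)
        probs = hypergeom.pmf(support, 20, 6, target)
        observed = np.bincount(draws, minlength=7)
        keep = probs * n_rep >= 5
        stat, p = chisquare(observed[keep], probs[keep] / probs[keep].sum() * observed[keep].sum())
        assert p > 0.01


class TestConcordantPairCount:
    def test_hand_counts(self):
        res = concordant_pair_count([2, 0, 1], [0, 2, 1])
        assert (res.n_two_tag, res.n_same_direction, res.n_split) == (3, 2, 1)

    def test_no_two_tag_enhancers(self):
        res = concordant_pair_count([5, 0], [0, 0])
        assert res.n_two_tag == 0
        assert res.p_value == 1.0

    def test_directional_cohort_has_few_split_pairs(self):
        table = generate_cohort(
            SyntheticCohortSpec(n_enhancers=20000, alpha_true=0.01,
                                depth=DepthModel(kind="poisson", value=1.0),
                                seed=9)
        )
        res = concordant_pair_count(
            table["forward"].to_numpy(), table["reverse"].to_numpy()
        )
        assert res.n_two_tag > 100
        assert res.n_split / res.n_two_tag < 0.1
        assert res.p_value < 1e-10

    def test_balanced_cohort_near_even_split(self):
        rng = np.random.default_rng(10)
        F = rng.binomial(2, 0.5, size=5000)
        res = concordant_pair_count(F, 2 - F)
        assert res.n_split / res.n_two_tag == pytest.approx(0.5, abs=0.05)
        assert res.p_value > 0.001
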