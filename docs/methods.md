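# Methods

## Model and assumptions

Each enhancer–sample observation is a pair of non-negative stranded tag
counts (F, R). The model assumes:

1. Conditional on a per-enhancer forward-transcription probability p, the
   forward count is Binomial(F+R, p) — tags are independent draws from the
   enhancer's strand preference, with the total depth treated as fixed
   (ancillary) rather than modelled.
2. Across enhancers, p ~ Beta(α, α). The symmetry assumption (equal shape
   parameters) encodes that enhancers are unoriented: the labels
   forward/reverse are genomic strand, not a biological polarity, so the
   population distribution of p must be symmetric about 1/2.
3. Enhancers are independent given α.

Integrating the binomial over the prior gives the symmetric beta-binomial
Pr(F, R | α) = C(F+R, F)·B(F+α, R+α)/B(α, α). The cohort log-likelihood
drops the combinatorial factor (constant in α):
L(α) = Σᵢ log[B(Fᵢ+α, Rᵢ+α)/B(α, α)]. Enhancers with F+R = 0 contribute
zero; enhancers with F+R = 1 contribute the constant log(1/2), so only
enhancers with at least two tags inform α. `fit_alpha` therefore restricts
to these and reports their count and tag total alongside the estimate.

The expected absolute directionality has the closed form
E|2p−1| = 2/(α·B(α,α)·4^α), evaluated in log space via `betaln`. It is
strictly decreasing: 1 at α→0 (every enhancer strictly one-sided), 1/2 at
α = 1 (uniform p), 0 at α→∞ (every enhancer balanced).

## Estimation and testing

- **Optimiser.** L(α) is maximised over log α ∈ [log 10⁻⁶, log 10⁶] with
  bounded Brent search (deterministic, derivative-free; the likelihood is
  smooth and unimodal in log α for real cohorts). The log parameterisation
  covers the scale range encountered in practice, from single-cell fits
  near 10⁻² to strongly concave pooled data. An optimum within 10⁻² (log
  units) of a bound whose likelihood the bound matches is reported *at*
  the bound with a `boundary` flag — strictly unidirectional cohorts
  legitimately push α̂ → 0 — rather than treated as a failure.
- **Likelihood-ratio test.** 2[L(α̂) − L(1)] is referred to χ²(1): one free
  parameter, with both α < 1 and α > 1 counting as departures. The
  significance level defaults to 0.05 and a fit is called `convex`
  (α̂ < 1, significant), `concave` (α̂ > 1, significant) or
  `uniform-not-rejected`. No multiple-testing correction is applied when
  classifying many samples; the raw per-sample calls are the quantity of
  interest and can be corrected downstream if desired.
- **Two-cohort comparison.** `compare_alpha` tests separate α per cohort
  against one shared α (statistic 2[L_a(α̂_a)+L_b(α̂_b)−L_ab(α̂_shared)],
  χ²(1)); this is the contrast used to ask whether, e.g., cluster-level
  counts are more directional than pseudobulk.
- All beta/gamma factors go through `gammaln`/`betaln`; factorials are
  never formed directly.

## Cross-sample analyses

- **Homogeneity (χ²).** Per enhancer, the 2×k forward/reverse table over
  samples with ≥ 10 tags (k ≥ 2 required), Pearson χ² with k−1 df, no
  continuity correction. A strand with zero tags in every qualifying
  sample makes the table degenerate; homogeneity trivially holds and the
  test reports statistic 0, p = 1.
- **Direction switching.** The majority direction comes from counts summed
  over qualifying samples. Each qualifying sample whose own majority
  opposes it is tested two-sided against the pooled forward fraction
  estimated from the *other* qualifying samples (leave-one-out, so the
  tested sample cannot drag the null toward itself). The per-sample
  threshold is Bonferroni-corrected by the number of qualifying samples:
  without the correction the per-enhancer false-call rate under a
  constant-p null grows with sample count (measured ≈ 0.084 at six
  samples, nominal 0.05); with it the rate stays at or below the nominal
  level, which is also how the observed switch rate in a time course from
  a single cell type can be read against the significance threshold.
- **Pooling profile.** For enhancers with ≥ 10 samples of ≥ 10 tags, the
  observed percentage of forward-majority samples (ties excluded, as a
  percentage of samples with a nonzero score) is compared with its
  expectation under a constant-p null, p̂ = ΣF/Σ(F+R). The expectation is
  the ratio of expectations 100·Σₛ P(Fₛ>Rₛ)/Σₛ P(Fₛ≠Rₛ) with per-sample
  totals fixed at their observed values — exact binomial sums, no
  simulation. The ratio-of-expectations approximation (rather than the
  expectation of the ratio, which requires enumeration exponential in the
  sample count) deviates by O(1/#samples) and is validated against exact
  enumeration at small sample counts in the tests.

## Detection filter

The bidirectionality screen keeps an expressed candidate when its pooled
|score| is strictly below 0.8 *and* at least one sample has ≥ 1 tag on
each strand. Both readings the source criterion leaves open were resolved
as: the score threshold applies to the pooled counts (the per-sample
clause is the separate "bidirectional expression in at least one sample"
condition), and one tag per strand is the weakest consistent notion of
per-sample bidirectional expression. Labels partition expressed candidates
into those passing the screen and those recovered only when the
requirement is dropped, so relaxing the policy is provably monotone.

## Synthetic cohorts

The generator draws p once per enhancer from Beta(α_true, α_true), then
per sample draws a total depth n and F ~ Binomial(n, p). Defaults:

- **Depth.** Log-normal totals, median 5 tags, σ_log = 1.5, floored to
  integers — a skewed distribution in which most enhancers are lowly
  expressed, matching the character of enhancer expression; constant and
  Poisson depth models are available, the latter (mean 0.3) being the
  sparse single-cell regime where most enhancer–cell pairs carry 0–2 tags.
- **Switching.** A fraction of enhancers use 1−p in the second condition
  (samples split evenly between conditions); an optional delta attenuates
  the flip. This is the simplest mechanism that produces opposite-sign
  directionality across cell types and the pooling-driven emergence of
  apparent bidirectionality.
- **Reproducibility.** One `numpy` Generator seeded from the spec; draws
  occur in a fixed documented order, so output is bit-reproducible.

What the generator does *not* emulate: genomic positions and sequence
context, allelic structure (real single-cell data cannot distinguish
alleles, so residual bidirectionality may be two unidirectional alleles),
depth–α dependence, exosome degradation kinetics, UMI errors, or
cross-enhancer correlation. Passing tests therefore demonstrate
correctness of the statistics under the model's own assumptions, not that
real data satisfy those assumptions.

## Calibration experiment

`alpha_recovery_experiment` refits α on cohorts generated at known α_true
with a prescribed budget of tags on informative (≥ 2-tag) enhancers. At a
budget of ~1500 tags, the median α̂ lands within 15% of the truth across
α_true ∈ [0.1, 5] and the LRT size at α_true = 1 is ≈ 0.05; at a budget of
50 tags fits become non-significant far more often than significantly
wrong-sided. Test and acceptance runs use 100–200 replicates per cell and
cohorts of a few hundred enhancers; these sizes give Monte-Carlo standard
errors comfortably inside the asserted tolerances while keeping the suite
quick.

## Numerical and degenerate-input conventions

- Directionality of a zero-tag observation is undefined and flagged, not
  an error or a zero.
- Expression bins sort ascending by total tags, ties broken by enhancer id
  for determinism; a trailing partial bin is kept and flagged so tag
  totals are conserved.
- Downsampling draws tag instances without replacement (multivariate
  hypergeometric over (enhancer, strand) cells), matching the notion of
  sequencing a smaller library from the same material; binomial thinning
  would add extra variance.
- Two-tag concordance tests the same-direction count against 1/2, the
  split probability under perfectly balanced transcription (p = 1/2 gives
  P(one tag each way) = 2·(1/2)² = 1/2).
- bedGraph intervals are assigned to the region containing their start
  position (the 5′ tag position in CTSS-style tracks), counting each tag
  exactly once across adjacent regions; minus-strand values are stored as
  absolute values since both sign conventions occur in the wild.
- Coordinates are BED 0-based half-open everywhere internally.

## Limitations

- The symmetric prior cannot represent a population with a genuine strand
  bias (it is the correct invariance for unoriented enhancers, but not for
  oriented features such as promoters).
- The switch test's leave-one-out + Bonferroni construction is one
  defensible reconstruction of a per-sample binomial switch test; other
  constructions (e.g. raw-level unions) trade calibration for sensitivity.
- χ² homogeneity p-values are asymptotic; the ≥ 10-tag filter bounds, but
  does not eliminate, small-expected-count distortion.
- Boundary fits (α̂ at 10⁻⁶ or 10⁶) mean the data prefer the limit; the
  reported α̂ is then a censored value, and its LRT p-value remains valid
  only as evidence against α = 1, not as support for the exact boundary
  value.
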