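# enhancerdir

Statistical analysis of enhancer transcription directionality from stranded
5′-tag counts (CAGE, 5′ scRNA-seq, GRO/PRO-cap and similar assays).

Active enhancers produce short capped RNAs on both genomic strands, and
balanced bidirectional expression is often used as a signature to detect
enhancers from transcriptome data. But within a single cell type an
enhancer typically transcribes predominantly in one direction — and the
preferred direction can differ between cell types, so pooling samples makes
directional enhancers *look* bidirectional. `enhancerdir` implements the
model and tests needed to quantify this, for computational biologists
working with stranded 5′-end count data.

## The model

For an enhancer with `F` forward and `R` reverse tags, the **directionality
score** is

```
d = (F − R) / (F + R)   ∈ [−1, +1]
```

(+1 forward-only, −1 reverse-only, 0 balanced). Conditional on a
forward-transcription probability `p`, counts are Binomial(F+R, p); across
enhancers `p ~ Beta(α, α)`. The compound distribution of (F, R) is the
symmetric beta-binomial

```
Pr(F, R | α) = C(F+R, F) · B(F+α, R+α) / B(α, α)
```

whose single shape parameter `α` summarises a dataset: `α < 1` (convex
beta) means the population skews unidirectional, `α > 1` (concave) skews
balanced-bidirectional. The expected absolute score has the closed form
`E|2p−1| = 2 / (α·B(α,α)·4^α)`, strictly decreasing in `α`. `α` is
estimated by maximum likelihood and tested against `α = 1` with a
one-degree-of-freedom likelihood-ratio test.

On top of the core fit the package provides: per-enhancer χ² tests of
directionality homogeneity across samples and binomial tests for direction
switching; a constant-`p` null model for the percentage of forward-majority
samples; hypergeometric downsampling; expression-binned `α` estimates;
the bidirectionality detection filter (pooled |d| < 0.8 plus bidirectional
expression in ≥ 1 sample) with its retention cost; a Mann–Whitney test of
directionality against external functionality labels; and a synthetic
cohort generator (including sparse single-cell cohorts and two-condition
direction switching) that makes all of it testable without external data.

## Worked example

Simulate two cell types in which 30% of enhancers switch their preferred
direction, then fit `α` per condition and on the pooled counts:

```python
from enhancerdir import (SyntheticCohortSpec, generate_cohort,
                         pool_samples, fit_alpha)

spec = SyntheticCohortSpec(n_enhancers=2000, alpha_true=0.5, n_samples=4,
                           switching_fraction=0.3, seed=42)
table = generate_cohort(spec)
for cond in ("A", "B"):
    sub = pool_samples(table[table["sample_id"].str.startswith(cond)])
    fit = fit_alpha(sub["forward"].to_numpy(), sub["reverse"].to_numpy())
    print(f"condition {cond}: alpha_hat={fit.alpha_hat:.3f}  "
          f"p={fit.p_value:.2e}  call={fit.shape_call}")
pooled = pool_samples(table)
fit = fit_alpha(pooled["forward"].to_numpy(), pooled["reverse"].to_numpy())
print(f"pooled     : alpha_hat={fit.alpha_hat:.3f}  "
      f"p={fit.p_value:.2e}  call={fit.shape_call}")
```

prints

```
condition A: alpha_hat=0.516  p=1.41e-82  call=convex
condition B: alpha_hat=0.517  p=2.49e-85  call=convex
pooled     : alpha_hat=0.718  p=1.49e-28  call=convex
```

Each condition recovers the generating `α = 0.5` (significantly convex:
directional expression). Pooling the two conditions inflates `α̂` to 0.72 —
the direction switches partially cancel, shifting the pooled population
toward apparent bidirectionality even though no single condition is
bidirectional.

The same pipeline is available from the shell:

```
enhancerdir simulate --seed 7 --n-enhancers 2000 --alpha 0.5 \
    --n-samples 4 --switching-fraction 0.3 --output cohort.tsv
enhancerdir fit --input cohort.tsv --output fits.tsv
enhancerdir switch --input cohort.tsv --output switching.tsv
enhancerdir detect --input cohort.tsv --output detection.tsv
```

All outputs are TSV with a `#` provenance header; rerunning with the same
seed and flags reproduces them byte for byte.

## Documentation

See `docs/methods.md` for the model assumptions, parameter defaults,
numerical choices and limitations.
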