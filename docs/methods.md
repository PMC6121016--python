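# Methods

## The problem

Solid tumor specimens are never pure: a biopsy contains cancer cells mixed
with stromal, immune and normal epithelial cells. If the fraction of cancer
cells (the *tumor purity*, λ ∈ (0, 1]) varies across samples, it acts as a
multiplicative confounder on gene expression. A gene whose pure-tumor mean
differs from its normal mean appears attenuated in low-purity samples, which
both inflates the apparent within-tumor variance and shrinks the apparent
group difference. Two-group tests that ignore purity therefore lose power,
and treating purity as an additive covariate misspecifies the mechanism.

## The model

Expression is assumed approximately Gaussian per gene after log2 transform
and quantile normalization. For gene *i*:

- pure-normal expression: `X_is ~ N(m_i, σ_i²)`
- pure-tumor expression: `Y_is = X_is + δ_is`, with `δ_is ~ N(μ_i, τ_i²)`
- observed tumor expression with purity λ_s:

  ```
  Y'_is = (1 − λ_s) X_is + λ_s Y_is = X_is + λ_s δ_is
  ```

so `Y'_is ~ N(m_i + λ_s μ_i, σ_i² + λ_s² τ_i²)`. The null hypothesis of no
differential expression is `H0: μ_i = 0`.

Stacking the n₀ normal and n₁ tumor samples into `Z_i`, the mean structure
is linear, `Z_i = W β_i + ε_i`, with the (n₀+n₁)×2 design

```
W = [1 0; …; 1 0; 1 λ_1; …; 1 λ_n1],    β_i = (m_i, μ_i).
```

### Estimation and testing

1. **Fit**: ordinary least squares, `β̂_i = (WᵀW)⁻¹ Wᵀ Z_i = H Z_i`.
2. **Group-wise residual variances**: `σ̂² = Σ_normal ε̂²/(n₀−2)` and
   `σ̂′² = Σ_tumor ε̂²/(n₁−2)`. The n−2 denominators charge both fitted
   coefficients to each group; this forces n₀ ≥ 3 and n₁ ≥ 3.
3. **Shrinkage**: per group, each gene's log-variance is pulled toward the
   cross-gene mean log-variance,
   `log σ̃² = (1−w)·log σ̂² + w·mean_genes(log σ̂²)`,
   i.e. a convex combination with the geometric mean. Default `w = 0.5`;
   `w = 0` is the identity (useful for closed-form checks), `w = 1` maps
   every gene to the geometric mean. Exact-zero variances are floored at
   the 1st percentile of the positive variances (1e-8 if none) before the
   log. This is a deliberately transparent moderated-variance rule; its
   benefit is largest for small n, and it is what makes the caller behave
   like a moderated statistic even at full purity.
4. **Covariance**: with `H = [H1 H2]` split into normal/tumor column
   blocks, `var(β̂) = σ̃²·H1H1ᵀ + σ̃′²·H2H2ᵀ`. At λ ≡ 1 this reduces to the
   familiar `var(μ̂) = σ̃²/n₀ + σ̃′²/n₁`.
5. **Wald test**: `t_i = β̂_i[2]/√var(β̂_i)[2,2]`, referred to a Student t
   with `n₀+n₁−2` degrees of freedom, two-sided. The df is fixed at
   n₀+n₁−2 (no Welch–Satterthwaite adjustment); with the group-wise
   variance estimates this is an approximation, whose adequacy the null
   calibration test measures empirically (type-I error within the 99%
   binomial band around 0.05 at n₀ = n₁ = 50, p-values passing a KS
   uniformity check).
6. **FDR**: Benjamini–Hochberg step-up across genes.

### Degenerate inputs and numerical choices

- Purity must lie in (0, 1]: a "tumor" sample with λ = 0 carries no tumor
  signal and degenerates the effect column.
- A gene constant within both groups has residuals and effect that are pure
  floating-point rounding noise; the ratio of two rounding errors is
  meaningless. `run_dectp` therefore snaps effects and residual variances
  below ~1e3·eps·scale (scale = the gene's max |value|) to exact zero, after
  which the degenerate path gives t = 0, p = 1. A zero variance paired with
  a genuinely nonzero effect yields p = 0 with a warning.
- Output rows keep the input gene order; the rank column orders by FDR with
  ties broken by p-value then gene id, so reruns are byte-identical.

## Preprocessing

`log2_transform` uses the single matrix-wide minimum non-zero value as the
offset (not per-gene), then `quantile_normalize` maps each column's ranks
onto the across-column mean of sorted values; tied values receive the mean
of the reference values they span. Default scope is joint across all
samples; `per_group` is available but normalizing groups separately can
erase or fabricate group-level shifts, so it is not the default.

## The simulation generator

`simulate_dataset` draws, per gene, `m_i ~ N(8, 2²)` (log2-expression
scale), `σ_i ~ |N(0,1)| + 0.25`, `τ_i ~ |N(0,1)| + 0.25`, and an effect
`μ_i` from a mixture: exactly 0 with probability 0.4, else `N(0, 2²)`.
Under these defaults the truth rule |μ_i| ≥ δ labels roughly 37%/19%/8% of
genes as true DEGs at δ = 1/2/3. Purities are `Uniform[0.05, 0.95]`;
optional reported-purity noise is `N(0, sd²)` (sd 0.1 in robustness runs)
clipped back into the purity range. All streams derive from one seed via
`SeedSequence.spawn`, so identical configs reproduce bit-identical data.

Two structural choices matter:

- The tumor signal is generated as `Y = X_component + δ` (shared noise plus
  a shift), not as an independent `N(m′, σ′²)` draw. Marginally these agree
  (`m′ = m + μ`, `σ′² = σ² + τ²`), but the shared-noise construction is what
  makes the observed tumor variance `σ² + λ²τ²` ≥ the normal variance —
  the confounding signature the diagnostics quantify.
- The observed normal group and the normal component inside each tumor
  sample are **independent** draws. Reusing the normal samples as the
  tumor's admixed component would correlate the two groups and, under the
  null, duplicate columns outright, making p-values arbitrarily
  conservative; independent draws match the model the caller assumes.

### What the generator does and does not emulate

It emulates Gaussian log-expression with gene-specific means/variances,
purity-dependent mixing, and noisy purity estimates. It does **not**
emulate read-count discreteness and mean–variance coupling of RNA-seq
counts, gene–gene correlation, batch effects, or empirical (data-derived)
parameter distributions. Passing benchmarks therefore demonstrate that the
caller exploits purity correctly when the mixture model holds, not that it
dominates on arbitrary real data.

## Evaluation

Methods are ranked per gene by |statistic| (for fixed df this is the same
ranking as 1 − p) and scored by ROC AUC against the truth labels, in the
Mann–Whitney formulation with half credit for ties. The baseline is the
pooled-variance two-sample t-test; a limma-style moderated test is not
re-implemented (on Gaussian data the t-test is a faithful stand-in, and the
shrinkage-off mode of the caller itself provides the un-moderated
comparison). At λ ≡ 1 with shrinkage off, the caller's ranking coincides
with the t-test's up to variance-denominator differences; with shrinkage on
it behaves like a moderated statistic and may rank strictly better.

## Diagnostics

Per-gene Spearman correlation (average-rank ties) between tumor expression
and purity; constant rows are flagged, not dropped. The permutation null
shuffles the purities once with a caller-supplied seed, mirroring a single
"Random" reference curve; callers wanting a multi-permutation null loop
over seeds. Decile grouping sorts genes by a test statistic (ties broken by
gene id) into 10 equal-size bins; the top-n curve reports the running mean
of |ρ| over a significance ranking.

## Problem sizes

Tests and the acceptance script use 1,000–2,000 genes per simulated
dataset, 10 seeded replicates per benchmark configuration (group sizes 10
and 50, δ ∈ {1, 2}), 2,000 null genes for calibration, and 2,000 genes with
μ = 2 for effect recovery. These sizes give Monte-Carlo standard errors
comfortably inside the asserted tolerances while keeping the full suite
under a minute.

## Known limitations

- Gaussian-only: count data (negative binomial) is out of scope.
- One tumor variance per gene: the generative model implies sample-specific
  variance σ² + λ_s²τ², but the estimator (by design, following the
  displayed formulas) uses a single σ′² per gene; the null calibration test
  bounds the practical cost at the sizes tested.
- The df choice n₀+n₁−2 is an approximation when two variances are
  estimated with n₀−2 and n₁−2 denominators.
- Purity is an input; estimating it (e.g. from methylation) is out of scope.
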