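# Methods

## The model

Case-control status is modeled by additive-effect logistic regression on the
m SNPs of one hit region:

    y_i ~ Bernoulli(p_i),   logit(p_i) = mu + sum_j x_ij * beta_j,

where `x_ij` is the column-centered allele count (0/1/2, or a fractional
dosage) of SNP j in individual i. Only a subset of SNPs are true signals; the
inferential target is the inclusion vector gamma, not the effect sizes.

A sparse fit at penalty `lam` solves

    min over (mu, beta) of  (1/n) * NLL(mu, beta) + lam * ||beta||_1,

with the intercept unpenalized. The 1/n loss normalization fixes the scale of
the penalty, giving the zeroing penalty the closed form
`lambda_max = (1/n) max_j |<x_j, y - ybar>|`: any `lam >= lambda_max` selects
nothing. All penalty grids are 100 (configurable) log-spaced values from
`lambda_max` down to `0.001 * lambda_max` by default.

## LLARRMA

For k = 1..K (default 100):

1. draw a stratified subsample without replacement: `ceil(phi*n1)` cases and
   `ceil(phi*n0)` controls (default phi = 0.5; ceiling rounding guarantees
   both classes for any valid phi);
2. choose a subsample-specific penalty `lam_k`:
   - permutation selection (default): the median over S = 25 permutations of
     the subsample response of `lambda_max` on the subsample's centered
     design. The median (not the max) is used so accuracy improves with S.
     `lam_k` may exceed the subsample's own `lambda_max`, in which case the
     subsample contributes an empty model;
   - complement deviance selection: the grid penalty minimizing the binomial
     deviance of the subsample-fit model on the held-out complement, whose
     rows are centered by the subsample column means (the frame the model
     was fit in). Ties go to the larger penalty;
3. fit the L1 path on the subsample and record the active set at `lam_k`
   (|coefficient| > 1e-8, penalty snapped to the nearest grid point, ties to
   the larger penalty).

Each SNP's RMIP is the mean of its K inclusion indicators. Per-subsample
randomness comes from counter-based child streams of one master seed, so
subsample k is reproducible and independent of K.

Missing genotypes enter through genotype posteriors: hard (MAP) and dosage
(expected allele count) imputation produce one plug-in matrix; multiple
imputation supplies one sampled matrix per subsample, so imputation
uncertainty propagates into the RMIPs. MAP ties break toward the larger
expected dosage. The built-in `naive_posterior` (joint frequencies with the
two most-correlated neighbor SNPs, pseudocount 0.5) exists so the pipeline is
testable without external phasing software; real analyses should feed
posteriors from a haplotype-based imputation program.

## Comparators

- Single-locus regression: per SNP, a one-predictor logistic fit scored by
  -log10 of the 1-df likelihood-ratio P-value against the intercept-only
  model, on per-SNP complete cases; scores cap at 300 under separation. The
  fits use a dedicated vectorized Newton solver, cross-checked against
  statsmodels in the tests.
- Stability Selection: the same subsampling, but one global penalty grid
  (anchored at the full data's `lambda_max`) shared by all K subsamples;
  entry (l, j) of the stability path is the fraction of subsamples in which
  SNP j is active at grid point l. Because the method leaves the penalty
  free, comparisons use "oracle" calibration: the grid row maximizing a
  truth-dependent criterion (default the initial AUC; the full-window AUC is
  available via the `window` argument). This is deliberately unfair in the
  competitor's favor.

## ROC evaluation

Power at threshold t = fraction of the q true signals scoring >= t; FPR = the
background analogue. Sweeping the distinct scores descending (ties enter
together) gives the ROC polyline from (0,0) to (1,1); AUC on an FPR window
[a, b] is the trapezium-rule integral with power linearly interpolated at the
window edges, normalized by b - a. The full-window AUC equals the
tie-corrected Mann-Whitney statistic (asserted in tests). The initial AUC
(window [0, 0.05]) measures enrichment among top-ranked SNPs — the relevant
quantity when few SNPs can be followed up. Study summaries report the mean
per-trial AUC with variance = cross-trial variance / trial count (normal
approximation); curves averaged across trials use threshold averaging.

## Synthetic hit regions

The generator emulates two designs: a 1,493 x 183 moderate-LD region and a
2,199 x 500 strong-LD region, since the underlying cohort genotypes are not
redistributable.

LD blocks: each block has a founder haplotype pool (size 8–12). Founder
alleles at the first SNP are independent draws at a frequency uniform in
[0.05, 0.95]; each founder's allele then flips with per-SNP probability
`pool_mutation_rate`, so founder columns carry gradually decaying LD. An
individual's haplotype copy is a mosaic of founders (per-SNP switch
probability `recombination_rate`) with a small copy-error rate; the genotype
is the sum of two copies. This yields graded, distance-decaying within-block
r2 and independent blocks — the qualitative structure of a real hit region. A
plain "copy one founder per block" model was tried first and rejected: it
produces bimodal LD (near-duplicate or uncorrelated SNP pairs), which no real
region shows. Pool columns are forced polymorphic; realized monomorphic SNPs
are regenerated (<= 10 tries).

Causal placement: the moderate-LD design places two SNPs in each of blocks 1
and 2 with within-pair r2 in [0.3, 0.9] (confounding but distinguishable) and
one free SNP in block 3. The strong-LD design places q SNPs uniformly.

Effects: "moderate" assigns a random permutation of allelic odds ratios
(1.246, 1.289, 1.332, 1.376, 1.419) — the printed endpoints with evenly
spaced interior values, a reconstruction. "Small" draws |log OR| from
Normal(log 1.25, 0.05 * log 1.25) folded positive with a random sign, giving
odds ratios around 1.25. The intercept solves
`sum_i expit(mu + eta_i) = n/2` by root bracketing, so draws average 50%
cases.

Missingness: per-SNP raw proportions come from a two-part density (80% of
SNPs uniform on [0, 0.5 p], 20% on [0.5 p, 4 p], emulating missingness that
varies strongly from SNP to SNP), rescaled so the overall deleted fraction is
p = 10% by default; deletions land uniformly among a 90% eligible subset of
individuals, so at least 10% of individuals stay complete.

What the generator does not emulate: population stratification and
between-subsample heterogeneity, genotyping batch artifacts, long-range LD,
allele-frequency spectra tied to ascertainment, and missingness correlated
with genotype (the generator's missingness is random given the eligible set).
Conclusions drawn from these simulations therefore speak to the methods'
behavior under clean, homogeneous sampling, not to robustness on messy
cohorts.

## Numerical choices

- Path solver: coordinate descent within an IRLS outer loop (warm starts,
  sequential strong-rule screening, unpenalized intercept), the glmnet
  algorithm. Convergence is certified by the KKT conditions (target 1e-8);
  the inner surrogate threshold is relative (1e-7 of per-sample null
  deviance) and tightens at most twice when progress stalls. Work per grid
  point is bounded by a sweep budget (default 100 full-data passes): on
  ill-conditioned dense path segments — hundreds of highly correlated active
  predictors late in the path — certified high accuracy is unaffordable for
  any coordinate-descent solver, and the budget bounds time while leaving
  sparse, interpretable segments (where selection actually happens) at
  certificate accuracy. A saturation stop carries solutions forward once the
  deviance ratio exceeds 0.999. Coefficients below 1e-12 are stored as exact
  zeros; the active-set threshold is 1e-8.
- IRLS probabilities are clipped at 1e-5; deviance computations clip at
  1e-12.
- Grid snapping: nearest grid value, ties to the larger penalty (sparser
  model). Permutation penalties below the grid floor clamp to the floor.
- Degenerate subsamples (constant response — impossible under stratified
  drawing, guarded anyway) are redrawn up to 10 times.
- Genotype coding is the count of the VCF ALT allele; no minor-allele
  re-polarization (the L1 methods and the LRT are sign-symmetric, asserted in
  tests).

## Problem sizes in the test suite

Unit tests run on toy instances (n <= 200, m <= 12). The end-to-end method
comparison uses the strong-LD design at n = 2,199 with m = 300 (six full-size
50-SNP blocks, preserving within-block proxy structure), q = 5, K = 50
subsamples, 50 replicates, with the stability-selection grid restricted to 40
points down to 0.05 * lambda_max — the sparse region where selection
operates; pilots showed the oracle's initial AUC changes by < 0.01 relative
to the full 100-point grid while costing 7x less. The null-calibration check
runs at n = 1,000, m = 150, K = 50, S = 25.

## Known limitations

- On this generator's homogeneous cohorts, oracle-calibrated Stability
  Selection — which picks, per dataset, the global penalty maximizing the
  very criterion being scored — attains a higher initial AUC than LLARRMA
  (pilot means ~0.45 vs ~0.32 at m = 300; the same ordering holds at the full
  m = 500). LLARRMA's documented advantage over a globally penalized
  competitor is expected to rest on between-subsample heterogeneity of real
  cohorts, which makes any single global penalty locally suboptimal; the
  generator does not reproduce that heterogeneity, and the corresponding
  directional assertion in the acceptance suite fails under these study
  conditions. LLARRMA's advantage over single-locus regression, by contrast,
  reproduces robustly.
- Permutation selection is discovery-calibrated and conservative: in weak
  signal regimes it occasionally selects nothing in every subsample,
  yielding an all-zero RMIP vector for that dataset.
- The naive posterior estimator conditions on at most a few neighbor SNPs
  and is far weaker than haplotype-model imputation; it is a testing
  stand-in, not a recommendation.
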