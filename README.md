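# llarrma

SNP reprioritization within GWAS hit regions by **LASSO local automatic
regularization resample model averaging (LLARRMA)**.

After a genome-wide scan flags a "hit region", local linkage disequilibrium
(LD) makes both the number of true signals and their identities ambiguous:
the top single-locus SNP is usually statistically indistinguishable from its
correlated neighbors, and which neighbor comes out on top is unstable to
resampling. LLARRMA addresses this by asking, for each SNP, how often it
would enter a sparse multi-SNP model under alternative realizations of the
data.

For a case-control phenotype `y_i ~ Bernoulli(p_i)` modeled as

    logit(p_i) = mu + sum_j x_ij * beta_j

with additive-coded, column-centered genotypes, LLARRMA draws K stratified
subsamples, fits an L1-penalized (LASSO) logistic path to each, chooses a
subsample-specific penalty automatically — by permutation selection (the
median over permuted responses of the smallest penalty zeroing all
coefficients) or by complement deviance (out-of-sample prediction on the
held-out individuals) — and records which SNPs are selected. The score per
SNP is its **resample model inclusion probability**,

    RMIP_j = (1/K) * sum_k gamma_hat_jk ,

the fraction of subsamples in which SNP j entered the model. Missing
genotypes are handled by hard, dosage, or multiple imputation (one sampled
imputation per subsample, so imputation uncertainty propagates into the
RMIPs).

The package also implements the standard comparators — single-locus logistic
likelihood-ratio scans and Stability Selection with truth-informed "oracle"
penalty calibration — a synthetic hit-region generator (LD-block genotypes,
calibrated phenotypes, SNP-varying missingness), and windowed ROC/AUC
evaluation with threshold averaging.

This targets one pre-identified hit region (hundreds of SNPs), not
genome-wide scanning.

## Worked example

```python
import numpy as np
from llarrma import simulate as sim
from llarrma import LLARRMA, SingleLocus, TrialResult, trial_auc

# a synthetic 1,493 x 183 moderate-LD hit region with five causal SNPs
ds = sim.simulate_study("study1A", seed=202)
res = LLARRMA(ds.genotypes, ds.response).fit(
    K=100, phi=0.5, criterion="perm", S=25, seed=7
)
print(res.summary(top=8))
```

```
LLARRMA (perm selection)  K=100 phi=0.5 S=25 seed=7
snp_id              RMIP  rank
snp0028            0.840     1
snp0053            0.780     2
snp0024            0.430     3
snp0026            0.360     4
snp0025            0.310     5
snp0054            0.300     6
snp0055            0.280     7
snp0030            0.210     8
```

The dataset's causal SNPs are snp0028, snp0030, snp0053, snp0054 and snp0077
(allelic odds ratios 1.246–1.419). Two causal SNPs head the ranking with
RMIPs 0.84 and 0.78 — they entered the sparse model in 84% and 78% of the 100
subsamples — and two more sit at ranks 6 and 8, while correlated neighbors
(snp0024–snp0026) carry intermediate RMIPs, honestly reflecting that they are
hard to separate from the signals. Scoring the ranking against the truth:

```python
init = trial_auc(TrialResult(res.rmip, ds.truth), 0, 0.05)
sl = SingleLocus(ds.genotypes, ds.response).fit()
init_sl = trial_auc(TrialResult(sl.logp, ds.truth), 0, 0.05)
print(init, init_sl)   # 0.643 vs 0.485
```

The initial AUC (the ROC area restricted to false-positive rates below 5%,
i.e. enrichment among top-ranked SNPs) is 0.643 for LLARRMA against 0.485 for
the single-locus scan on the same data: the resampled multi-SNP model ranks
true signals ahead of their LD proxies more often than one-SNP-at-a-time
testing does.

The same analyses run from the shell:

```sh
llarrma simulate --scenario study1A --seed 202 --out region/
llarrma run --genotypes region/genotypes.csv --phenotypes region/phenotypes.csv \
            --method llarrma-perm --subsamples 100 --seed 7 --out scores.tsv
llarrma evaluate --scores scores.tsv --truth region/truth.json
```

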