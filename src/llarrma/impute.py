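"""Hard, dosage, and sampled imputation from genotype posteriors.

Haplotype-based imputation programs (fastPHASE, IMPUTE, MACH) output a
posterior distribution over genotypes {0, 1, 2} for each missing entry.
This module turns such posteriors into analysis-ready matrices three ways:

- hard: the maximum a posteriori genotype (plug-in point estimate);
- dosage: the posterior expected allele count, a value in [0, 2];
- sampled: one random draw per entry; repeated draws give the ensemble
  consumed by multiple-imputation resampling.

``naive_posterior`` is a deliberately simple built-in posterior estimator
based on joint genotype frequencies with the most-correlated neighboring
SNPs. It exists so the full pipeline runs and can be tested without
external phasing software; it is not a competitor to haplotype-based
imputation and should not be used where accuracy matters.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import GenotypeMatrix, GenotypePosterior

logger = logging.getLogger("llarrma")

MIN_OBSERVED_FOR_JOINT = 20  # below this a SNP falls back to marginal frequencies


def _check_coverage(X: GenotypeMatrix, post: GenotypePosterior) -> dict[tuple[int, int], int]:
    lookup = post.index_lookup()
    missing = np.argwhere(X.mask)
    for i, j in missing:
        if (int(i), int(j)) not in lookup:
            raise ValueError(f"no posterior for missing entry ({i}, {j})")
    return lookup

def _filled(X: GenotypeMatrix, fill: np.ndarray, post: GenotypePosterior) -> GenotypeMatrix:
    out = X.copy()
    out.values[post.rows, post.cols] = np.where(
        np.isnan(out.values[post.rows, post.cols]),
        fill,
        out.values[post.rows, post.cols],
    )
    if np.isnan(out.values).any():
        raise AssertionError("unfilled missing entries remain")
    return out


def hard_impute(X: GenotypeMatrix, post: GenotypePosterior) -> GenotypeMatrix:
    """Replace each missing entry by its maximum a posteriori genotype.

    Probability ties are broken toward the larger genotype (the larger
    expected dosage), so (0.5, 0.5, 0) imputes 1.
    """
    _check_coverage(X, post)
    # argmax with ties to the LARGER index: reverse, argmax, map back
    rev = post.probs[:, ::-1]
    calls = 2 - rev.argmax(axis=1)
    return _filled(X, calls.astype(float), post)


def dosage_impute(X: GenotypeMatrix, post: GenotypePosterior) -> GenotypeMatrix:
    """Replace each missing entry by its posterior expected allele count."""
    _check_coverage(X, post)
    dosage = post.probs[:, 1] + 2.0 * post.probs[:, 2]
    return _filled(X, dosage, post)


def sample_imputation(
    X: GenotypeMatrix, post: GenotypePosterior, rng: np.random.Generator
) -> GenotypeMatrix:
    """Replace each missing entry by an independent draw from its posterior."""
    _check_coverage(X, post)
    u = rng.random(len(post))
    cum = post.probs.cumsum(axis=1)
    draws = (u[:, None] > cum).sum(axis=1)  # inverse-CDF over {0,1,2}
    return _filled(X, draws.astype(float), post)


def _marginal_triple(col: np.ndarray, pseudocount: float = 0.5) -> np.ndarray:
    obs = col[~np.isnan(col)]
    counts = np.array([(obs == g).sum() for g in (0, 1, 2)], dtype=float) + pseudocount
    return counts / counts.sum()


def naive_posterior(
    X: GenotypeMatrix, neighbors: int = 2, pseudocount: float = 0.5
) -> GenotypePosterior:
    """Empirical-frequency posterior for every missing entry.

    For a missing entry (i, j), the posterior over genotypes g at SNP j is
    proportional to the joint frequency (with `pseudocount` added per cell)
    of g together with individual i's observed genotypes at the `neighbors`
    SNPs most correlated with j. SNPs with fewer than 20 observed genotypes,
    or individuals with no observed neighbor genotype, fall back to the
    marginal genotype frequencies of SNP j.
    """
    values = X.values
    n, m = values.shape
    obs_mask = ~np.isnan(values)
    rows_out, cols_out, probs_out = [], [], []

    # column correlations on standardized, mean-filled columns (fast proxy
    # for pairwise-complete Pearson r)
    col_means = np.nanmean(values, axis=0)
    filled = np.where(obs_mask, values, col_means)
    centered = filled - filled.mean(axis=0)
    sd = centered.std(axis=0)
    sd[sd == 0] = 1.0
    Z = centered / sd
    corr = (Z.T @ Z) / n
    np.fill_diagonal(corr, 0.0)

    for j in range(m):
        miss_rows = np.flatnonzero(~obs_mask[:, j])
        if miss_rows.size == 0:
            continue
        marg = _marginal_triple(values[:, j], pseudocount)
        n_obs = int(obs_mask[:, j].sum())
        if n_obs < MIN_OBSERVED_FOR_JOINT:
            logger.warning(
                "SNP %s has only %d observed genotypes; using marginal frequencies",
                X.snp_ids[j], n_obs,
            )
            for i in miss_rows:
                rows_out.append(i), cols_out.append(j), probs_out.append(marg)
            continue
        nb = np.argsort(-np.abs(corr[j]))[:neighbors]
        # joint counts over (g_j, g_nb1, ..., g_nbk) on fully observed rows
        joint = np.full((3,) * (1 + len(nb)), pseudocount)
        complete = obs_mask[:, j] & obs_mask[:, nb].all(axis=1)
        for i in np.flatnonzero(complete):
            idx = (int(values[i, j]),) + tuple(int(values[i, b]) for b in nb)
            joint[idx] += 1.0
        for i in miss_rows:
            obs_nb = [b for b in nb if obs_mask[i, b]]
            if not obs_nb:
                triple = marg
            else:
                # marginalize unobserved neighbors, condition on observed ones
                tab = joint
                for axis_pos, b in reversed(list(enumerate(nb, start=1))):
                    if obs_mask[i, b]:
                        tab = np.take(tab, int(values[i, b]), axis=axis_pos)
                    else:
                        tab = tab.sum(axis=axis_pos)
                triple = tab / tab.sum()
            rows_out.append(i), cols_out.append(j), probs_out.append(triple)

    if not rows_out:
        return GenotypePosterior(
            np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64), np.empty((0, 3))
        )
    return GenotypePosterior(np.array(rows_out), np.array(cols_out), np.array(probs_out))
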