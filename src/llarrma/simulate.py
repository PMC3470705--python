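"""Synthetic hit-region case-control data.

The original cancer and WTCCC '58 genotype datasets behind the simulation
designs are not redistributable, so this module emulates their statistical
structure: LD-block genotypes from haplotype pools, restricted causal-SNP
placement, odds-ratio effect assignment, intercept calibration for a 50/50
case-control balance, Bernoulli phenotype draws, and a missingness
generator with SNP-varying missingness proportions.

Two study templates are provided:

- ``study1`` (emulating a colorectal-cancer hit region on 18q21):
  n = 1,493 individuals, m = 183 SNPs in blocks of moderate LD; five causal
  SNPs -- two pairs placed within LD blocks subject to a within-pair r^2
  window plus one free SNP -- with moderate (study 1A) or small (study 1B)
  effects; ~10% missing genotypes available on request.
- ``study2`` (emulating a WTCCC '58 birth-cohort region on chromosome 22):
  n = 2,199 individuals, m = 500 SNPs in blocks of strong LD; q causal SNPs
  placed uniformly at random with small effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .containers import CaseControlResponse, GenotypeMatrix

logger = logging.getLogger("llarrma")

# Moderate-effect allelic odds ratios. The printed endpoints are 1.246 and
# 1.419; the three interior values are an evenly spaced reconstruction.
MODERATE_ODDS = np.array([1.246, 1.289, 1.332, 1.376, 1.419])
SMALL_EFFECT_MEAN_OR = 1.25
SMALL_EFFECT_REL_SD = 0.05

R2_WINDOW = (0.3, 0.9)  # within-pair r^2 for restricted causal placement


@dataclass
class LDBlockSpec:
    """One LD block generated from a founder haplotype pool.

    The founder haplotypes are generated as flip chains along the block:
    founder alleles at the first SNP are independent draws at a random
    frequency in [0.05, 0.95], and each founder's allele flips with per-SNP
    probability ``pool_mutation_rate``, so founder columns carry gradually
    decaying LD. Each individual's haplotype copy is then a mosaic of the
    pool members: it starts from a random founder and switches to a new
    random founder with per-SNP probability ``recombination_rate``, with a
    per-SNP copy-error flip probability ``mutation_rate``. Low pool
    mutation and switch rates give strong, gradually decaying within-block
    LD. When ``recombine_at_boundary`` is False, individuals enter the
    block on the founder they left the previous block with (requires equal
    pool sizes), extending LD across the boundary.
    """

    n_snps: int
    pool_size: int = 8
    pool_mutation_rate: float = 0.05
    mutation_rate: float = 0.01
    recombination_rate: float = 0.05
    recombine_at_boundary: bool = True

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("block must contain at least one SNP")
        if self.pool_size < 2:
            raise ValueError("haplotype pool needs at least two members")


# block layouts emulating the two hit regions: a mixture of high and low LD
STUDY1_BLOCKS = [
    LDBlockSpec(35, pool_size=8, pool_mutation_rate=0.05, mutation_rate=0.01,
                recombination_rate=0.04),
    LDBlockSpec(30, pool_size=8, pool_mutation_rate=0.05, mutation_rate=0.01,
                recombination_rate=0.04),
    LDBlockSpec(25, pool_size=8, pool_mutation_rate=0.06, mutation_rate=0.01,
                recombination_rate=0.05),
    LDBlockSpec(35, pool_size=10, pool_mutation_rate=0.12, mutation_rate=0.02,
                recombination_rate=0.10),
    LDBlockSpec(30, pool_size=10, pool_mutation_rate=0.12, mutation_rate=0.02,
                recombination_rate=0.10),
    LDBlockSpec(28, pool_size=12, pool_mutation_rate=0.20, mutation_rate=0.02,
                recombination_rate=0.20),
]  # 183 SNPs, moderate LD

STUDY2_BLOCKS = [
    LDBlockSpec(
        50,
        pool_size=8,
        pool_mutation_rate=0.015 + 0.02 * (b % 3),
        mutation_rate=0.005,
        recombination_rate=0.01 + 0.01 * (b % 3),
    )
    for b in range(10)
]  # 500 SNPs, strong LD with interspersed weaker stretches

STUDY1_N = 1493
STUDY2_N = 2199


@dataclass
class TrueModel:
    """Ground truth of one simulated trial."""

    causal_indices: np.ndarray
    beta: np.ndarray  # log-odds effects, one per causal SNP
    mu: float  # intercept calibrated for a 50/50 case-control split
    causal_blocks: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.causal_indices = np.asarray(self.causal_indices, dtype=np.int64)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.causal_indices.size < 1:
            raise ValueError("need at least one causal SNP")
        if np.unique(self.causal_indices).size != self.causal_indices.size:
            raise ValueError("causal indices must be distinct")

    def truth_vector(self, m: int) -> np.ndarray:
        truth = np.zeros(m, dtype=np.int8)
        truth[self.causal_indices] = 1
        return truth


@dataclass
class MissingnessSpec:
    """Configuration of the empirical missingness generator.

    ``p_total`` is the overall fraction of genotype entries to delete;
    ``eligible_fraction`` bounds the individuals who may receive missing
    genotypes (the rest stay complete). Per-SNP raw proportions come from
    ``density``: by default 80% of SNPs draw Uniform(0, 0.5*p_total) and
    20% draw Uniform(0.5*p_total, 4*p_total), mimicking missingness that
    varies considerably from SNP to SNP.
    """

    p_total: float = 0.10
    eligible_fraction: float = 0.9
    density: object = None  # callable (m, rng) -> per-SNP raw proportions

    def __post_init__(self) -> None:
        if not 0 <= self.p_total < 1:
            raise ValueError("p_total must be in [0, 1)")
        if not 0 < self.eligible_fraction <= 0.9:
            raise ValueError(
                "eligible_fraction must be in (0, 0.9] so >=10% of individuals "
                "stay complete"
            )

    def draw_proportions(self, m: int, rng: np.random.Generator) -> np.ndarray:
        if self.density is not None:
            return np.asarray(self.density(m, rng), dtype=float)
        q = rng.uniform(0.0, 0.5 * self.p_total, size=m)
        heavy = rng.random(m) < 0.2
        q[heavy] = rng.uniform(0.5 * self.p_total, 4.0 * self.p_total, size=int(heavy.sum()))
        return q


def simulate_genotypes(
    n: int,
    specs: list[LDBlockSpec],
    rng: np.random.Generator,
    positions_start: int = 1,
    position_step: int = 2500,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Generate LD-block genotypes for n individuals.

    Per block: a founder haplotype pool with allele frequencies drawn in
    [0.05, 0.95]; each individual gets two haplotype copies, each a mosaic
    of pool members (per-SNP founder-switch probability = recombination
    rate) with per-SNP mutation. The genotype is the allele sum, giving
    gradually decaying within-block LD; blocks are independent unless a
    block declines recombination at its boundary. Returns the matrix plus
    each SNP's block index. Monomorphic SNPs are regenerated (new pool
    column) up to 10 times.
    """
    if n < 50:
        raise ValueError("need n >= 50 individuals")
    cols, block_ids = [], []
    prev_idx = (None, None)
    prev_pool_size = None
    for b, spec in enumerate(specs):
        mb = spec.n_snps
        pool = np.empty((spec.pool_size, mb), dtype=np.int8)
        base_freq = rng.uniform(0.05, 0.95)
        pool[:, 0] = rng.random(spec.pool_size) < base_freq
        for j in range(1, mb):
            flips = rng.random(spec.pool_size) < spec.pool_mutation_rate
            pool[:, j] = pool[:, j - 1] ^ flips
        # keep every founder column polymorphic, so pool allele frequencies
        # stay within [1/pool_size, 1 - 1/pool_size] (inside [0.05, 0.95])
        for j in range(mb):
            if pool[:, j].min() == pool[:, j].max():
                pool[rng.integers(0, spec.pool_size), j] ^= 1
        # mosaic founder indices for both chromosome copies, shape (n, mb)
        idx_pair = []
        for c in range(2):
            if (
                not spec.recombine_at_boundary
                and prev_idx[c] is not None
                and prev_pool_size == spec.pool_size
            ):
                cur = prev_idx[c][:, -1].copy()
            else:
                cur = rng.integers(0, spec.pool_size, size=n)
            I = np.empty((n, mb), dtype=np.int64)
            I[:, 0] = cur
            for j in range(1, mb):
                switch = rng.random(n) < spec.recombination_rate
                cur = np.where(switch, rng.integers(0, spec.pool_size, size=n), cur)
                I[:, j] = cur
            idx_pair.append(I)
        snp_axis = np.arange(mb)
        h1 = pool[idx_pair[0], snp_axis]
        h2 = pool[idx_pair[1], snp_axis]
        if spec.mutation_rate > 0:
            h1 = h1 ^ (rng.random((n, mb)) < spec.mutation_rate)
            h2 = h2 ^ (rng.random((n, mb)) < spec.mutation_rate)
        G = (h1 + h2).astype(float)
        for j in range(mb):
            for attempt in range(10):
                if G[:, j].min() != G[:, j].max():
                    break
                newcol = (rng.random(spec.pool_size) < rng.uniform(0.05, 0.95)).astype(np.int8)
                c1 = newcol[idx_pair[0][:, j]] ^ (rng.random(n) < spec.mutation_rate)
                c2 = newcol[idx_pair[1][:, j]] ^ (rng.random(n) < spec.mutation_rate)
                G[:, j] = c1 + c2
            else:
                raise RuntimeError(f"SNP {j} of block {b} stayed monomorphic")
        cols.append(G)
        block_ids.extend([b] * mb)
        prev_idx = tuple(idx_pair)
        prev_pool_size = spec.pool_size
    values = np.hstack(cols)
    m = values.shape[1]
    gm = GenotypeMatrix(
        values,
        snp_ids=[f"snp{j:04d}" for j in range(m)],
        sample_ids=[f"ind{i:05d}" for i in range(n)],
        positions=positions_start + position_step * np.arange(m),
    )
    return gm, np.asarray(block_ids)


def _pair_r2(x: np.ndarray, z: np.ndarray) -> float:
    r = np.corrcoef(x, z)[0, 1]
    return float(r * r)


def place_causal(
    X: GenotypeMatrix,
    blocks: np.ndarray,
    scenario: str,
    rng: np.random.Generator,
    q: int = 5,
    r2_window: tuple[float, float] = R2_WINDOW,
    max_tries: int = 1000,
) -> np.ndarray:
    """Choose causal SNP indices.

    ``study1``: two SNPs from block 1 and two from block 2, each pair with
    within-pair r^2 inside ``r2_window`` (confounding correlation without
    redundancy), plus one SNP at random from block 3 -- five in total.
    ``study2``: q indices uniform without replacement among all SNPs.
    """
    values = X.values
    if scenario == "study2":
        return np.sort(rng.choice(X.m, size=q, replace=False))
    if scenario != "study1":
        raise ValueError(f"unknown scenario {scenario!r}")

    chosen = []
    for block in (0, 1):
        members = np.flatnonzero(blocks == block)
        for _ in range(max_tries):
            pair = rng.choice(members, size=2, replace=False)
            r2 = _pair_r2(values[:, pair[0]], values[:, pair[1]])
            if r2_window[0] <= r2 <= r2_window[1]:
                chosen.extend(pair.tolist())
                break
        else:
            r2s = [
                _pair_r2(values[:, a], values[:, b])
                for a in members[:20]
                for b in members[:20]
                if a < b
            ]
            raise RuntimeError(
                f"no SNP pair in block {block} with r^2 in {r2_window} after "
                f"{max_tries} tries; block r^2 range [{min(r2s):.3f}, {max(r2s):.3f}]"
            )
    block3 = np.flatnonzero(blocks == 2)
    chosen.append(int(rng.choice(block3)))
    return np.array(sorted(chosen))


def assign_effects(q: int, mode: str, rng: np.random.Generator) -> np.ndarray:
    """Log-odds effects for q causal SNPs.

    ``moderate`` (q must be 5): a uniformly random permutation of the
    moderate odds-ratio vector, on the log-odds scale. ``small``: each
    effect is s * |z| with random sign s and |z| ~ Normal(log 1.25,
    0.05 * log 1.25) folded positive -- allelic odds ratios around 1.25.
    """
    if q < 1:
        raise ValueError("need at least one causal SNP")
    if mode == "moderate":
        if q != 5:
            raise ValueError("moderate mode assigns exactly 5 effects")
        return np.log(rng.permutation(MODERATE_ODDS))
    if mode == "small":
        mean = np.log(SMALL_EFFECT_MEAN_OR)
        mag = np.abs(rng.normal(mean, SMALL_EFFECT_REL_SD * mean, size=q))
        signs = rng.choice([-1.0, 1.0], size=q)
        return signs * mag
    raise ValueError(f"unknown effect mode {mode!r}")


def compute_intercept(eta: np.ndarray) -> float:
    """Intercept giving an expected 50/50 case-control split.

    Solves sum_i expit(mu + eta_i) = n/2 by root bracketing; the solution
    exists and is unique by monotonicity.
    """
    eta = np.asarray(eta, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise ValueError("linear predictor must be finite")
    n = eta.size
    target = n / 2.0

    def f(mu: float) -> float:
        return float(expit(mu + eta).sum() - target)

    if f(0.0) == 0.0:
        return 0.0
    lo, hi = -50.0, 50.0
    mu = brentq(f, lo, hi, xtol=1e-12)
    assert abs(f(mu)) <= 1e-6 * n
    return float(mu)


def simulate_phenotypes(
    X: GenotypeMatrix, model: TrueModel, rng: np.random.Generator
) -> CaseControlResponse:
    """Bernoulli phenotypes from the additive logistic model.

    p_i = expit(mu + sum over causal SNPs of centered genotype * effect).
    """
    xc = X.values[:, model.causal_indices]
    if np.isnan(xc).any():
        raise ValueError("causal SNP genotypes must be complete")
    xc = xc - xc.mean(axis=0)
    p = expit(model.mu + xc @ model.beta)
    return CaseControlResponse(rng.binomial(1, p))


def generate_missingness(
    X: GenotypeMatrix, spec: MissingnessSpec, rng: np.random.Generator
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Delete genotypes to an overall target fraction with SNP-varying rates.

    Per-SNP raw proportions q_j are drawn from the configured density,
    rescaled by c = p_total * m / sum(q_j) so the overall deleted fraction
    is p_total up to per-SNP rounding, and deletions land uniformly among
    the eligible individuals. Ineligible individuals stay fully observed.
    """
    n, m = X.n, X.m
    n_eligible = int(np.floor(spec.eligible_fraction * n))
    eligible = rng.choice(n, size=n_eligible, replace=False)
    for attempt in range(10):
        q = spec.draw_proportions(m, rng)
        if spec.p_total == 0:
            d = np.zeros(m, dtype=np.int64)
            break
        c = spec.p_total * m / q.sum()
        d = np.round(c * q * n).astype(np.int64)
        if d.max() <= n_eligible:
            break
        logger.warning("missingness draw %d exceeded eligible count; redrawing", attempt)
    else:
        raise RuntimeError("could not satisfy per-SNP missingness within eligible set")

    out = X.copy()
    for j in range(m):
        if d[j] > 0:
            hit = rng.choice(eligible, size=d[j], replace=False)
            out.values[hit, j] = np.nan
    return out, out.mask


@dataclass
class SimulatedStudy:
    """One simulated hit-region trial."""

    genotypes: GenotypeMatrix  # complete
    response: CaseControlResponse
    true_model: TrueModel
    blocks: np.ndarray
    scenario: str
    incomplete: GenotypeMatrix | None = None
    mask: np.ndarray | None = field(default=None, repr=False)

    @property
    def truth(self) -> np.ndarray:
        return self.true_model.truth_vector(self.genotypes.m)


def _tile_blocks(blocks: list[LDBlockSpec], m: int) -> list[LDBlockSpec]:
    """Cycle the block patterns at full block size until m SNPs are reached,
    preserving the within-block LD scale (proxy richness) at reduced m."""
    out, acc, i = [], 0, 0
    while acc < m:
        b = blocks[i % len(blocks)]
        nb = min(b.n_snps, m - acc)
        out.append(
            LDBlockSpec(
                nb,
                pool_size=b.pool_size,
                pool_mutation_rate=b.pool_mutation_rate,
                mutation_rate=b.mutation_rate,
                recombination_rate=b.recombination_rate,
                recombine_at_boundary=b.recombine_at_boundary,
            )
        )
        acc += nb
        i += 1
    return out


def _scale_blocks(blocks: list[LDBlockSpec], m: int | None) -> list[LDBlockSpec]:
    if m is None:
        return blocks
    total = sum(b.n_snps for b in blocks)
    out, acc = [], 0
    for i, b in enumerate(blocks):
        nb = max(1, round(b.n_snps * m / total)) if i < len(blocks) - 1 else m - acc
        if nb < 1:
            raise ValueError("m too small for the block layout")
        out.append(
            LDBlockSpec(
                nb,
                pool_size=b.pool_size,
                pool_mutation_rate=b.pool_mutation_rate,
                mutation_rate=b.mutation_rate,
                recombination_rate=b.recombination_rate,
                recombine_at_boundary=b.recombine_at_boundary,
            )
        )
        acc += nb
    return out


def simulate_study(
    scenario: str,
    seed=None,
    q: int = 5,
    n: int | None = None,
    m: int | None = None,
    with_missingness: bool = False,
    missingness: MissingnessSpec | None = None,
) -> SimulatedStudy:
    """End-to-end scenario builder: ``study1A``, ``study1B`` or ``study2``.

    study1A/1B use n=1,493 and m=183 with restricted causal placement and
    moderate/small effects; study2 uses n=2,199 and m=500 with q causal
    SNPs placed uniformly and small effects. ``n``/``m`` override the
    design sizes for reduced-scale runs.
    """
    from .resampling import child_rng

    if scenario not in ("study1A", "study1B", "study2"):
        raise ValueError(f"unknown scenario {scenario!r}")
    base = "study1" if scenario.startswith("study1") else "study2"
    if base == "study1":
        blocks_spec = _scale_blocks(STUDY1_BLOCKS, m)
    else:
        blocks_spec = STUDY2_BLOCKS if m is None else _tile_blocks(STUDY2_BLOCKS, m)
    n_eff = n if n is not None else (STUDY1_N if base == "study1" else STUDY2_N)

    geno_rng = child_rng(seed, 0)
    X, blocks = simulate_genotypes(n_eff, blocks_spec, geno_rng)

    place_rng = child_rng(seed, 1)
    if base == "study1":
        causal = place_causal(X, blocks, "study1", place_rng)
        mode = "moderate" if scenario == "study1A" else "small"
    else:
        causal = place_causal(X, blocks, "study2", place_rng, q=q)
        mode = "small"
    beta = assign_effects(causal.size, mode, child_rng(seed, 2))

    xc = X.values[:, causal]
    xc = xc - xc.mean(axis=0)
    mu = compute_intercept(xc @ beta)
    model = TrueModel(causal, beta, mu, causal_blocks=blocks[causal])
    y = simulate_phenotypes(X, model, child_rng(seed, 3))

    study = SimulatedStudy(
        genotypes=X, response=y, true_model=model, blocks=blocks, scenario=scenario
    )
    if with_missingness:
        spec = missingness if missingness is not None else MissingnessSpec()
        study.incomplete, study.mask = generate_missingness(X, spec, child_rng(seed, 4))
    return study
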