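"""Synthetic hit-region generator: LD structure, effects, phenotypes,
missingness."""

import numpy as np
import pytest

from llarrma import simulate as sim
from llarrma.containers import CaseControlResponse
from llarrma.resampling import child_rng
from llarrma.simulate import (
    LDBlockSpec,
    MissingnessSpec,
    MODERATE_ODDS,
    TrueModel,
    assign_effects,
    compute_intercept,
    generate_missingness,
    place_causal,
    simulate_genotypes,
    simulate_phenotypes,
    simulate_study,
)


class TestSimulateGenotypes:
    def test_no_recombination_tiny_pool_gives_near_perfect_ld(self):
        spec = [LDBlockSpec(6, pool_size=2, pool_mutation_rate=0.0,
                            mutation_rate=0.0, recombination_rate=0.0)]
        gm, _ = simulate_genotypes(2000, spec, child_rng(0))
        r = np.corrcoef(gm.values.T)
        assert np.abs(r[np.triu_indices(6, 1)]).min() > 0.95

    def test_between_block_independence(self):
        specs = [LDBlockSpec(10, pool_size=4, recombination_rate=0.02),
                 LDBlockSpec(10, pool_size=4, recombination_rate=0.02)]
        gm, blocks = simulate_genotypes(2000, specs, child_rng(1))
        r = np.corrcoef(gm.values.T)
        between = np.abs(r[np.ix_(blocks == 0, blocks == 1)])
        assert between.mean() < 0.05

    def test_within_block_ld_decays_with_distance(self):
        spec = [LDBlockSpec(30, pool_size=8, pool_mutation_rate=0.04,
                            mutation_rate=0.005, recombination_rate=0.02)]
        gm, _ = simulate_genotypes(1500, spec, child_rng(2))
        r2 = np.corrcoef(gm.values.T) ** 2
        near = np.mean([r2[j, j + 1] for j in range(29)])
        far = np.mean([r2[j, j + 20] for j in range(10)])
        assert near > far

    def test_all_snps_polymorphic_and_in_range(self):
        gm, _ = simulate_genotypes(200, sim.STUDY1_BLOCKS, child_rng(3))
        assert gm.values.min() >= 0 and gm.values.max() <= 2
        assert np.all(gm.values.std(axis=0) > 0)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            simulate_genotypes(10, [LDBlockSpec(5)], child_rng(0))


class TestPlaceCausal:
    def test_study1_block_counts(self):
        ds_rng = child_rng(4)
        gm, blocks = simulate_genotypes(800, sim.STUDY1_BLOCKS, ds_rng)
        for rep in range(5):
            idx = place_causal(gm, blocks, "study1", child_rng(5, rep))
            assert idx.size == 5 and np.unique(idx).size == 5
            counts = [int((blocks[idx] == b).sum()) for b in (0, 1, 2)]
            assert counts == [2, 2, 1]

    def test_study1_pair_r2_inside_window(self):
        gm, blocks = simulate_genotypes(800, sim.STUDY1_BLOCKS, child_rng(6))
        idx = place_causal(gm, blocks, "study1", child_rng(7))
        for b in (0, 1):
            pair = idx[blocks[idx] == b]
            r = np.corrcoef(gm.values[:, pair[0]], gm.values[:, pair[1]])[0, 1]
            assert 0.3 <= r * r <= 0.9

    def test_study2_uniform_q(self):
        gm, blocks = simulate_genotypes(200, sim.STUDY2_BLOCKS[:2], child_rng(8))
        idx = place_causal(gm, blocks, "study2", child_rng(9), q=7)
        assert idx.size == 7 and np.unique(idx).size == 7

    def test_study2_all_causal_when_q_equals_m(self):
        gm, blocks = simulate_genotypes(100, [LDBlockSpec(8, pool_size=4)], child_rng(10))
        idx = place_causal(gm, blocks, "study2", child_rng(11), q=8)
        assert np.array_equal(idx, np.arange(8))

    def test_impossible_window_errors(self):
        gm, blocks = simulate_genotypes(500, sim.STUDY1_BLOCKS, child_rng(12))
        with pytest.raises(RuntimeError, match="r\\^2"):
            place_causal(gm, blocks, "study1", child_rng(13),
                         r2_window=(0.99999, 1.0), max_tries=50)


class TestAssignEffects:
    def test_moderate_is_permutation_of_default_odds(self):
        beta = assign_effects(5, "moderate", child_rng(14))
        assert np.allclose(np.sort(np.exp(beta)), np.sort(MODERATE_ODDS))

    def test_moderate_odds_range_endpoints(self):
        beta = assign_effects(5, "moderate", child_rng(15))
        odds = np.exp(beta)
        assert odds.min() == pytest.approx(1.246)
        assert odds.max() == pytest.approx(1.419)

    def test_moderate_requires_q5(self):
        with pytest.raises(ValueError):
            assign_effects(3, "moderate", child_rng(0))

    def test_small_effects_monte_carlo_mean(self):
        beta = assign_effects(10000, "small", child_rng(16))
        assert np.exp(np.abs(beta)).mean() == pytest.approx(1.25, abs=0.01)
        # signs are balanced
        assert abs(np.mean(np.sign(beta))) < 0.05


class TestComputeIntercept:
    def test_zero_eta(self):
        assert compute_intercept(np.zeros(10)) == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_eta(self):
        eta = np.array([-2.0, -1.0, 1.0, 2.0])
        assert compute_intercept(eta) == pytest.approx(0.0, abs=1e-9)

    def test_self_consistency(self):
        from scipy.special import expit

        rng = child_rng(17)
        eta = rng.normal(0.4, 1.2, size=1500)
        mu = compute_intercept(eta)
        assert expit(mu + eta).sum() == pytest.approx(750, abs=1e-4 * 1500)


class TestSimulatePhenotypes:
    def test_zero_effects_give_fair_coin(self):
        gm, _ = simulate_genotypes(4000, [LDBlockSpec(3, pool_size=4)], child_rng(18))
        model = TrueModel(np.array([0]), np.array([0.0]), mu=0.0)
        y = simulate_phenotypes(gm, model, child_rng(19))
        assert abs(y.y.mean() - 0.5) < 0.03

    def test_fixed_seed_reproducible(self):
        gm, blocks = simulate_genotypes(300, [LDBlockSpec(5, pool_size=4)], child_rng(20))
        model = TrueModel(np.array([1]), np.array([0.4]), mu=0.1)
        y1 = simulate_phenotypes(gm, model, child_rng(21))
        y2 = simulate_phenotypes(gm, model, child_rng(21))
        assert np.array_equal(y1.y, y2.y)

    def test_calibrated_intercept_gives_half_cases(self):
        ds = simulate_study("study1A", seed=22)
        fracs = [
            simulate_phenotypes(ds.genotypes, ds.true_model, child_rng(23, r)).y.mean()
            for r in range(200)
        ]
        assert np.mean(fracs) == pytest.approx(0.5, abs=0.02)


class TestGenerateMissingness:
    def test_zero_target_deletes_nothing(self):
        gm, _ = simulate_genotypes(100, [LDBlockSpec(5, pool_size=4)], child_rng(24))
        out, mask = generate_missingness(gm, MissingnessSpec(p_total=0.0), child_rng(25))
        assert mask.sum() == 0

    def test_ineligible_individuals_stay_complete(self):
        gm, _ = simulate_genotypes(200, [LDBlockSpec(20, pool_size=6)], child_rng(26))
        out, mask = generate_missingness(gm, MissingnessSpec(), child_rng(27))
        incomplete_rows = mask.any(axis=1).sum()
        assert incomplete_rows <= int(0.9 * 200)

    def test_realized_fraction_near_target(self):
        ds = simulate_study("study1A", seed=28)
        out, mask = generate_missingness(ds.genotypes, MissingnessSpec(), child_rng(29))
        realized = mask.mean()
        assert abs(realized - 0.10) < 0.001

    def test_eligible_fraction_bounds(self):
        with pytest.raises(ValueError):
            MissingnessSpec(eligible_fraction=0.95)
        with pytest.raises(ValueError):
            MissingnessSpec(p_total=1.0)


class TestScenarioBuilders:
    def test_study1_design_sizes(self):
        ds = simulate_study("study1A", seed=30)
        assert ds.genotypes.values.shape == (1493, 183)
        assert ds.truth.sum() == 5

    def test_study2_design_sizes(self):
        ds = simulate_study("study2", seed=31, q=3)
        assert ds.genotypes.values.shape == (2199, 500)
        assert ds.truth.sum() == 3

    def test_study1b_uses_small_effects(self):
        ds = simulate_study("study1B", seed=32)
        odds = np.exp(np.abs(ds.true_model.beta))
        assert np.all((odds > 1.1) & (odds < 1.45))
        assert not np.allclose(np.sort(np.exp(ds.true_model.beta)), np.sort(MODERATE_ODDS))

    def test_missingness_on_request(self):
        ds = simulate_study("study1A", seed=33, with_missingness=True)
        assert ds.incomplete is not None
        assert 0.08 < np.isnan(ds.incomplete.values).mean() < 0.12

    def test_signals_detectable_by_single_locus(self):
        """On study1A draws, at least one causal SNP ranks in the single-locus
        top 10 in nearly every replicate (signals are detectable by design)."""
        from llarrma.competitors import single_locus_scores

        hits = 0
        reps = 25
        for r in range(reps):
            ds = simulate_study("study1A", seed=600 + r)
            scores = single_locus_scores(ds.genotypes, ds.response)
            top10 = np.argsort(-scores)[:10]
            if np.intersect1d(top10, ds.true_model.causal_indices).size >= 1:
                hits += 1
        assert hits >= 0.9 * reps
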