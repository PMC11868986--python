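import numpy as np
import pytest

from regsnap.binding_disruption import (
    DisruptionResult,
    NullCache,
    REF_MISMATCH,
    affinity_pvalue,
    affinity_pass_count,
    best_scores_batch,
    call_disrupting,
    evaluate_variants,
    rank_pvalue,
    score_variant,
)
from regsnap.genotypes_ld import VariantSite
from regsnap.motif_core import BackgroundModel, PWM, best_match_score, log_odds

from conftest import random_pwm
from oracles import (
    naive_exact_affinity_p,
    naive_exact_rank_p,
    naive_log_odds,
)


class TestAffinityPvalue:
    def test_below_minimum_is_one(self, small_pwm, uniform_bg):
        p, _ = affinity_pvalue(-1e9, small_pwm, uniform_bg, 5, 2, "exact")
        assert p == 1.0

    def test_above_maximum_is_zero(self, small_pwm, uniform_bg):
        p, _ = affinity_pvalue(1e9, small_pwm, uniform_bg, 5, 2, "exact")
        assert p == 0.0

    def test_exact_matches_enumeration(self, rng, uniform_bg):
        for _ in range(6):
            pwm = random_pwm(rng, int(rng.integers(1, 3)))
            lo = naive_log_odds(pwm.probs.tolist(), [0.25] * 4)
            observed = float(rng.normal(0, 1))
            p, se = affinity_pvalue(observed, pwm, uniform_bg, 3, 1, "exact")
            expected = naive_exact_affinity_p(lo, [0.25] * 4, 3, 1, observed)
            assert se is None
            assert p == pytest.approx(expected, abs=1e-12)

    def test_exact_nonuniform_background(self, rng):
        bg = BackgroundModel(np.array([0.4, 0.1, 0.2, 0.3]))
        pwm = random_pwm(rng, 2)
        lo = naive_log_odds(pwm.probs.tolist(), [0.4, 0.1, 0.2, 0.3])
        observed = 0.5
        p, _ = affinity_pvalue(observed, pwm, bg, 4, 2, "exact")
        expected = naive_exact_affinity_p(lo, [0.4, 0.1, 0.2, 0.3], 4, 2,
                                          observed)
        assert p == pytest.approx(expected, abs=1e-12)

    def test_mc_within_3se(self, rng, uniform_bg):
        pwm = random_pwm(rng, 2)
        cache = NullCache(3, 50_000)
        observed = 1.0
        exact, _ = affinity_pvalue(observed, pwm, uniform_bg, 4, 2, "exact")
        mc, se = affinity_pvalue(observed, pwm, uniform_bg, 4, 2, "mc",
                                 n_mc=50_000, cache=cache)
        assert abs(mc - exact) <= 3 * max(se, 1e-4)

    def test_exact_refused_for_long_scans(self, small_pwm, uniform_bg):
        with pytest.raises(ValueError):
            affinity_pvalue(0.0, small_pwm, uniform_bg, 41, 20, "exact")

    def test_invalid_mode(self, small_pwm, uniform_bg):
        with pytest.raises(ValueError):
            affinity_pvalue(0.0, small_pwm, uniform_bg, 5, 2, "bogus")


class TestRankPvalue:
    def test_identical_alleles(self, small_pwm, uniform_bg):
        p, _ = rank_pvalue(small_pwm, "ACGTA", 2, "G", "G", uniform_bg)
        assert p == 1.0

    def test_allele_blind_motif(self, uniform_bg):
        flat = PWM("flat", np.full((2, 4), 0.25))
        p, _ = rank_pvalue(flat, "ACGTA", 2, "A", "C", uniform_bg, "exact")
        assert p == 1.0

    def test_exact_matches_enumeration(self, rng, uniform_bg):
        for _ in range(4):
            pwm = random_pwm(rng, 3)
            lo = naive_log_odds(pwm.probs.tolist(), [0.25] * 4)
            window = "".join(rng.choice(list("ACGT"), size=5))
            ref, alt = "A", "G"
            p, _ = rank_pvalue(pwm, window, 2, ref, alt, uniform_bg, "exact")
            from oracles import naive_best_score
            s_ref = naive_best_score(lo, window[:2] + ref + window[3:], 2)
            s_alt = naive_best_score(lo, window[:2] + alt + window[3:], 2)
            expected = naive_exact_rank_p(lo, [0.25] * 4, 5, 2, ref, alt,
                                          abs(s_ref - s_alt))
            assert p == pytest.approx(expected, abs=1e-12)

    def test_mc_within_3se(self, rng, uniform_bg):
        pwm = random_pwm(rng, 3)
        window = "ACGTA"
        exact, _ = rank_pvalue(pwm, window, 2, "A", "G", uniform_bg, "exact")
        mc, se = rank_pvalue(pwm, window, 2, "A", "G", uniform_bg, "mc",
                             n_mc=50_000, cache=NullCache(5, 50_000))
        assert abs(mc - exact) <= 3 * max(se, 1e-4)


class TestScoreVariant:
    @pytest.fixture
    def reference(self):
        return {"chr1": "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT"}

    def test_ref_mismatch(self, small_pwm, reference):
        var = VariantSite("chr1", 10, "v", "T", ("C",))  # actual base is G
        with pytest.raises(REF_MISMATCH):
            score_variant(small_pwm, reference, var)

    def test_same_allele_direction_none(self, small_pwm, reference):
        var = VariantSite("chr1", 10, "v", "G", ("G",))
        (res,) = score_variant(small_pwm, reference, var)
        assert res.direction == "none"
        assert res.p_rank == 1.0
        assert res.score_ref == res.score_alt

    def test_multiallelic_one_result_per_alt(self, small_pwm, reference):
        var = VariantSite("chr1", 10, "v", "G", ("A", "C"))
        results = score_variant(small_pwm, reference, var)
        assert len(results) == 2

    def test_truncated_scan_near_contig_start(self, small_pwm, reference):
        var = VariantSite("chr1", 1, "v", "C", ("A",))
        (res,) = score_variant(small_pwm, reference, var)
        assert np.isfinite(res.score_ref)

    def test_scores_match_best_match_score(self, small_pwm, reference,
                                           uniform_bg):
        var = VariantSite("chr1", 20, "v", "A", ("T",))
        (res,) = score_variant(small_pwm, reference, var, half_window=20,
                               background=uniform_bg)
        window = reference["chr1"][0:41]
        expected, _, _ = best_match_score(small_pwm, window, 20, "T",
                                          uniform_bg)
        assert res.score_alt == pytest.approx(expected, abs=1e-12)


class TestBatchScores:
    def test_batch_agrees_with_single(self, rng, uniform_bg):
        pwm = random_pwm(rng, 4)
        lo = log_odds(pwm, uniform_bg)
        codes = rng.integers(0, 4, size=(50, 9)).astype(np.int8)
        batch = best_scores_batch(codes, lo, 4)
        from regsnap.motif_core import decode
        for i in range(50):
            seq = decode(codes[i])
            expected, _, _ = best_match_score(pwm, seq, 4, seq[4], uniform_bg)
            assert batch[i] == pytest.approx(expected, abs=1e-9)


class TestCallDisrupting:
    def _res(self, p_ref, p_alt, p_rank, vid="v", motif="m"):
        return DisruptionResult(vid, motif, 1.0, 0.0, p_ref, p_alt, p_rank,
                                "loss")

    def test_two_gate_rule_kept(self):
        results = [self._res(0.0005, 0.2, 0.004)]
        kept, summary = call_disrupting(results, n_tests=10)
        assert len(kept) == 1  # 0.004 < 0.05/10

    def test_affinity_gate_fails(self):
        results = [self._res(0.002, 0.002, 1e-9)]
        kept, _ = call_disrupting(results, n_tests=10)
        assert kept == []

    def test_rank_gate_fails(self):
        results = [self._res(0.0001, 0.5, 0.04)]
        kept, _ = call_disrupting(results, n_tests=10)
        assert kept == []  # 0.04 >= 0.005

    def test_default_n_tests_is_result_count(self):
        results = [self._res(0.0001, 0.5, 0.004) for _ in range(10)]
        kept, summary = call_disrupting(results)
        assert summary["n_tests"] == 10
        assert len(kept) == 10

    def test_n_tests_validation(self):
        with pytest.raises(ValueError):
            call_disrupting([self._res(0.1, 0.1, 0.1)], n_tests=0)

    def test_summary_counts_direction(self):
        results = [self._res(1e-5, 0.5, 1e-6, vid=f"v{i}") for i in range(3)]
        results[0].direction = "gain"
        kept, summary = call_disrupting(results, n_tests=3)
        assert summary["per_motif"]["m"] == {"loss": 2, "gain": 1, "none": 0}

    def test_affinity_pass_count(self):
        results = [self._res(0.0005, 0.9, 0.5), self._res(0.5, 0.9, 0.5)]
        assert affinity_pass_count(results) == 1


class TestEvaluateVariants:
    def test_exact_small_scan(self, uniform_bg, rng):
        reference = {"chr1": "ACGTACGTA"}
        pwm = random_pwm(rng, 2)
        var = VariantSite("chr1", 4, "v", "A", ("G",))
        results = evaluate_variants([pwm], reference, [var], half_window=3,
                                    background=uniform_bg, mode="exact")
        (res,) = results
        assert 0.0 <= res.p_ref <= 1.0
        assert 0.0 <= res.p_rank <= 1.0
        assert res.mc_se is None

    def test_round_trip_against_manifest(self, default_scenario):
        # the generator's true_delta_score is reproduced exactly by scoring
        from regsnap.genotypes_ld import read_variant_sites
        from regsnap.synthetic_data import default_generating_pwm
        from regsnap.pipeline_cli import _read_fasta

        manifest, paths = default_scenario
        reference = _read_fasta(paths["reference"])
        variants = {v.id: v for v in read_variant_sites(paths["variants"])}
        pwm = default_generating_pwm()
        for vid, true_delta, _ in manifest.causal_variants:
            (res,) = score_variant(pwm, reference, variants[vid])
            assert res.delta_score == pytest.approx(true_delta, abs=1e-9)
            assert res.direction == "loss"


class TestCalibration:
    def test_affinity_pvalues_superuniform(self, rng, uniform_bg):
        # exact null p-values of random draws never exceed their nominal level
        pwm = random_pwm(rng, 2)
        cache = NullCache(0)
        draws = uniform_bg.sample(rng, 2000, 5)
        lo = log_odds(pwm, uniform_bg)
        scores = best_scores_batch(draws, lo, 2)
        pvals = np.array([
            affinity_pvalue(s, pwm, uniform_bg, 5, 2, "exact", cache=cache)[0]
            for s in scores])
        for alpha in (0.01, 0.05, 0.2, 0.5):
            frac = float((pvals <= alpha).mean())
            se = np.sqrt(alpha * (1 - alpha) / pvals.size)
            assert frac <= alpha + 3 * se
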