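import filecmp
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from regsnap.eqtl_integration import integrate
from regsnap.genotypes_ld import GenotypePanel, compute_r2
from regsnap.motif_core import BackgroundModel, best_match_score, log_odds
from regsnap.synthetic_data import (
    HaplotypeBlock,
    SimulationManifest,
    default_generating_pwm,
    plant_disrupting_variants,
    sample_motif_instance,
    simulate_annotations,
    simulate_chipseq_peaks,
    simulate_eqtl_tables,
    simulate_haplotype_panel,
    simulate_reference,
    simulate_scenario,
)


class TestSimulateReference:
    def test_seed_determinism(self):
        a, _ = simulate_reference(10_000, 0.5, seed=7)
        b, _ = simulate_reference(10_000, 0.5, seed=7)
        assert a == b

    def test_gc_within_binomial_bound(self):
        seq, bg = simulate_reference(100_000, 0.6, seed=1)
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        bound = 3 * np.sqrt(0.6 * 0.4 / 100_000)
        assert abs(gc - 0.6) <= bound
        assert abs(bg.base_freqs[1] + bg.base_freqs[2] - 0.6) <= bound + 1e-4

    def test_degenerate_gc(self):
        with pytest.raises(ValueError):
            simulate_reference(10_000, 0.0, seed=1)

    def test_short_length(self):
        with pytest.raises(ValueError):
            simulate_reference(100, 0.5, seed=1)


class TestHaplotypePanel:
    def panel(self, variants, matrix):
        return GenotypePanel(variants, matrix, True,
                             [f"S{i}" for i in range(matrix.shape[0] // 2)])

    def test_single_founder_perfect_ld(self):
        variants, matrix, _ = simulate_haplotype_panel(
            200, [HaplotypeBlock(4, founder_haps=1)], seed=2)
        panel = self.panel(variants, matrix)
        ids = [v.id for v in variants]
        for other in ids[1:]:
            assert compute_r2(panel, ids[0], other) == pytest.approx(1.0)

    def test_target_r2_half(self):
        variants, matrix, proxies = simulate_haplotype_panel(
            2000, [HaplotypeBlock(2, target_r2_profile=[0.5])], seed=3)
        panel = self.panel(variants, matrix)
        r2 = compute_r2(panel, variants[0].id, variants[1].id)
        assert 0.45 <= r2 <= 0.55
        assert proxies == [("idx0", "blk0_snp1", 0.5)]

    def test_tuple_blocks_accepted(self):
        variants, matrix, _ = simulate_haplotype_panel(
            100, [(3, 4, None)], seed=1)
        assert len(variants) == 3

    def test_biallelic_codes_only(self):
        _, matrix, _ = simulate_haplotype_panel(
            100, [HaplotypeBlock(5, founder_haps=4)], seed=9)
        assert set(np.unique(matrix)) <= {0, 1}

    def test_small_panel_rejected(self):
        with pytest.raises(ValueError):
            simulate_haplotype_panel(10, [HaplotypeBlock(2)], seed=0)

    def test_block_needs_two_snps(self):
        with pytest.raises(ValueError):
            HaplotypeBlock(1)

    def test_bad_target_r2(self):
        with pytest.raises(ValueError):
            HaplotypeBlock(2, target_r2_profile=[1.5])


class TestChipseqPeaks:
    @pytest.fixture
    def reference(self):
        seq, _ = simulate_reference(50_000, 0.45, seed=5)
        return seq

    def test_plant_frac_zero(self, reference):
        _, peaks, sites = simulate_chipseq_peaks(
            reference, default_generating_pwm(), 50, 0.0, seed=1)
        assert sites == []
        assert len(peaks) == 50

    def test_plant_count_exact(self, reference):
        _, _, sites = simulate_chipseq_peaks(
            reference, default_generating_pwm(), 100, 0.8, seed=1)
        assert len(sites) == 80

    def test_heights_positive(self, reference):
        _, peaks, _ = simulate_chipseq_peaks(
            reference, default_generating_pwm(), 100, 0.5, seed=2)
        assert all(p.height > 0 for p in peaks)

    def test_pwm_wider_than_peak(self, reference):
        with pytest.raises(ValueError):
            simulate_chipseq_peaks(reference, default_generating_pwm(),
                                   10, 0.5, seed=1, peak_width=10)

    def test_planted_peaks_score_higher(self, reference):
        # rescoring with the generating PWM separates planted from unplanted
        pwm = default_generating_pwm()
        bg = BackgroundModel.uniform()
        new_ref, peaks, sites = simulate_chipseq_peaks(
            reference, pwm, 60, 0.5, seed=3)
        planted_names = {s[0] for s in sites}
        def best(peak):
            mid = peak.center
            window = new_ref[mid - 20:mid + 21]
            s, _, _ = best_match_score(pwm, window, 20, window[20], bg)
            return s
        planted = [best(p) for p in peaks if p.name in planted_names]
        unplanted = [best(p) for p in peaks if p.name not in planted_names]
        assert np.mean(planted) > np.mean(unplanted)

    def test_planted_heights_enriched_at_top(self, reference):
        _, peaks, sites = simulate_chipseq_peaks(
            reference, default_generating_pwm(), 100, 0.5, seed=4)
        planted_names = {s[0] for s in sites}
        top = sorted(peaks, key=lambda p: -p.height)[:20]
        frac = sum(p.name in planted_names for p in top) / 20
        assert frac > 0.5


class TestPlantDisruptingVariants:
    @pytest.fixture
    def planted(self):
        seq, _ = simulate_reference(40_000, 0.45, seed=6)
        pwm = default_generating_pwm()
        new_ref, peaks, sites = simulate_chipseq_peaks(seq, pwm, 60, 0.8,
                                                       seed=6)
        return new_ref, pwm, peaks, sites

    def test_causal_deltas_nonzero(self, planted):
        ref, pwm, peaks, sites = planted
        variants, truth = plant_disrupting_variants(pwm, ref, peaks, sites,
                                                    10, 0, seed=1)
        assert len(truth) == 10
        assert all(abs(d) > 0 for d in truth.values())

    def test_insufficient_sites(self, planted):
        ref, pwm, peaks, sites = planted
        with pytest.raises(ValueError):
            plant_disrupting_variants(pwm, ref, peaks, sites,
                                      len(sites) + 1, 0, seed=1)

    def test_null_variants_far_from_sites(self, planted):
        ref, pwm, peaks, sites = planted
        variants, _ = plant_disrupting_variants(pwm, ref, peaks, sites,
                                                0, 50, seed=2)
        site_spans = []
        peak_by = {p.name: p for p in peaks}
        for name, offset, _ in sites:
            start = peak_by[name].start + offset
            site_spans.append((start, start + len(pwm)))
        for v in variants:
            assert all(v.pos0 < s - 100 or v.pos0 >= e + 100
                       for s, e in site_spans)

    def test_ref_allele_matches_reference(self, planted):
        ref, pwm, peaks, sites = planted
        variants, _ = plant_disrupting_variants(pwm, ref, peaks, sites,
                                                5, 5, seed=3)
        for v in variants:
            assert ref[v.pos0].upper() == v.ref
            assert v.ref != v.alt

    def test_zero_variants_rejected(self, planted):
        ref, pwm, peaks, sites = planted
        with pytest.raises(ValueError):
            plant_disrupting_variants(pwm, ref, peaks, sites, 0, 0, seed=1)


class TestEqtlTables:
    def test_requires_two_datasets(self):
        with pytest.raises(ValueError):
            simulate_eqtl_tables(["v1", "v2"], 1, 1, seed=0)

    def test_n_true_exceeds_variants(self):
        with pytest.raises(ValueError):
            simulate_eqtl_tables(["v1"], 2, 5, seed=0)

    def test_planted_recovered_by_integration(self):
        ids = [f"v{i}" for i in range(60)]
        tables, effects = simulate_eqtl_tables(ids, 3, 5, seed=4)
        frame = pd.concat([pd.DataFrame(rows) for rows in tables.values()],
                          ignore_index=True)
        summaries = integrate(ids, frame, q_max=0.001)
        replicated = {s.variant_id for s in summaries if s.replicated}
        assert replicated >= set(ids[:5])

    def test_null_only_rarely_significant(self):
        sig = 0
        for seed in range(10):
            ids = [f"v{i}" for i in range(80)]
            tables, _ = simulate_eqtl_tables(ids, 2, 0, seed=seed)
            frame = pd.concat([pd.DataFrame(r) for r in tables.values()],
                              ignore_index=True)
            summaries = integrate(ids, frame, q_max=0.001)
            sig += sum(s.n_significant_datasets > 0 for s in summaries)
        assert sig <= 2

    def test_unknown_true_id(self):
        with pytest.raises(ValueError):
            simulate_eqtl_tables(["v1", "v2"], 2, 1, seed=0,
                                 true_ids=["nope"])


class TestAnnotations:
    def test_flip_zero_perfect_causal(self):
        ids = [f"v{i}" for i in range(20)]
        rows, truth = simulate_annotations(ids, ids[:10], flip_prob=0.0,
                                           seed=1)
        for row in rows[:10]:
            assert row["regulomedb_category"].startswith("1")
            assert all(row[f] for f in ("promoter_mark", "enhancer_mark",
                                        "dnase_protein", "motif_change"))

    def test_flip_mean_score(self):
        ids = [f"c{i}" for i in range(100)]
        rows, _ = simulate_annotations(ids, ids, flip_prob=0.1, seed=2)
        scores = [sum(bool(r[f]) for f in ("promoter_mark", "enhancer_mark",
                                           "dnase_protein", "motif_change"))
                  for r in rows]
        se = np.sqrt(4 * 0.9 * 0.1 / 100)
        assert abs(np.mean(scores) - 3.6) <= 3 * se

    def test_no_causal_no_category1(self):
        ids = [f"v{i}" for i in range(30)]
        rows, _ = simulate_annotations(ids, [], seed=3)
        assert not any(r["regulomedb_category"].startswith("1") for r in rows)

    def test_unknown_causal_id(self):
        with pytest.raises(ValueError):
            simulate_annotations(["v1"], ["ghost"], seed=0)

    def test_flip_prob_range(self):
        with pytest.raises(ValueError):
            simulate_annotations(["v1"], [], flip_prob=0.5, seed=0)


class TestScenario:
    def test_byte_identical_reruns(self, tmp_path):
        m1, p1 = simulate_scenario(tmp_path / "a", seed=42, n_peaks=30,
                                   n_null=20)
        m2, p2 = simulate_scenario(tmp_path / "b", seed=42, n_peaks=30,
                                   n_null=20)
        for key in p1:
            assert (tmp_path / "a" / p1[key].name).read_bytes() == \
                   (tmp_path / "b" / p2[key].name).read_bytes(), key

    def test_manifest_roundtrip(self, tmp_path):
        manifest, paths = simulate_scenario(tmp_path / "s", seed=3,
                                            n_peaks=30, n_null=20)
        back = SimulationManifest.from_json(paths["manifest"])
        assert back.causal_variants == manifest.causal_variants
        assert back.planted_proxies == manifest.planted_proxies

    def test_all_ids_exist_in_files(self, default_scenario):
        manifest, paths = default_scenario
        from regsnap.genotypes_ld import read_variant_sites
        vcf_ids = {v.id for v in read_variant_sites(paths["variants"])}
        for vid, _, _ in manifest.causal_variants:
            assert vid in vcf_ids
        annot = pd.read_csv(paths["annotations"], sep="\t")
        assert set(annot["variant"]) == vcf_ids
        peaks_named = {line.split("\t")[3]
                       for line in Path(paths["peaks"]).read_text().splitlines()}
        for peak_id, _, _ in manifest.planted_motif_sites:
            assert peak_id in peaks_named

    def test_instance_sampling_follows_pwm(self, rng):
        pwm = default_generating_pwm()
        inst = sample_motif_instance(pwm, rng)
        assert len(inst) == len(pwm)
        assert set(inst) <= set("ACGT")
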