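"""Generator contracts: determinism, parsability, zero cases, recovery."""

import math

import pytest
from Bio import SeqIO
from cyvcf2 import VCF

from genovuln.homology import classify_duplication, compute_pd
from genovuln.pipeline import analyze_specimen_bundle
from genovuln.simulate import (
    SimulationConfig,
    generate_specimen,
    generate_transcriptome,
    generate_variants,
    generate_scores,
    write_specimen,
)
from genovuln.transcripts import STOP_CODONS, gene_id_of


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"duplicated_fraction": 1.2},
            {"het_snv_rate": -0.1},
            {"mean_cds_len_bp": 100},
            {"mean_cds_len_bp": 901},
            {"n_genes": 0},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            SimulationConfig(**kw)


class TestDeterminism:
    def test_same_seed_byte_identical_files(self, tmp_path):
        cfg = SimulationConfig(n_genes=30, het_snv_rate=0.002, seed=7)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        p1 = write_specimen(generate_specimen(cfg, "syn", "s1"), d1)
        p2 = write_specimen(generate_specimen(cfg, "syn", "s1"), d2)
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

    def test_different_seeds_differ(self):
        a = generate_specimen(SimulationConfig(n_genes=30, seed=1), "syn", "s1")
        b = generate_specimen(SimulationConfig(n_genes=30, seed=2), "syn", "s1")
        assert [t.seq for t in a.transcripts] != [t.seq for t in b.transcripts]


class TestGenerateTranscriptome:
    def test_zero_duplicated_fraction(self):
        _, truth = generate_transcriptome(
            SimulationConfig(n_genes=10, duplicated_fraction=0.0, seed=3)
        )
        assert truth.true_pd == 0.0
        assert truth.n_families_multi == 0

    def test_saturated_duplication_every_gene_has_homolog(self):
        _, truth = generate_transcriptome(
            SimulationConfig(n_genes=10, duplicated_fraction=1.0, seed=3)
        )
        families = {}
        for g in truth.genes.values():
            families.setdefault(g.family, []).append(g.gene_id)
        assert all(len(members) >= 2 for members in families.values())
        assert truth.true_pd == 1.0

    def test_cds_structure(self):
        _, truth = generate_transcriptome(SimulationConfig(n_genes=15, seed=9))
        for g in truth.genes.values():
            assert g.cds.startswith("ATG")
            assert g.cds[-3:] in STOP_CODONS
            internal = [g.cds[i : i + 3] for i in range(0, len(g.cds) - 3, 3)]
            assert not any(c in STOP_CODONS for c in internal)

    def test_fasta_parses_with_strict_parser(self, small_bundle_paths, small_bundle):
        records = list(SeqIO.parse(str(small_bundle_paths["fasta"]), "fasta"))
        assert len(records) == len(small_bundle.transcripts)
        assert all(gene_id_of(r.id) in small_bundle.truth.genes for r in records)


class TestGenerateVariants:
    def test_zero_rate_header_only_vcf(self, tmp_path):
        cfg = SimulationConfig(n_genes=10, het_snv_rate=0.0, seed=4)
        bundle = generate_specimen(cfg, "syn", "s1")
        paths = write_specimen(bundle, tmp_path)
        assert bundle.variants == []
        assert list(VCF(str(paths["vcf"]))) == []

    def test_vcf_parses_and_matches_ledger(self, small_bundle_paths, small_bundle):
        records = list(VCF(str(small_bundle_paths["vcf"])))
        assert len(records) == len(small_bundle.variants)
        for rec, v in zip(records, small_bundle.variants):
            assert (rec.CHROM, rec.POS, rec.REF, rec.ALT[0]) == (
                v.transcript_id, v.pos, v.ref, v.alt,
            )
            assert rec.INFO.get("MQ") == pytest.approx(v.mq, abs=0.05)

    def test_pure_missense_composition(self, tmp_path):
        cfg = SimulationConfig(
            n_genes=40, het_snv_rate=0.003,
            nonsyn_target_fraction=1.0, nonsense_given_nonsyn=0.0,
            low_mq_fraction=0.0, seed=6,
        )
        bundle = generate_specimen(cfg, "syn", "s1")
        paths = write_specimen(bundle, tmp_path)
        result = analyze_specimen_bundle(bundle, paths["vcf"])
        assert result.indices["nonsyn_fraction"] == pytest.approx(1.0)
        assert result.indices["nonsense_fraction"] == pytest.approx(0.0)
        per = result.per_transcript
        assert per["n_syn"].sum() == 0

    def test_syn_rate_recovery_on_a_megabase(self):
        """Spec-scale recovery: ~1 Mb of CDS at rate 0.002 recovers syn/kb."""
        cfg = SimulationConfig(
            n_genes=1100, het_snv_rate=0.002, seed=7, low_mq_fraction=0.0
        )
        _, truth = generate_transcriptome(cfg)
        variants = generate_variants(truth, cfg)
        total_cds = sum(g.cds_len for g in truth.genes.values())
        assert total_cds > 0.9e6
        n_syn = sum(1 for v in variants if v.effect == "synonymous")
        rate_syn_true = cfg.het_snv_rate * (1 - cfg.nonsyn_target_fraction)
        expected = rate_syn_true * total_cds
        se = math.sqrt(expected)
        assert abs(n_syn - expected) <= 3 * se


class TestGenerateScores:
    def test_zero_deleterious_fraction(self, tmp_path):
        cfg = SimulationConfig(
            n_genes=40, het_snv_rate=0.003, deleterious_fraction_provean=0.0, seed=8
        )
        bundle = generate_specimen(cfg, "syn", "s1")
        paths = write_specimen(bundle, tmp_path)
        result = analyze_specimen_bundle(bundle, paths["vcf"])
        assert result.indices["provean_fraction"] == 0.0

    def test_all_sift_missing_flagged_no_data(self, tmp_path):
        cfg = SimulationConfig(
            n_genes=30, het_snv_rate=0.003, sift_missing_rate=1.0, seed=9
        )
        bundle = generate_specimen(cfg, "syn", "s1")
        paths = write_specimen(bundle, tmp_path)
        result = analyze_specimen_bundle(bundle, paths["vcf"])
        assert math.isnan(result.indices["sift_fraction"])

    def test_deleterious_fraction_recovery(self):
        cfg = SimulationConfig(
            n_genes=400, het_snv_rate=0.003,
            deleterious_fraction_provean=0.4, sift_missing_rate=0.0, seed=3,
        )
        _, truth = generate_transcriptome(cfg)
        variants = generate_variants(truth, cfg)
        scores = generate_scores(variants, cfg)
        assert len(scores) >= 500
        frac = sum(s.provean_deleterious for s in scores) / len(scores)
        se = math.sqrt(0.4 * 0.6 / len(scores))
        assert abs(frac - 0.4) <= 3 * se
        # drawn scores respect the thresholds exactly
        for s in scores:
            assert s.provean_deleterious == (s.score.provean_score <= -2.5)
            if s.score.sift_score is not None:
                assert s.sift_deleterious == (s.score.sift_score < 0.05)


class TestPDRecovery:
    def test_pd_recovered_within_binomial_error(self, tmp_path):
        cfg = SimulationConfig(n_genes=200, duplicated_fraction=0.7, seed=1)
        bundle = generate_specimen(cfg, "syn", "s1")
        labels = classify_duplication(
            bundle.self_hits, bundle.plant_hits, set(bundle.truth.genes)
        )
        pd_est = compute_pd(labels)
        assert pd_est == pytest.approx(bundle.truth.true_pd)
        se = math.sqrt(0.7 * 0.3 / 200)
        assert abs(pd_est - 0.7) <= 3 * se
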