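"""Reciprocal-best ortholog pairing and species-specific substitution calling."""

import pytest

from genovuln.deleterious import EffectScore
from genovuln.homology import HomologyHit, NoDataError
from genovuln.orthologs import (
    IntegratedReference,
    OrthologPair,
    build_integrated_reference,
    deleterious_substitution_fraction,
    find_substitutions,
    pair_orthologs,
)
from genovuln.simulate import (
    SimulationConfig,
    generate_pair_homology,
    generate_species_pair,
    write_vcf,
)
from genovuln.transcripts import CodingRegion, Transcript, translate


def xhit(q, s, ident, evalue=1e-50, length=200):
    return HomologyHit(
        query_id=q, subject_id=s, percent_identity=ident,
        alignment_length=length, evalue=evalue, query_length=length,
    )


def ref_for(cds, gene="A_c0_g0", tid=None, mask=()):
    tid = tid or f"{gene}_i1"
    region = CodingRegion(tid, "+", 0, len(cds), cds, translate(cds))
    return IntegratedReference(
        species=gene[0], regions={gene: region}, het_mask=set(mask)
    )


@pytest.fixture(scope="module")
def synthetic_pair(tmp_path_factory):
    cfg = SimulationConfig(
        n_genes=120, het_snv_rate=0.001, interspecies_divergence=0.02, seed=11
    )
    pair = generate_species_pair(cfg, "spa", "spb")
    d = tmp_path_factory.mktemp("pairvcf")
    write_vcf(pair.het_a, pair.transcripts_a, d / "a.vcf", "pooledA")
    write_vcf(pair.het_b, pair.transcripts_b, d / "b.vcf", "pooledB")
    ref_a = build_integrated_reference(pair.transcripts_a, d / "a.vcf", "spa")
    ref_b = build_integrated_reference(pair.transcripts_b, d / "b.vcf", "spb")
    return pair, ref_a, ref_b


class TestPairOrthologs:
    def test_identity_exactly_80_excluded(self):
        pairs = pair_orthologs([xhit("A", "B", 80.0)], [xhit("B", "A", 80.0)])
        assert pairs == []

    def test_mutual_best_at_95_paired(self):
        pairs = pair_orthologs([xhit("A", "B", 95.0)], [xhit("B", "A", 95.0)])
        assert [(p.gene_a, p.gene_b) for p in pairs] == [("A", "B")]

    def test_non_reciprocal_best_not_paired(self):
        # A's best is B, but B's best is C
        pairs = pair_orthologs(
            [xhit("A", "B", 95.0)],
            [xhit("B", "A", 95.0, evalue=1e-10), xhit("B", "C", 99.0, evalue=1e-60)],
        )
        assert pairs == []

    def test_divergence_sweep_matches_ledger(self):
        """Above the identity cliff pairs form; below it they are excluded."""
        cfg = SimulationConfig(n_genes=30, seed=5)
        for divergence, expect_all in ((0.01, True), (0.15, False)):
            pair = generate_species_pair(cfg, "qa", "qb", divergence=divergence)
            hits_ab, hits_ba = generate_pair_homology(pair)
            pairs = pair_orthologs(hits_ab, hits_ba)
            paired = {p.gene_a for p in pairs}
            for gene, ident in pair.protein_identity.items():
                assert (gene in paired) == (round(ident, 2) > 80.0), (gene, ident)
            if expect_all:
                assert len(pairs) == 30


class TestFindSubstitutions:
    def test_identical_cds_yields_nothing(self):
        cds = "ATG" + "GCT" * 60 + "TAA"
        ra = ref_for(cds, "A_c0_g0")
        rb = ref_for(cds, "B_c0_g0")
        pair = OrthologPair("A_c0_g0", "B_c0_g0", 100.0)
        assert find_substitutions(pair, ra, rb) == []

    def test_single_third_position_synonymous_difference(self):
        cds_a = "ATG" + "GCT" * 60 + "TAA"
        cds_b = "ATG" + "GCC" + "GCT" * 59 + "TAA"  # codon 1: GCT -> GCC (Ala)
        ra = ref_for(cds_a, "A_c0_g0")
        rb = ref_for(cds_b, "B_c0_g0")
        sites = find_substitutions(OrthologPair("A_c0_g0", "B_c0_g0", 99.0), ra, rb)
        assert len(sites) == 1
        assert sites[0].effect == "synonymous"
        assert sites[0].codon_index_a == 1

    def test_het_masked_codon_not_reported(self):
        cds_a = "ATG" + "GCT" * 60 + "TAA"
        cds_b = "ATG" + "CCT" + "GCT" * 59 + "TAA"  # nonsyn difference in codon 1
        ra = ref_for(cds_a, "A_c0_g0", mask={("A_c0_g0_i1", 4)})
        rb = ref_for(cds_b, "B_c0_g0")
        sites = find_substitutions(OrthologPair("A_c0_g0", "B_c0_g0", 99.0), ra, rb)
        assert sites == []

    def test_direction_symmetry(self, synthetic_pair):
        pair, ref_a, ref_b = synthetic_pair
        hits_ab, hits_ba = generate_pair_homology(pair)
        pairs = pair_orthologs(hits_ab, hits_ba)
        p = pairs[0]
        fwd = find_substitutions(p, ref_a, ref_b)
        rev = find_substitutions(
            OrthologPair(p.gene_b, p.gene_a, p.percent_identity), ref_b, ref_a
        )
        assert {(s.codon_index_a, s.codon_a, s.codon_b) for s in fwd} == {
            (s.codon_index_b, s.codon_b, s.codon_a) for s in rev
        }

    def test_ledger_recall_precision_and_mask_exclusion(self, synthetic_pair):
        pair, ref_a, ref_b = synthetic_pair
        hits_ab, hits_ba = generate_pair_homology(pair)
        pairs = pair_orthologs(hits_ab, hits_ba)
        found = set()
        for p in pairs:
            for s in find_substitutions(p, ref_a, ref_b):
                found.add((s.gene_a, s.codon_index_a))
        unmasked = {
            (s.gene_id_a, s.codon_index)
            for s in pair.substitutions
            if not s.masked
        }
        masked = {
            (s.gene_id_a, s.codon_index) for s in pair.substitutions if s.masked
        }
        assert unmasked, "fixture must plant substitutions"
        assert masked, "fixture must mask some substitutions"
        assert found == unmasked
        assert not (found & masked)


class TestSubstitutionLoad:
    def _one_gene_sites_scores(self, proveans):
        cds_a = "ATG" + "GCT" * 60 + "TAA"
        # three nonsynonymous codon differences at codons 1..3
        alt = ["CCT", "TCT", "ACT"]
        cds_b = "ATG" + "".join(alt) + "GCT" * 57 + "TAA"
        ra = ref_for(cds_a, "A_c0_g0")
        rb = ref_for(cds_b, "B_c0_g0")
        sites = find_substitutions(OrthologPair("A_c0_g0", "B_c0_g0", 97.0), ra, rb)
        scores = [
            EffectScore("A_c0_g0", s.codon_index_a + 1, s.aa_a, s.aa_b, p, None)
            for s, p in zip(sites, proveans)
        ]
        return sites, scores

    def test_literal_negative_score_denominator(self):
        sites, scores = self._one_gene_sites_scores([-3.0, -1.0, 2.0])
        load = deleterious_substitution_fraction(sites, scores, "provean", query="a")
        assert load.mean == pytest.approx(0.5)  # 1 of the 2 negative-score sites

    def test_all_nonsyn_denominator_switch(self):
        sites, scores = self._one_gene_sites_scores([-3.0, -1.0, 2.0])
        load = deleterious_substitution_fraction(
            sites, scores, "provean", query="a", provean_denominator="all_nonsyn"
        )
        assert load.mean == pytest.approx(1 / 3)

    def test_no_nonsyn_is_no_data(self):
        with pytest.raises(NoDataError):
            deleterious_substitution_fraction([], [], "provean")

    def test_recovery_per_direction(self, synthetic_pair):
        pair, ref_a, ref_b = synthetic_pair
        hits = generate_pair_homology(pair)
        pairs = pair_orthologs(*hits)
        sites = [
            s for p in pairs for s in find_substitutions(p, ref_a, ref_b)
        ]
        for query, scores, refq in (
            ("a", pair.scores_a, ref_a),
            ("b", pair.scores_b, ref_b),
        ):
            load = deleterious_substitution_fraction(
                [s for s in sites],
                [st.score for st in scores],
                "sift",
                query=query,
                gene_of_transcript=refq.gene_of_transcript,
            )
            truth = [st.sift_deleterious for st in scores if st.sift_deleterious is not None]
            p_true = sum(truth) / len(truth)
            # per-gene proportions have variance <= p(1-p); bound the SE of
            # their mean by sqrt(p(1-p)/n_genes)
            se = (p_true * (1 - p_true) / len(load.per_gene)) ** 0.5
            assert abs(load.mean - p_true) <= 3 * max(se, 0.02)
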