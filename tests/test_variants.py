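"""MQ filtering, codon-level effect classification, and the SNV indices."""

import itertools

import pytest
from Bio.Seq import reverse_complement

from genovuln.transcripts import CODON_TABLE, CodingRegion, translate
from genovuln.variants import (
    Effect,
    SNV,
    Zygosity,
    annotate_snv,
    filter_snvs,
    specimen_indices,
    summarize_transcript,
)

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def region_for_codon(codon: str, strand: str = "+") -> CodingRegion:
    """A 4-codon CDS with the probed codon second: ATG <codon> GGG TAA."""
    cds = "ATG" + codon + "GGGTAA"
    if strand == "+":
        seq_start = 0
    else:
        seq_start = 0
    return CodingRegion(
        transcript_id="S_c0_g0_i1",
        strand=strand,
        start=seq_start,
        end=seq_start + 12,
        cds=cds,
        protein=translate(cds),
    )


def oracle_effect(codon: str, cp: int, alt: str) -> Effect:
    """Direct codon-table comparison, independent of the annotation machinery."""
    ref_aa = CODON_TABLE[codon]
    alt_aa = CODON_TABLE[codon[:cp] + alt + codon[cp + 1 :]]
    if ref_aa == "*":
        return Effect.UNASSESSABLE
    if alt_aa == "*":
        return Effect.NONSENSE
    return Effect.SYNONYMOUS if ref_aa == alt_aa else Effect.MISSENSE


def all_single_base_changes():
    for codon in map("".join, itertools.product(_BASES, repeat=3)):
        for cp in range(3):
            for alt in _BASES:
                if alt != codon[cp]:
                    yield codon, cp, alt


class TestAnnotateSNV:
    def test_nonsense_example(self):
        region = region_for_codon("TAC")
        snv = SNV("S_c0_g0_i1", pos=6, ref="C", alt="A", zygosity=Zygosity.HET, rms_mq=50)
        assert annotate_snv(snv, region).effect is Effect.NONSENSE

    def test_synonymous_example(self):
        region = region_for_codon("CTG")
        snv = SNV("S_c0_g0_i1", pos=6, ref="G", alt="A", zygosity=Zygosity.HET, rms_mq=50)
        assert annotate_snv(snv, region).effect is Effect.SYNONYMOUS

    def test_noncoding_outside_cds(self):
        region = region_for_codon("CTG")
        snv = SNV("S_c0_g0_i1", pos=13, ref="A", alt="G", zygosity=Zygosity.HET, rms_mq=50)
        assert annotate_snv(snv, region, transcript_len=20).effect is Effect.NONCODING

    def test_position_beyond_transcript_is_error(self):
        region = region_for_codon("CTG")
        snv = SNV("S_c0_g0_i1", pos=21, ref="A", alt="G", zygosity=Zygosity.HET, rms_mq=50)
        with pytest.raises(ValueError):
            annotate_snv(snv, region, transcript_len=20)

    def test_exhaustive_enumeration_oracle(self):
        """All 576 single-base codon changes agree with the codon-table oracle."""
        partition = {e: 0 for e in Effect}
        for codon, cp, alt in all_single_base_changes():
            region = region_for_codon(codon)
            snv = SNV(
                "S_c0_g0_i1", pos=3 + cp + 1, ref=codon[cp], alt=alt,
                zygosity=Zygosity.HET, rms_mq=50,
            )
            got = annotate_snv(snv, region).effect
            assert got is oracle_effect(codon, cp, alt), (codon, cp, alt)
            partition[got] += 1
        assert sum(partition.values()) == 576
        # the genetic code fixes the partition of the 549 sense-codon changes
        assert partition[Effect.UNASSESSABLE] == 27  # 3 stop codons x 9 changes
        assert (
            partition[Effect.SYNONYMOUS]
            + partition[Effect.MISSENSE]
            + partition[Effect.NONSENSE]
            == 549
        )

    def test_strand_symmetry(self):
        """Annotating on the reverse-complemented transcript gives the same effect."""
        for codon, cp, alt in itertools.islice(all_single_base_changes(), 0, 576, 7):
            fwd = region_for_codon(codon)
            # transcript is the reverse complement; CDS string is unchanged
            rev = CodingRegion(
                transcript_id="S_c0_g0_i1", strand="-", start=0, end=12,
                cds=fwd.cds, protein=fwd.protein,
            )
            pos_fwd = 3 + cp + 1
            snv_fwd = SNV(
                "S_c0_g0_i1", pos_fwd, ref=codon[cp], alt=alt,
                zygosity=Zygosity.HET, rms_mq=50,
            )
            snv_rev = SNV(
                "S_c0_g0_i1", pos=12 - pos_fwd + 1,
                ref=_COMP[codon[cp]], alt=_COMP[alt],
                zygosity=Zygosity.HET, rms_mq=50,
            )
            assert annotate_snv(snv_fwd, fwd).effect is annotate_snv(snv_rev, rev).effect


class TestFilterSNVs:
    def _write_vcf(self, tmp_path, rows):
        path = tmp_path / "t.vcf"
        header = (
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS MQ">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            "##contig=<ID=tig1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
        )
        path.write_text(header + "".join(rows))
        return path

    def test_mq_exactly_30_rejected(self, tmp_path):
        path = self._write_vcf(tmp_path, ["tig1\t10\t.\tA\tG\t.\tPASS\tMQ=30\tGT\t0/1\n"])
        snvs, log = filter_snvs(path)
        assert snvs == [] and log.n_low_mq == 1

    def test_mq_31_het_retained(self, tmp_path):
        path = self._write_vcf(tmp_path, ["tig1\t10\t.\tA\tG\t.\tPASS\tMQ=31\tGT\t0/1\n"])
        snvs, _ = filter_snvs(path)
        assert len(snvs) == 1
        assert snvs[0].zygosity is Zygosity.HET

    def test_hom_genotype_recognised(self, tmp_path):
        path = self._write_vcf(tmp_path, ["tig1\t10\t.\tA\tG\t.\tPASS\tMQ=40\tGT\t1/1\n"])
        snvs, _ = filter_snvs(path)
        assert snvs[0].zygosity is Zygosity.HOM

    def test_indel_excluded_and_counted(self, tmp_path):
        path = self._write_vcf(tmp_path, ["tig1\t10\t.\tAT\tA\t.\tPASS\tMQ=40\tGT\t0/1\n"])
        snvs, log = filter_snvs(path)
        assert snvs == [] and log.n_not_snv == 1

    def test_half_call_skipped(self, tmp_path):
        path = self._write_vcf(tmp_path, ["tig1\t10\t.\tA\tG\t.\tPASS\tMQ=40\tGT\t./1\n"])
        snvs, log = filter_snvs(path)
        assert snvs == [] and log.n_missing_genotype == 1

    def test_unknown_transcript_is_hard_error(self, tmp_path):
        path = self._write_vcf(tmp_path, ["tig1\t10\t.\tA\tG\t.\tPASS\tMQ=40\tGT\t0/1\n"])
        with pytest.raises(KeyError, match="tig1"):
            filter_snvs(path, known_transcripts={"other"})


class TestSummaries:
    def _ann(self, region, pos, ref, alt):
        return annotate_snv(
            SNV("S_c0_g0_i1", pos, ref, alt, Zygosity.HET, 50.0), region
        )

    def test_arithmetic_examples(self):
        cds = "ATG" + "GCT" * 498 + "TAA"  # 1500 bp
        region = CodingRegion("S_c0_g0_i1", "+", 0, 1500, cds, translate(cds))
        # three synonymous changes at third positions (GCT -> GCC)
        ann = [self._ann(region, p, "T", "C") for p in (6, 9, 12)]
        s = summarize_transcript(ann, region)
        assert s.n_syn == 3 and s.syn_per_kb == pytest.approx(2.0)

    def test_fraction_example(self):
        cds = "ATG" + "TAC" * 98 + "TAA"
        region = CodingRegion("S_c0_g0_i1", "+", 0, len(cds), cds, translate(cds))
        ann = (
            [self._ann(region, p, "C", "T") for p in (6, 9)]  # TAC->TAT syn
            + [self._ann(region, p, "T", "C") for p in (7, 10)]  # TAC->CAC missense
            + [self._ann(region, 12, "C", "A")]  # TAC->TAA nonsense
        )
        s = summarize_transcript(ann, region)
        assert s.nonsyn_fraction == pytest.approx(0.6)
        assert s.nonsense_fraction == pytest.approx(1 / 3)
        assert s.n_syn + s.n_missense + s.n_nonsense == 5

    def test_specimen_means(self):
        cds = "ATG" + "GCT" * 331 + "TAA"
        region = CodingRegion("S_c0_g0_i1", "+", 0, len(cds), cds, translate(cds))
        s1 = summarize_transcript([self._ann(region, 6, "T", "C")], region)
        # 1 syn on 999 bp -> ~1.001/kb; scale second summary via empty
        s2 = summarize_transcript([], region)
        idx = specimen_indices([s1, s2])
        assert idx.syn_per_kb == pytest.approx((s1.syn_per_kb + 0.0) / 2)
        # fraction mean skips the zero-SNV transcript
        assert idx.nonsyn_fraction == pytest.approx(0.0)

    def test_conservation_on_generated_data(self, small_bundle):
        """Planted effect classes are recovered exactly through annotation."""
        from collections import Counter

        for gene_id, g in small_bundle.truth.genes.items():
            region = g.region()
            planted = [v for v in small_bundle.variants if v.gene_id == gene_id]
            ann = [
                annotate_snv(
                    SNV(v.transcript_id, v.pos, v.ref, v.alt, Zygosity.HET, v.mq),
                    region,
                )
                for v in planted
            ]
            got = Counter(a.effect.value for a in ann)
            want = Counter(v.effect for v in planted)
            assert got == want
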