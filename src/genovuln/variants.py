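"""SNV filtering, codon-level effect annotation, and the SNV-composition indices.

Variants called against the transcript assembly are filtered on RMS mapping
quality (strictly > 30), mapped into the chosen coding region of the longest
isoform, and classified by substituting the alternate allele into the
reference codon: synonymous, missense, or nonsense (premature stop).  Three
per-specimen indices follow: heterozygous synonymous SNVs per kb of coding
sequence, the nonsynonymous fraction of all coding SNVs, and the nonsense
fraction of nonsynonymous SNVs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

import pandas as pd
from cyvcf2 import VCF

from .transcripts import CODON_TABLE, CodingRegion

MQ_THRESHOLD = 30.0

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASES = ("A", "C", "G", "T")


class Effect(str, Enum):
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    NONCODING = "noncoding"
    UNASSESSABLE = "unassessable"


CODING_EFFECTS = (Effect.SYNONYMOUS, Effect.MISSENSE, Effect.NONSENSE)


class Zygosity(str, Enum):
    HET = "het"
    HOM = "hom"


@dataclass(frozen=True)
class SNV:
    transcript_id: str
    pos: int  # 1-based transcript coordinate
    ref: str
    alt: str
    zygosity: Zygosity
    rms_mq: float

    def __post_init__(self) -> None:
        if self.ref == self.alt or self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(
                f"invalid SNV alleles {self.ref}>{self.alt} at {self.transcript_id}:{self.pos}"
            )


@dataclass(frozen=True)
class AnnotatedSNV:
    snv: SNV
    effect: Effect
    cds_offset: int | None = None  # 0-based within the CDS, coding strand
    codon_index: int | None = None
    codon_pos: int | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None

    @property
    def transcript_id(self) -> str:
        return self.snv.transcript_id


@dataclass
class FilterLog:
    """Per-run audit of why VCF records were dropped."""

    n_records: int = 0
    n_retained: int = 0
    n_low_mq: int = 0
    n_not_snv: int = 0
    n_multiallelic: int = 0
    n_missing_genotype: int = 0
    n_unknown_transcript: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def filter_snvs(
    vcf_path: str | Path,
    mq_threshold: float = MQ_THRESHOLD,
    known_transcripts: set[str] | None = None,
) -> tuple[list[SNV], FilterLog]:
    """Read biallelic SNVs passing the RMS-MQ filter from a VCF.

    MQ exactly at the threshold is rejected (the filter is strictly ``>``).
    Indels, multi-allelic records, and records with missing or half-called
    genotypes are skipped and counted in the log.  When ``known_transcripts``
    is given, a record on an unknown transcript is a hard error.
    """
    snvs: list[SNV] = []
    log = FilterLog()
    for rec in VCF(str(vcf_path)):
        log.n_records += 1
        if known_transcripts is not None and rec.CHROM not in known_transcripts:
            raise KeyError(
                f"VCF record on transcript {rec.CHROM!r} absent from the assembly"
            )
        if len(rec.ALT) != 1:
            log.n_multiallelic += 1
            continue
        ref, alt = rec.REF, rec.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
            log.n_not_snv += 1
            continue
        mq = rec.INFO.get("MQ")
        if mq is None or not float(mq) > mq_threshold:
            log.n_low_mq += 1
            continue
        a, b = rec.genotypes[0][0], rec.genotypes[0][1]
        if a < 0 or b < 0:
            log.n_missing_genotype += 1
            continue
        zyg = Zygosity.HET if a != b else Zygosity.HOM
        snvs.append(
            SNV(
                transcript_id=rec.CHROM,
                pos=rec.POS,
                ref=ref,
                alt=alt,
                zygosity=zyg,
                rms_mq=float(mq),
            )
        )
        log.n_retained += 1
    return snvs, log


def annotate_snv(s: SNV, c: CodingRegion, transcript_len: int | None = None) -> AnnotatedSNV:
    """Classify one SNV against a coding region (strand-aware).

    The alternate allele is substituted into the reference codon at the
    SNV's codon position; effects compare the two translations.  Positions
    outside the CDS are noncoding; codons containing N, a reference-allele
    mismatch, or a reference stop codon (contig-edge stop) are unassessable.
    """
    if transcript_len is not None and s.pos > transcript_len:
        raise ValueError(
            f"SNV position {s.pos} beyond transcript {s.transcript_id!r} "
            f"length {transcript_len}"
        )
    if s.transcript_id != c.transcript_id:
        raise ValueError(f"SNV on {s.transcript_id!r} annotated against {c.transcript_id!r}")
    pos0 = s.pos - 1
    if not c.start <= pos0 < c.end:
        return AnnotatedSNV(snv=s, effect=Effect.NONCODING)

    if c.strand == "+":
        cds_offset = pos0 - c.start
        ref_cs, alt_cs = s.ref, s.alt
    else:
        cds_offset = (c.end - 1) - pos0
        ref_cs, alt_cs = _COMPLEMENT[s.ref], _COMPLEMENT[s.alt]

    codon_index, codon_pos = divmod(cds_offset, 3)
    ref_codon = c.codon(codon_index)
    if ref_codon[codon_pos] != ref_cs:
        return AnnotatedSNV(snv=s, effect=Effect.UNASSESSABLE)
    alt_codon = ref_codon[:codon_pos] + alt_cs + ref_codon[codon_pos + 1 :]
    ref_aa = CODON_TABLE.get(ref_codon, "X")
    alt_aa = CODON_TABLE.get(alt_codon, "X")

    if ref_aa == "X" or alt_aa == "X" or ref_aa == "*":
        effect = Effect.UNASSESSABLE
    elif alt_aa == "*":
        effect = Effect.NONSENSE
    elif ref_aa == alt_aa:
        effect = Effect.SYNONYMOUS
    else:
        effect = Effect.MISSENSE
    return AnnotatedSNV(
        snv=s,
        effect=effect,
        cds_offset=cds_offset,
        codon_index=codon_index,
        codon_pos=codon_pos,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
    )


@dataclass(frozen=True)
class TranscriptSNVSummary:
    transcript_id: str
    cds_len_bp: int
    n_syn: int
    n_missense: int
    n_nonsense: int

    @property
    def n_nonsyn(self) -> int:
        return self.n_missense + self.n_nonsense

    @property
    def n_coding(self) -> int:
        return self.n_syn + self.n_nonsyn

    @property
    def syn_per_kb(self) -> float:
        return 1000.0 * self.n_syn / self.cds_len_bp

    @property
    def nonsyn_fraction(self) -> float:
        return self.n_nonsyn / self.n_coding if self.n_coding else math.nan

    @property
    def nonsense_fraction(self) -> float:
        return self.n_nonsense / self.n_nonsyn if self.n_nonsyn else math.nan


def summarize_transcript(
    annotated: Iterable[AnnotatedSNV], c: CodingRegion
) -> TranscriptSNVSummary:
    """Count heterozygous coding SNVs by effect class on one coding region."""
    counts = {Effect.SYNONYMOUS: 0, Effect.MISSENSE: 0, Effect.NONSENSE: 0}
    for a in annotated:
        if a.snv.zygosity is not Zygosity.HET:
            continue
        if a.effect in counts:
            counts[a.effect] += 1
    return TranscriptSNVSummary(
        transcript_id=c.transcript_id,
        cds_len_bp=c.cds_len,
        n_syn=counts[Effect.SYNONYMOUS],
        n_missense=counts[Effect.MISSENSE],
        n_nonsense=counts[Effect.NONSENSE],
    )


@dataclass(frozen=True)
class SpecimenSNVIndices:
    syn_per_kb: float
    nonsyn_fraction: float
    nonsense_fraction: float
    n_transcripts: int
    n_with_snvs: int


def specimen_indices(summaries: Iterable[TranscriptSNVSummary]) -> SpecimenSNVIndices:
    """Unweighted per-transcript means of the three SNV-composition indices.

    syn/kb averages over every transcript in the retained universe (zero-SNV
    transcripts included); the two fractions average only over transcripts
    where they are defined (>=1 coding het SNV, resp. >=1 nonsynonymous SNV).
    """
    summaries = list(summaries)
    if not summaries:
        return SpecimenSNVIndices(math.nan, math.nan, math.nan, 0, 0)
    syn_rates = [s.syn_per_kb for s in summaries]
    nonsyn = [s.nonsyn_fraction for s in summaries if s.n_coding > 0]
    nonsense = [s.nonsense_fraction for s in summaries if s.n_nonsyn > 0]
    return SpecimenSNVIndices(
        syn_per_kb=sum(syn_rates) / len(syn_rates),
        nonsyn_fraction=sum(nonsyn) / len(nonsyn) if nonsyn else math.nan,
        nonsense_fraction=sum(nonsense) / len(nonsense) if nonsense else math.nan,
        n_transcripts=len(summaries),
        n_with_snvs=len(nonsyn),
    )


def summaries_to_frame(summaries: Iterable[TranscriptSNVSummary]) -> pd.DataFrame:
    rows = [
        {
            "transcript_id": s.transcript_id,
            "cds_len_bp": s.cds_len_bp,
            "n_syn": s.n_syn,
            "n_missense": s.n_missense,
            "n_nonsense": s.n_nonsense,
            "syn_per_kb": s.syn_per_kb,
            "nonsyn_fraction": s.nonsyn_fraction,
            "nonsense_fraction": s.nonsense_fraction,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows)
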