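"""Interspecies substitution analysis between an endangered/non-endangered pair.

Each species contributes an integrated reference: one longest-CDS transcript
per gene plus a per-position heterozygosity mask from its pooled variant
calls.  Orthologs are reciprocal best protein hits at > 80% identity.  A
protein-guided global alignment (affine gaps, BLOSUM62) back-projected to
codons yields the codon columns where the two coding sequences differ; a
column under either species' heterozygosity mask is excluded — only
species-specific homozygous differences count as substitutions.  Deleterious
proportions are computed per gene with each species used as the query, from
that direction's PROVEAN/SIFT score table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import Align
from Bio.Align import substitution_matrices

from .deleterious import (
    PROVEAN_THRESHOLD,
    SIFT_THRESHOLD,
    EffectScore,
    classify_provean,
    classify_sift,
)
from .homology import HomologyHit, NoDataError
from .transcripts import (
    CODON_TABLE,
    CodingRegion,
    Transcript,
    find_coding_regions,
    select_longest_isoform,
)
from .variants import filter_snvs, Zygosity

IDENTITY_MIN_PCT = 80.0
GAP_GUARD_CODONS = 2


@dataclass
class IntegratedReference:
    """Per-species longest-CDS gene set with a pooled heterozygosity mask."""

    species: str
    regions: dict[str, CodingRegion]  # gene_id -> coding region
    het_mask: set[tuple[str, int]]  # (transcript_id, 1-based position)
    gene_of_transcript: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.gene_of_transcript:
            self.gene_of_transcript = {
                r.transcript_id: g for g, r in self.regions.items()
            }


def build_integrated_reference(
    transcripts: list[Transcript],
    vcf_path: str | Path | None,
    species: str,
) -> IntegratedReference:
    """Longest isoform per gene, ORF-called, plus the het mask from the pooled VCF.

    The mask takes every heterozygous-genotype record regardless of mapping
    quality: for substitution calling, any read-backed evidence of within-
    species polymorphism disqualifies the site.
    """
    longest = select_longest_isoform(transcripts)
    regions = find_coding_regions(longest)
    mask: set[tuple[str, int]] = set()
    if vcf_path is not None:
        ids = {t.id for t in transcripts}
        snvs, _ = filter_snvs(vcf_path, mq_threshold=-1.0, known_transcripts=ids)
        mask = {
            (s.transcript_id, s.pos) for s in snvs if s.zygosity is Zygosity.HET
        }
    return IntegratedReference(species=species, regions=regions, het_mask=mask)


@dataclass(frozen=True)
class OrthologPair:
    gene_a: str
    gene_b: str
    percent_identity: float


def _best_hit(hits: Iterable[HomologyHit], identity_min: float) -> dict[str, HomologyHit]:
    """Best qualifying hit per query: lowest E-value, then identity x length."""
    best: dict[str, HomologyHit] = {}
    for h in hits:
        if not h.percent_identity > identity_min:
            continue
        cur = best.get(h.query_id)
        if cur is None:
            best[h.query_id] = h
            continue
        key = (h.evalue, -h.percent_identity * h.alignment_length, h.subject_id)
        cur_key = (cur.evalue, -cur.percent_identity * cur.alignment_length, cur.subject_id)
        if key < cur_key:
            best[h.query_id] = h
    return best


def pair_orthologs(
    hits_ab: Iterable[HomologyHit],
    hits_ba: Iterable[HomologyHit],
    identity_min: float = IDENTITY_MIN_PCT,
) -> list[OrthologPair]:
    """Reciprocal best hits, identity strictly > the threshold in both directions."""
    best_ab = _best_hit(hits_ab, identity_min)
    best_ba = _best_hit(hits_ba, identity_min)
    pairs = []
    for a, hit in sorted(best_ab.items()):
        back = best_ba.get(hit.subject_id)
        if back is not None and back.subject_id == a:
            pairs.append(
                OrthologPair(
                    gene_a=a,
                    gene_b=hit.subject_id,
                    percent_identity=min(hit.percent_identity, back.percent_identity),
                )
            )
    return pairs


@dataclass(frozen=True)
class SubstitutionSite:
    gene_a: str
    gene_b: str
    codon_index_a: int
    codon_index_b: int
    codon_a: str
    codon_b: str
    effect: str  # synonymous | nonsynonymous

    @property
    def aa_a(self) -> str:
        return CODON_TABLE.get(self.codon_a, "X")

    @property
    def aa_b(self) -> str:
        return CODON_TABLE.get(self.codon_b, "X")


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def codon_transcript_positions(region: CodingRegion, codon_index: int) -> list[int]:
    """1-based transcript positions of a codon's three bases (strand-aware)."""
    if region.strand == "+":
        first = region.start + 3 * codon_index
        return [first + 1, first + 2, first + 3]
    last = region.end - 3 * codon_index
    return [last - 2, last - 1, last]


def find_substitutions(
    pair: OrthologPair,
    ref_a: IntegratedReference,
    ref_b: IntegratedReference,
) -> list[SubstitutionSite]:
    """Codon columns where the aligned CDSs differ, outside both het masks.

    The ortholog proteins are globally aligned and the alignment projected
    back to codons; columns within ``GAP_GUARD_CODONS`` of an alignment gap
    are dropped as alignment-uncertain.  A column whose codon overlaps a
    heterozygous position in either species is never reported.
    """
    region_a = ref_a.regions[pair.gene_a]
    region_b = ref_b.regions[pair.gene_b]
    prot_a = region_a.protein
    prot_b = region_b.protein

    aligner = _protein_aligner()
    aln = aligner.align(prot_a, prot_b)[0]
    # column-wise residue indices; -1 marks a gap
    cols: list[tuple[int, int]] = []
    ia = ib = 0
    for (sa, ea), (sb, eb) in zip(*aln.aligned):
        while ia < sa:
            cols.append((ia, -1))
            ia += 1
        while ib < sb:
            cols.append((-1, ib))
            ib += 1
        for k in range(ea - sa):
            cols.append((sa + k, sb + k))
        ia, ib = ea, eb
    while ia < len(prot_a):
        cols.append((ia, -1))
        ia += 1
    while ib < len(prot_b):
        cols.append((-1, ib))
        ib += 1

    gap_cols = [i for i, (a, b) in enumerate(cols) if a < 0 or b < 0]
    sites: list[SubstitutionSite] = []
    for i, (a, b) in enumerate(cols):
        if a < 0 or b < 0:
            continue
        if any(abs(i - g) <= GAP_GUARD_CODONS for g in gap_cols):
            continue
        codon_a = region_a.codon(a)
        codon_b = region_b.codon(b)
        if codon_a == codon_b:
            continue
        if "N" in codon_a or "N" in codon_b:
            continue
        masked = any(
            (region_a.transcript_id, p) in ref_a.het_mask
            for p in codon_transcript_positions(region_a, a)
        ) or any(
            (region_b.transcript_id, p) in ref_b.het_mask
            for p in codon_transcript_positions(region_b, b)
        )
        if masked:
            continue
        aa_a, aa_b = CODON_TABLE.get(codon_a, "X"), CODON_TABLE.get(codon_b, "X")
        if "*" in (aa_a, aa_b) or "X" in (aa_a, aa_b):
            continue
        effect = "synonymous" if aa_a == aa_b else "nonsynonymous"
        sites.append(
            SubstitutionSite(
                gene_a=pair.gene_a,
                gene_b=pair.gene_b,
                codon_index_a=a,
                codon_index_b=b,
                codon_a=codon_a,
                codon_b=codon_b,
                effect=effect,
            )
        )
    return sites


@dataclass(frozen=True)
class SubstitutionLoad:
    per_gene: dict[str, float]
    mean: float
    n_sites_numerator: int
    n_sites_denominator: int


def deleterious_substitution_fraction(
    sites: Iterable[SubstitutionSite],
    scores: Iterable[EffectScore],
    method: str,
    query: str = "a",
    provean_denominator: str = "negative_scores",
    provean_threshold: float = PROVEAN_THRESHOLD,
    sift_threshold: float = SIFT_THRESHOLD,
    gene_of_transcript: dict[str, str] | None = None,
) -> SubstitutionLoad:
    """Per-gene deleterious proportion of nonsynonymous substitutions.

    ``query`` selects which species' coordinates/alleles the score table is
    keyed on.  Score rows name transcripts; ``gene_of_transcript`` (e.g. from
    the query species' :class:`IntegratedReference`) maps them onto the gene
    IDs the sites carry.  For PROVEAN the numerator is score <= -2.5; the
    denominator is either the substitutions with score < 0
    (``negative_scores``, the default reading) or every scored nonsynonymous
    substitution (``all_nonsyn``).  For SIFT: numerator score < 0.05 over the
    SIFT-evaluated substitutions.
    """
    if method not in ("provean", "sift"):
        raise ValueError(f"unknown method {method!r}")
    if provean_denominator not in ("negative_scores", "all_nonsyn"):
        raise ValueError(f"unknown provean_denominator {provean_denominator!r}")
    if query not in ("a", "b"):
        raise ValueError("query must be 'a' or 'b'")

    sites = [s for s in sites if s.effect == "nonsynonymous"]
    by_key: dict[tuple, SubstitutionSite] = {}
    for s in sites:
        if query == "a":
            key = (s.gene_a, s.codon_index_a + 1, s.aa_a, s.aa_b)
        else:
            key = (s.gene_b, s.codon_index_b + 1, s.aa_b, s.aa_a)
        by_key[key] = s

    counts: dict[str, list[int]] = {}
    n_num = n_den = 0
    for sc in scores:
        gene_key = (
            gene_of_transcript.get(sc.transcript_id, sc.transcript_id)
            if gene_of_transcript is not None
            else sc.transcript_id
        )
        key = (gene_key, sc.pos_1based, sc.ref_aa, sc.alt_aa)
        site = by_key.get(key)
        if site is None:
            raise KeyError(f"score row {key} matches no nonsynonymous substitution")
        gene = site.gene_a if query == "a" else site.gene_b
        num = den = 0
        if method == "provean":
            dele = classify_provean(sc.provean_score, provean_threshold) == "deleterious"
            in_den = (
                sc.provean_score < 0
                if provean_denominator == "negative_scores"
                else True
            )
            num, den = int(dele and in_den), int(in_den)
        else:
            call = classify_sift(sc.sift_score, sift_threshold)
            if call != "unevaluated":
                num, den = int(call == "deleterious"), 1
        if den:
            d, t = counts.get(gene, (0, 0))
            counts[gene] = [d + num, t + den]
            n_num += num
            n_den += den

    per_gene = {g: d / t for g, (d, t) in counts.items() if t}
    if not per_gene:
        raise NoDataError(f"no evaluated nonsynonymous substitutions for {method!r}")
    return SubstitutionLoad(
        per_gene=per_gene,
        mean=sum(per_gene.values()) / len(per_gene),
        n_sites_numerator=n_num,
        n_sites_denominator=n_den,
    )
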