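"""Synthetic transcriptome study generator.

Emits fully self-contained inputs — transcript FASTA with assembler-style
cluster/gene/isoform IDs, VCF of heterozygous SNVs, within-set and plant-DB
homology tables, PROVEAN/SIFT score tables, and interspecies ortholog pairs —
with the statistical structure the downstream indices assume, plus a JSON
truth ledger for parameter-recovery and oracle tests.

What is emulated: gene families with a controllable duplicated fraction;
per-transcript heterozygous SNVs with controllable density and
nonsynonymous/nonsense composition; effect-score tables with controllable
deleterious fractions and SIFT dropout; diverged ortholog pairs carrying
homozygous substitutions.  Codon content is uniform over the 61 sense codons
(composition targets are enforced by site selection, not codon bias); reads,
expression levels and assembly errors are not simulated.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .deleterious import EffectScore, write_scores
from .homology import HomologyHit
from .transcripts import (
    CODON_TABLE,
    STOP_CODONS,
    CodingRegion,
    Transcript,
    find_orf,
    translate,
)

_SENSE_CODONS = sorted(c for c in CODON_TABLE if CODON_TABLE[c] != "*")
_STOPS = sorted(STOP_CODONS)
_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generative model; defaults sit in the range of the study system.

    Rates are per coding base pair; ``interspecies_divergence`` is
    substitutions per coding site between an ortholog pair.
    """

    n_genes: int = 200
    duplicated_fraction: float = 0.70
    mean_cds_len_bp: int = 900
    het_snv_rate: float = 0.0005
    nonsyn_target_fraction: float = 0.55
    nonsense_given_nonsyn: float = 0.03
    deleterious_fraction_provean: float = 0.35
    deleterious_fraction_sift: float = 0.25
    sift_missing_rate: float = 0.10
    interspecies_divergence: float = 0.02
    n_specimens: int = 3
    seed: int = 0
    low_mq_fraction: float = 0.05
    masked_substitution_fraction: float = 0.10

    def __post_init__(self) -> None:
        probs = {
            "duplicated_fraction": self.duplicated_fraction,
            "nonsyn_target_fraction": self.nonsyn_target_fraction,
            "nonsense_given_nonsyn": self.nonsense_given_nonsyn,
            "deleterious_fraction_provean": self.deleterious_fraction_provean,
            "deleterious_fraction_sift": self.deleterious_fraction_sift,
            "sift_missing_rate": self.sift_missing_rate,
            "low_mq_fraction": self.low_mq_fraction,
            "masked_substitution_fraction": self.masked_substitution_fraction,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.het_snv_rate < 0 or self.interspecies_divergence < 0:
            raise ValueError("rates must be non-negative")
        if self.mean_cds_len_bp < 150 or self.mean_cds_len_bp % 3:
            raise ValueError("mean_cds_len_bp must be a multiple of 3 and >= 150")
        if self.n_genes < 1 or self.n_specimens < 1:
            raise ValueError("n_genes and n_specimens must be >= 1")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


def _rng_for(config_seed: int, *labels: str) -> np.random.Generator:
    """Deterministic generator keyed on the config seed and string labels."""
    tags = [zlib.crc32(lb.encode()) for lb in labels]
    return np.random.default_rng([config_seed & 0x7FFFFFFF, *tags])


# ---------------------------------------------------------------------------
# transcriptome


@dataclass
class GeneTruth:
    gene_id: str
    longest_isoform_id: str
    family: int
    duplicated: bool
    cds_start: int  # 0-based on the longest isoform, forward strand
    cds: str  # includes terminal stop
    isoform_ids: list[str] = field(default_factory=list)

    @property
    def cds_len(self) -> int:
        return len(self.cds)

    @property
    def coding_span_bp(self) -> int:
        """Coding positions available for SNV placement (stop codon excluded)."""
        return len(self.cds) - 3

    def region(self) -> CodingRegion:
        return CodingRegion(
            transcript_id=self.longest_isoform_id,
            strand="+",
            start=self.cds_start,
            end=self.cds_start + len(self.cds),
            cds=self.cds,
            protein=translate(self.cds),
        )


@dataclass
class TranscriptomeTruth:
    species: str
    genes: dict[str, GeneTruth]
    n_families_multi: int

    @property
    def true_pd(self) -> float:
        n_dup = sum(g.duplicated for g in self.genes.values())
        return n_dup / len(self.genes)


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + (n_codons-2) random sense codons + a random stop codon."""
    body = "".join(
        _SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), n_codons - 2)
    )
    return "ATG" + body + _STOPS[rng.integers(0, 3)]


def _mutate_cds(rng: np.random.Generator, cds: str, rate: float) -> str:
    """Low-divergence paralog copy: point substitutions that never touch a stop."""
    seq = list(cds)
    coding_end = len(cds) - 3
    n_mut = rng.binomial(coding_end - 3, rate)
    positions = rng.choice(np.arange(3, coding_end), size=min(n_mut, coding_end - 3), replace=False)
    for pos in sorted(int(p) for p in positions):
        ci, cp = divmod(pos, 3)
        codon = "".join(seq[3 * ci : 3 * ci + 3])
        alts = [b for b in _BASES if b != seq[pos]]
        rng.shuffle(alts)
        for alt in alts:
            new = codon[:cp] + alt + codon[cp + 1 :]
            if new not in STOP_CODONS:
                seq[pos] = alt
                break
    return "".join(seq)


def _build_gene_sequence(
    rng: np.random.Generator, cds: str
) -> tuple[str, int]:
    """Wrap a CDS in UTRs; returns (sequence, cds_start).

    The 5' UTR is frame-aligned and terminates in a stop codon so the chosen
    reading frame cannot extend upstream of the true CDS start.
    """
    n5 = int(rng.integers(0, 15))
    utr5 = ""
    if n5:
        utr5 = (
            "".join(_SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), n5 - 1))
            + _STOPS[rng.integers(0, 3)]
        )
    n3 = int(rng.integers(0, 45))
    utr3 = "".join(_BASES[i] for i in rng.integers(0, 4, n3))
    return utr5 + cds + utr3, len(utr5)


def generate_transcriptome(
    config: SimulationConfig, species_label: str = "SYN", single_isoform: bool = False
) -> tuple[list[Transcript], TranscriptomeTruth]:
    """Simulate one specimen's assembled transcript set.

    Genes flagged duplicated (probability ``duplicated_fraction``) are grouped
    into families of two (a leftover flagged gene joins the previous family;
    a lone flagged gene is demoted) whose members share a cluster ID and a
    low-divergence CDS copy.  Each gene gets 1-3 isoforms; the longest carries
    the full CDS, shorter ones are 3' truncations.  Every emitted longest
    isoform is verified to ORF-call back to its true coding region.
    """
    rng = _rng_for(config.seed, "transcriptome", species_label)
    mean_codons = config.mean_cds_len_bp // 3

    flags = rng.random(config.n_genes) < config.duplicated_fraction
    flagged = [i for i in range(config.n_genes) if flags[i]]
    if len(flagged) == 1:
        flags[flagged[0]] = False
        flagged = []

    # family id per gene; flagged genes pair up, odd leftover joins last family
    family_of: dict[int, int] = {}
    n_fam = 0
    for a, b in zip(flagged[0::2], flagged[1::2]):
        family_of[a] = n_fam
        family_of[b] = n_fam
        n_fam += 1
    if len(flagged) % 2 and flagged:
        family_of[flagged[-1]] = n_fam - 1
    next_cluster = n_fam

    base_cds: dict[int, str] = {}  # family -> founder CDS
    member_of: dict[int, int] = {}  # gene index -> member number within cluster
    genes: dict[str, GeneTruth] = {}
    transcripts: list[Transcript] = []

    for gi in range(config.n_genes):
        n_codons = max(53, int(round(rng.normal(mean_codons, 0.15 * mean_codons))))
        if gi in family_of:
            fam = family_of[gi]
            member = sum(1 for g, f in member_of.items() if family_of.get(g) == fam)
            member_of[gi] = member
            if fam not in base_cds:
                base_cds[fam] = _random_cds(rng, n_codons)
                cds = base_cds[fam]
            else:
                cds = _mutate_cds(rng, base_cds[fam], rate=0.02)
            cluster = fam
        else:
            cluster = next_cluster
            next_cluster += 1
            member = 0
            cds = _random_cds(rng, n_codons)

        n_iso = 1 if single_isoform else int(rng.integers(1, 4))
        gene_id = f"{species_label}_c{cluster}_g{member}"
        # verify the ORF caller recovers exactly the planted CDS; resample on
        # the rare chance a shifted frame beats it
        for _ in range(25):
            seq, cds_start = _build_gene_sequence(rng, cds)
            probe = Transcript(id=f"{gene_id}_i1", seq=seq, species=species_label)
            cr = find_orf(probe)
            if (
                cr is not None
                and cr.strand == "+"
                and cr.start == cds_start
                and cr.end == cds_start + len(cds)
            ):
                break
            cds = _random_cds(rng, n_codons) if gi not in family_of else _mutate_cds(
                rng, base_cds[family_of[gi]], rate=0.02
            )
        else:  # pragma: no cover - probability vanishes with 25 attempts
            raise RuntimeError(f"could not build an ORF-stable gene for {gene_id}")

        iso_ids = [f"{gene_id}_i{k + 1}" for k in range(n_iso)]
        truth = GeneTruth(
            gene_id=gene_id,
            longest_isoform_id=iso_ids[0],
            family=cluster,
            duplicated=gi in family_of,
            cds_start=cds_start,
            cds=cds,
            isoform_ids=iso_ids,
        )
        genes[gene_id] = truth
        transcripts.append(Transcript(id=iso_ids[0], seq=seq, species=species_label))
        for k in range(1, n_iso):
            cut = int(rng.integers(len(seq) // 2, len(seq)))
            transcripts.append(
                Transcript(id=iso_ids[k], seq=seq[:cut], species=species_label)
            )

    return transcripts, TranscriptomeTruth(
        species=species_label, genes=genes, n_families_multi=len(base_cds)
    )


# ---------------------------------------------------------------------------
# variants


@dataclass
class PlantedVariant:
    gene_id: str
    transcript_id: str
    pos: int  # 1-based transcript coordinate
    ref: str
    alt: str
    cds_offset: int
    codon_index: int
    ref_aa: str
    alt_aa: str
    effect: str  # synonymous | missense | nonsense
    mq: float
    zygosity: str = "het"

    @property
    def passes_mq(self) -> bool:
        return self.mq > 30.0


def _classify_change(codon: str, cp: int, alt: str) -> tuple[str, str, str]:
    alt_codon = codon[:cp] + alt + codon[cp + 1 :]
    ref_aa, alt_aa = CODON_TABLE[codon], CODON_TABLE[alt_codon]
    if alt_aa == "*":
        effect = "nonsense"
    elif ref_aa == alt_aa:
        effect = "synonymous"
    else:
        effect = "missense"
    return ref_aa, alt_aa, effect


def _place_variant(
    rng: np.random.Generator, cds: str, target: str, taken: set[int]
) -> tuple[int, str, str, str, str] | None:
    """Pick (cds_offset, alt, ref_aa, alt_aa, effect) matching the target class.

    Rejection-samples positions/alleles, then falls back to exhaustive scan;
    None when the CDS offers no site of the target class (tiny genes).
    """
    span = len(cds) - 3  # stop codon not mutated
    for _ in range(300):
        off = int(rng.integers(0, span))
        if off in taken:
            continue
        ci, cp = divmod(off, 3)
        codon = cds[3 * ci : 3 * ci + 3]
        alt = _BASES[rng.integers(0, 4)]
        if alt == cds[off]:
            continue
        ref_aa, alt_aa, effect = _classify_change(codon, cp, alt)
        if effect == target:
            return off, alt, ref_aa, alt_aa, effect
    for off in rng.permutation(span):
        off = int(off)
        if off in taken:
            continue
        ci, cp = divmod(off, 3)
        codon = cds[3 * ci : 3 * ci + 3]
        for alt in _BASES:
            if alt == cds[off]:
                continue
            ref_aa, alt_aa, effect = _classify_change(codon, cp, alt)
            if effect == target:
                return off, alt, ref_aa, alt_aa, effect
    return None


def generate_variants(
    truth: TranscriptomeTruth, config: SimulationConfig, stream: str = "variants"
) -> list[PlantedVariant]:
    """Plant heterozygous SNVs on coding positions of each longest isoform.

    Per-SNV effect class is drawn from the configured composition
    (nonsynonymous with probability ``nonsyn_target_fraction``, nonsense given
    nonsynonymous with ``nonsense_given_nonsyn``) and a matching site is
    found; ``low_mq_fraction`` of records receive RMS MQ <= 30.
    """
    rng = _rng_for(config.seed, stream, truth.species)
    planted: list[PlantedVariant] = []
    for gene_id in sorted(truth.genes):
        g = truth.genes[gene_id]
        n_snv = rng.binomial(g.coding_span_bp, config.het_snv_rate)
        taken: set[int] = set()
        for _ in range(n_snv):
            if rng.random() < config.nonsyn_target_fraction:
                target = (
                    "nonsense"
                    if rng.random() < config.nonsense_given_nonsyn
                    else "missense"
                )
            else:
                target = "synonymous"
            site = _place_variant(rng, g.cds, target, taken)
            if site is None and target == "nonsense":
                site = _place_variant(rng, g.cds, "missense", taken)
            if site is None:
                continue
            off, alt, ref_aa, alt_aa, effect = site
            taken.add(off)
            if rng.random() < config.low_mq_fraction:
                mq = float(np.round(rng.uniform(10.0, 30.0), 1))
            else:
                mq = float(np.round(rng.uniform(35.0, 60.0), 1))
            planted.append(
                PlantedVariant(
                    gene_id=gene_id,
                    transcript_id=g.longest_isoform_id,
                    pos=g.cds_start + off + 1,
                    ref=g.cds[off],
                    alt=alt,
                    cds_offset=off,
                    codon_index=off // 3,
                    ref_aa=ref_aa,
                    alt_aa=alt_aa,
                    effect=effect,
                    mq=mq,
                )
            )
    planted.sort(key=lambda v: (v.transcript_id, v.pos))
    return planted


def inflate_paralog_variants(
    truth: TranscriptomeTruth,
    base: list[PlantedVariant],
    config: SimulationConfig,
    extra_rate: float,
) -> list[PlantedVariant]:
    """Plant additional het SNVs on duplicated genes only (mapping-artifact model).

    Emulates the inflation of apparent heterozygosity on paralogous
    transcripts caused by cross-paralog read mapping; singleton genes keep
    exactly the base variant set.
    """
    extra_all = generate_variants(
        truth, config.replace(het_snv_rate=extra_rate), stream="paralog_inflation"
    )
    seen = {(v.transcript_id, v.pos) for v in base}
    merged = base + [
        v
        for v in extra_all
        if truth.genes[v.gene_id].duplicated and (v.transcript_id, v.pos) not in seen
    ]
    merged.sort(key=lambda v: (v.transcript_id, v.pos))
    return merged


# ---------------------------------------------------------------------------
# scores


@dataclass
class ScoreTruth:
    score: EffectScore
    provean_deleterious: bool
    sift_deleterious: bool | None  # None when SIFT missing


def generate_scores(
    variants: list[PlantedVariant],
    config: SimulationConfig,
    species: str = "SYN",
    stream: str = "scores",
) -> list[ScoreTruth]:
    """PROVEAN/SIFT scores for nonsynonymous variants that pass the MQ filter."""
    rng = _rng_for(config.seed, stream, species)
    out: list[ScoreTruth] = []
    for v in variants:
        if v.effect == "synonymous" or not v.passes_mq:
            continue
        dele_p = bool(rng.random() < config.deleterious_fraction_provean)
        provean = (
            rng.uniform(-8.0, -2.5) if dele_p else rng.uniform(-2.4, 4.0)
        )
        if rng.random() < config.sift_missing_rate:
            sift, dele_s = None, None
        else:
            dele_s = bool(rng.random() < config.deleterious_fraction_sift)
            sift = rng.uniform(0.0, 0.0499) if dele_s else rng.uniform(0.05, 1.0)
        out.append(
            ScoreTruth(
                score=EffectScore(
                    transcript_id=v.transcript_id,
                    pos_1based=v.codon_index + 1,
                    ref_aa=v.ref_aa,
                    alt_aa=v.alt_aa,
                    provean_score=float(np.round(provean, 4)),
                    sift_score=None if sift is None else float(np.round(sift, 4)),
                ),
                provean_deleterious=dele_p,
                sift_deleterious=dele_s,
            )
        )
    return out


# ---------------------------------------------------------------------------
# homology tables


def generate_homology(
    truth: TranscriptomeTruth,
) -> tuple[list[HomologyHit], list[HomologyHit]]:
    """Within-set and plant-DB hit tables implied by the family structure.

    Family members hit each other (tiny E-value, full coverage); every gene
    hits one plant protein.  Proteins are the longest-isoform translations.
    """
    by_family: dict[int, list[GeneTruth]] = {}
    for g in truth.genes.values():
        by_family.setdefault(g.family, []).append(g)

    self_hits: list[HomologyHit] = []
    for fam in sorted(by_family):
        members = sorted(by_family[fam], key=lambda g: g.gene_id)
        if len(members) < 2:
            continue
        for q in members:
            qlen = len(translate(q.cds))
            for s in members:
                if s.gene_id == q.gene_id:
                    continue
                self_hits.append(
                    HomologyHit(
                        query_id=q.gene_id,
                        subject_id=s.gene_id,
                        percent_identity=98.0,
                        alignment_length=qlen,
                        evalue=1e-50,
                        query_length=qlen,
                    )
                )

    plant_hits = []
    for i, gene_id in enumerate(sorted(truth.genes)):
        qlen = len(translate(truth.genes[gene_id].cds))
        plant_hits.append(
            HomologyHit(
                query_id=gene_id,
                subject_id=f"PLANT_{i:05d}",
                percent_identity=62.0,
                alignment_length=max(1, int(0.8 * qlen)),
                evalue=1e-30,
                query_length=qlen,
            )
        )
    return self_hits, plant_hits


# ---------------------------------------------------------------------------
# species pairs (interspecies substitutions)


@dataclass
class SubstitutionTruth:
    gene_id_a: str
    gene_id_b: str
    codon_index: int
    codon_a: str
    codon_b: str
    effect: str  # synonymous | nonsynonymous
    masked: bool = False
    provean_dele_query_a: bool | None = None
    provean_dele_query_b: bool | None = None
    sift_dele_query_a: bool | None = None
    sift_dele_query_b: bool | None = None


@dataclass
class SpeciesPairTruth:
    truth_a: TranscriptomeTruth
    truth_b: TranscriptomeTruth
    transcripts_a: list[Transcript]
    transcripts_b: list[Transcript]
    substitutions: list[SubstitutionTruth]
    het_a: list[PlantedVariant]
    het_b: list[PlantedVariant]
    scores_a: list[ScoreTruth]  # species A as query
    scores_b: list[ScoreTruth]
    protein_identity: dict[str, float]  # gene_id_a -> percent identity


def _diverge_cds(
    rng: np.random.Generator, cds: str, rate: float
) -> tuple[str, list[tuple[int, str, str]]]:
    """Substitute coding sites at the given per-site rate; stops never created."""
    seq = list(cds)
    events: list[tuple[int, str, str]] = []
    span = len(cds) - 3
    n_sub = rng.binomial(span, rate)
    positions = sorted(
        int(p) for p in rng.choice(span, size=min(n_sub, span), replace=False)
    )
    for pos in positions:
        ci, cp = divmod(pos, 3)
        codon = "".join(seq[3 * ci : 3 * ci + 3])
        alts = [b for b in _BASES if b != seq[pos]]
        rng.shuffle(alts)
        for alt in alts:
            new = codon[:cp] + alt + codon[cp + 1 :]
            if new not in STOP_CODONS:
                events.append((pos, seq[pos], alt))
                seq[pos] = alt
                break
    return "".join(seq), events


def generate_species_pair(
    config: SimulationConfig,
    label_a: str = "SPA",
    label_b: str = "SPB",
    divergence: float | None = None,
) -> SpeciesPairTruth:
    """Two orthologous transcript sets diverged at the configured rate.

    Species B genes are per-site substituted copies of species A genes (same
    cluster/gene numbering, so reciprocal-best pairing has a known answer).
    Pooled heterozygous SNVs are planted in both species; additionally a
    ``masked_substitution_fraction`` of substitution codons receive a het call
    so the het-exclusion rule is exercised.  Per-direction PROVEAN/SIFT scores
    are drawn for every nonsynonymous substitution.
    """
    if divergence is None:
        divergence = config.interspecies_divergence
    transcripts_a, truth_a = generate_transcriptome(
        config, species_label=label_a, single_isoform=False
    )
    seq_of = {t.id: t.seq for t in transcripts_a}
    rng = _rng_for(config.seed, "pair", label_a, label_b)

    genes_b: dict[str, GeneTruth] = {}
    transcripts_b: list[Transcript] = []
    substitutions: list[SubstitutionTruth] = []
    identity: dict[str, float] = {}
    for gene_id in sorted(truth_a.genes):
        ga = truth_a.genes[gene_id]
        gene_id_b = gene_id.replace(label_a, label_b, 1)
        seq_a = seq_of[ga.longest_isoform_id]
        # re-diverge on the rare chance the substituted CDS no longer wins the
        # six-frame ORF scan of its transcript
        for _ in range(10):
            cds_b, events = _diverge_cds(rng, ga.cds, divergence)
            seq_b = (
                seq_a[: ga.cds_start] + cds_b + seq_a[ga.cds_start + len(ga.cds) :]
            )
            probe = Transcript(id=f"{gene_id_b}_i1", seq=seq_b, species=label_b)
            cr = find_orf(probe)
            if (
                cr is not None
                and cr.strand == "+"
                and cr.start == ga.cds_start
                and cr.end == ga.cds_start + len(cds_b)
            ):
                break
        else:  # pragma: no cover
            raise RuntimeError(f"could not build an ORF-stable ortholog for {gene_id_b}")
        gb = GeneTruth(
            gene_id=gene_id_b,
            longest_isoform_id=f"{gene_id_b}_i1",
            family=ga.family,
            duplicated=ga.duplicated,
            cds_start=ga.cds_start,
            cds=cds_b,
            isoform_ids=[f"{gene_id_b}_i1"],
        )
        genes_b[gene_id_b] = gb
        transcripts_b.append(probe)

        prot_a, prot_b = translate(ga.cds), translate(gb.cds)
        n_same = sum(a == b for a, b in zip(prot_a, prot_b))
        identity[gene_id] = 100.0 * n_same / len(prot_a)

        by_codon: dict[int, list[tuple[int, str, str]]] = {}
        for pos, ref, alt in events:
            by_codon.setdefault(pos // 3, []).append((pos, ref, alt))
        for ci in sorted(by_codon):
            codon_a = ga.cds[3 * ci : 3 * ci + 3]
            codon_b = cds_b[3 * ci : 3 * ci + 3]
            effect = (
                "synonymous"
                if CODON_TABLE[codon_a] == CODON_TABLE[codon_b]
                else "nonsynonymous"
            )
            substitutions.append(
                SubstitutionTruth(
                    gene_id_a=gene_id,
                    gene_id_b=gene_id_b,
                    codon_index=ci,
                    codon_a=codon_a,
                    codon_b=codon_b,
                    effect=effect,
                )
            )

    truth_b = TranscriptomeTruth(
        species=label_b, genes=genes_b, n_families_multi=truth_a.n_families_multi
    )

    het_a = generate_variants(truth_a, config, stream="pooled_het")
    het_b = generate_variants(truth_b, config, stream="pooled_het")

    # force a fraction of substitution codons under a het call in one species
    extra_a: list[PlantedVariant] = []
    extra_b: list[PlantedVariant] = []
    for sub in substitutions:
        if rng.random() >= config.masked_substitution_fraction:
            continue
        which = rng.random() < 0.5
        truth = truth_a if which else truth_b
        gid = sub.gene_id_a if which else sub.gene_id_b
        g = truth.genes[gid]
        off = 3 * sub.codon_index  # first base of the codon
        ref = g.cds[off]
        alt = next(b for b in _BASES if b != ref)
        pv = PlantedVariant(
            gene_id=gid,
            transcript_id=g.longest_isoform_id,
            pos=g.cds_start + off + 1,
            ref=ref,
            alt=alt,
            cds_offset=off,
            codon_index=sub.codon_index,
            ref_aa=CODON_TABLE[g.cds[3 * sub.codon_index : 3 * sub.codon_index + 3]],
            alt_aa="X",
            effect="forced_mask",
            mq=50.0,
        )
        (extra_a if which else extra_b).append(pv)

    def _merge(base: list[PlantedVariant], extra: list[PlantedVariant]):
        seen = {(v.transcript_id, v.pos) for v in base}
        merged = base + [v for v in extra if (v.transcript_id, v.pos) not in seen]
        merged.sort(key=lambda v: (v.transcript_id, v.pos))
        return merged

    het_a = _merge(het_a, extra_a)
    het_b = _merge(het_b, extra_b)

    # mark masked substitutions from the realised het positions
    het_pos_a = {(v.transcript_id, v.pos) for v in het_a}
    het_pos_b = {(v.transcript_id, v.pos) for v in het_b}
    for sub in substitutions:
        ga = truth_a.genes[sub.gene_id_a]
        gb = genes_b[sub.gene_id_b]
        pos_a = {
            (ga.longest_isoform_id, ga.cds_start + 3 * sub.codon_index + k + 1)
            for k in range(3)
        }
        pos_b = {
            (gb.longest_isoform_id, gb.cds_start + 3 * sub.codon_index + k + 1)
            for k in range(3)
        }
        sub.masked = bool(pos_a & het_pos_a or pos_b & het_pos_b)

    # per-direction effect scores for nonsynonymous substitutions
    scores_a: list[ScoreTruth] = []
    scores_b: list[ScoreTruth] = []
    srng = _rng_for(config.seed, "pair_scores", label_a, label_b)
    for sub in substitutions:
        # only sites the pipeline can submit are scored: nonsynonymous and
        # not disqualified by a heterozygous call in either species
        if sub.effect != "nonsynonymous" or sub.masked:
            continue
        for as_query_a in (True, False):
            gid = sub.gene_id_a if as_query_a else sub.gene_id_b
            truth = truth_a if as_query_a else truth_b
            ref_aa = CODON_TABLE[sub.codon_a if as_query_a else sub.codon_b]
            alt_aa = CODON_TABLE[sub.codon_b if as_query_a else sub.codon_a]
            dele_p = bool(srng.random() < config.deleterious_fraction_provean)
            provean = srng.uniform(-8.0, -2.5) if dele_p else srng.uniform(-2.4, 4.0)
            if srng.random() < config.sift_missing_rate:
                sift, dele_s = None, None
            else:
                dele_s = bool(srng.random() < config.deleterious_fraction_sift)
                sift = srng.uniform(0.0, 0.0499) if dele_s else srng.uniform(0.05, 1.0)
            st = ScoreTruth(
                score=EffectScore(
                    transcript_id=truth.genes[gid].longest_isoform_id,
                    pos_1based=sub.codon_index + 1,
                    ref_aa=ref_aa,
                    alt_aa=alt_aa,
                    provean_score=float(np.round(provean, 4)),
                    sift_score=None if sift is None else float(np.round(sift, 4)),
                ),
                provean_deleterious=dele_p,
                sift_deleterious=dele_s,
            )
            if as_query_a:
                sub.provean_dele_query_a = dele_p
                sub.sift_dele_query_a = dele_s
                scores_a.append(st)
            else:
                sub.provean_dele_query_b = dele_p
                sub.sift_dele_query_b = dele_s
                scores_b.append(st)

    return SpeciesPairTruth(
        truth_a=truth_a,
        truth_b=truth_b,
        transcripts_a=transcripts_a,
        transcripts_b=transcripts_b,
        substitutions=substitutions,
        het_a=het_a,
        het_b=het_b,
        scores_a=scores_a,
        scores_b=scores_b,
        protein_identity=identity,
    )


def generate_pair_homology(
    pair: SpeciesPairTruth,
) -> tuple[list[HomologyHit], list[HomologyHit]]:
    """Cross-species hit tables in both query directions, identity from truth."""
    hits_ab: list[HomologyHit] = []
    hits_ba: list[HomologyHit] = []
    for gene_id in sorted(pair.truth_a.genes):
        ga = pair.truth_a.genes[gene_id]
        gb_id = gene_id.replace(pair.truth_a.species, pair.truth_b.species, 1)
        gb = pair.truth_b.genes[gb_id]
        ident = pair.protein_identity[gene_id]
        la = len(translate(ga.cds))
        lb = len(translate(gb.cds))
        hits_ab.append(
            HomologyHit(
                query_id=gene_id,
                subject_id=gb_id,
                percent_identity=float(np.round(ident, 2)),
                alignment_length=la,
                evalue=1e-80,
                query_length=la,
            )
        )
        hits_ba.append(
            HomologyHit(
                query_id=gb_id,
                subject_id=gene_id,
                percent_identity=float(np.round(ident, 2)),
                alignment_length=lb,
                evalue=1e-80,
                query_length=lb,
            )
        )
    return hits_ab, hits_ba


# ---------------------------------------------------------------------------
# file writers


def write_fasta(transcripts: list[Transcript], path: str | Path) -> None:
    """60-column wrapped FASTA."""
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.id}\n")
            for i in range(0, len(t.seq), 60):
                fh.write(t.seq[i : i + 60] + "\n")


def write_vcf(
    variants: list[PlantedVariant],
    transcripts: list[Transcript],
    path: str | Path,
    sample: str = "specimen",
) -> None:
    """Minimal VCFv4.2: GT per sample, RMS mapping quality as INFO MQ."""
    lengths = {t.id: len(t.seq) for t in transcripts}
    for v in variants:
        if v.transcript_id not in lengths:
            raise KeyError(
                f"variant on transcript {v.transcript_id!r} absent from the FASTA"
            )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for tid in sorted({v.transcript_id for v in variants}):
            fh.write(f"##contig=<ID={tid},length={lengths[tid]}>\n")
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for v in sorted(variants, key=lambda v: (v.transcript_id, v.pos)):
            gt = "0/1" if v.zygosity == "het" else "1/1"
            fh.write(
                f"{v.transcript_id}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t"
                f"MQ={v.mq:g}\tGT\t{gt}\n"
            )


def write_blast_tab(hits: list[HomologyHit], path: str | Path) -> None:
    """13-column tabular hits (outfmt-6 style + qlen)."""
    with open(path, "w") as fh:
        fh.write("# qseqid sseqid pident length mismatch gapopen qstart qend "
                 "sstart send evalue bitscore qlen\n")
        for h in hits:
            n_mismatch = int(round(h.alignment_length * (100 - h.percent_identity) / 100))
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.percent_identity:.2f}\t"
                f"{h.alignment_length}\t{n_mismatch}\t0\t1\t{h.alignment_length}\t"
                f"1\t{h.alignment_length}\t{h.evalue:.2e}\t{2.0 * h.alignment_length:.1f}\t"
                f"{h.query_length}\n"
            )


@dataclass
class SpecimenBundle:
    """One specimen's generated inputs plus its truth objects."""

    species: str
    specimen: str
    transcripts: list[Transcript]
    truth: TranscriptomeTruth
    variants: list[PlantedVariant]
    scores: list[ScoreTruth]
    self_hits: list[HomologyHit]
    plant_hits: list[HomologyHit]


def generate_specimen(
    config: SimulationConfig, species: str, specimen: str
) -> SpecimenBundle:
    """Full input set for one specimen (own assembly, variants, scores, homology)."""
    spec_cfg = config.replace(seed=int(_rng_for(config.seed, species, specimen).integers(0, 2**31 - 1)))
    transcripts, truth = generate_transcriptome(spec_cfg, species_label=species)
    variants = generate_variants(truth, spec_cfg)
    scores = generate_scores(variants, spec_cfg, species=species)
    self_hits, plant_hits = generate_homology(truth)
    return SpecimenBundle(
        species=species,
        specimen=specimen,
        transcripts=transcripts,
        truth=truth,
        variants=variants,
        scores=scores,
        self_hits=self_hits,
        plant_hits=plant_hits,
    )


def write_specimen(bundle: SpecimenBundle, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prefix = f"{bundle.species}_{bundle.specimen}"
    paths = {
        "fasta": outdir / f"{prefix}.fasta",
        "vcf": outdir / f"{prefix}.vcf",
        "self_hits": outdir / f"{prefix}.self.tsv",
        "plant_hits": outdir / f"{prefix}.plant.tsv",
        "scores": outdir / f"{prefix}.scores.tsv",
        "truth": outdir / f"{prefix}.truth.json",
    }
    write_fasta(bundle.transcripts, paths["fasta"])
    write_vcf(bundle.variants, bundle.transcripts, paths["vcf"], sample=prefix)
    write_blast_tab(bundle.self_hits, paths["self_hits"])
    write_blast_tab(bundle.plant_hits, paths["plant_hits"])
    write_scores([s.score for s in bundle.scores], paths["scores"])
    ledger = {
        "species": bundle.species,
        "specimen": bundle.specimen,
        "true_pd": bundle.truth.true_pd,
        "variants": [dataclasses.asdict(v) for v in bundle.variants],
        "genes": {
            gid: {
                "longest_isoform_id": g.longest_isoform_id,
                "duplicated": g.duplicated,
                "cds_start": g.cds_start,
                "cds_len": g.cds_len,
            }
            for gid, g in bundle.truth.genes.items()
        },
    }
    paths["truth"].write_text(json.dumps(ledger, indent=0, sort_keys=True))
    return paths


# ---------------------------------------------------------------------------
# study-condition presets

#: Conditions for an endangered-island-endemic-like species: lower
#: heterozygosity and duplicated-gene fraction, higher nonsynonymous /
#: nonsense / deleterious load.  Contrasts mirror the direction and rough
#: magnitude of the published species averages, with SNV densities scaled up
#: so a few hundred simulated genes carry enough variants for the direction
#: of each index to be resolvable.
EIE_LIKE = SimulationConfig(
    n_genes=300,
    duplicated_fraction=0.68,
    het_snv_rate=0.0008,
    nonsyn_target_fraction=0.62,
    nonsense_given_nonsyn=0.06,
    deleterious_fraction_provean=0.40,
    deleterious_fraction_sift=0.30,
    n_specimens=3,
)

#: Non-endangered widespread congener conditions (see :data:`EIE_LIKE`).
NE_LIKE = SimulationConfig(
    n_genes=300,
    duplicated_fraction=0.78,
    het_snv_rate=0.0016,
    nonsyn_target_fraction=0.50,
    nonsense_given_nonsyn=0.012,
    deleterious_fraction_provean=0.28,
    deleterious_fraction_sift=0.18,
    n_specimens=3,
)
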