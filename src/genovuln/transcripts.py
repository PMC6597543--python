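"""Transcript models: isoform selection, reading-frame identification, translation.

De novo assemblers emit several splicing isoforms per gene under a
cluster/gene/isoform ID hierarchy.  For per-gene indices we keep the single
longest isoform, locate its coding region as the longest stop-free stretch
over all six reading frames (edge-tolerant: no start-codon requirement, the
terminal stop is optional at a contig edge), translate it with the standard
genetic code, and discard proteins shorter than 50 amino acids.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio.Data import CodonTable
from Bio.Seq import reverse_complement

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
#: codon -> one-letter amino acid; stop codons map to '*'
CODON_TABLE: dict[str, str] = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    CODON_TABLE[_stop] = "*"

STOP_CODONS = frozenset(_STANDARD.stop_codons)
MIN_PROTEIN_AA = 50

_ID_RE = re.compile(r"^(?P<prefix>.*)_c(?P<cluster>\d+)_g(?P<gene>\d+)_i(?P<isoform>\d+)$")
_VALID_SEQ_RE = re.compile(r"^[ACGTN]+$")


class TranscriptIDError(ValueError):
    """Raised when a transcript ID does not follow the cluster/gene/isoform scheme."""


@dataclass(frozen=True)
class Transcript:
    """An assembled contig attributed to a species/specimen."""

    id: str
    seq: str
    species: str = ""
    specimen: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"empty sequence for transcript {self.id!r}")
        if not _VALID_SEQ_RE.match(self.seq.upper()):
            raise ValueError(
                f"transcript {self.id!r}: sequence contains non-IUPAC characters "
                "(alphabet is A/C/G/T/N)"
            )


@dataclass(frozen=True)
class CodingRegion:
    """A reading frame chosen on a transcript.

    ``start``/``end`` are 0-based half-open positions on the forward
    (as-assembled) transcript sequence regardless of strand; ``cds`` is read
    5'->3' on the coding strand and includes the terminal stop codon when one
    is present; ``protein`` never includes the stop.
    """

    transcript_id: str
    strand: str
    start: int
    end: int
    cds: str
    protein: str

    @property
    def cds_len(self) -> int:
        return self.end - self.start

    def codon(self, codon_index: int) -> str:
        return self.cds[3 * codon_index : 3 * codon_index + 3]


def parse_transcript_id(transcript_id: str) -> tuple[str, str, str]:
    """Split an assembler-style ID into (gene_id, cluster_gene_key, isoform).

    Gene identity is the cluster+gene part of the ID; isoforms of one gene
    differ only in the trailing ``_i`` field.
    """
    m = _ID_RE.match(transcript_id)
    if m is None:
        raise TranscriptIDError(
            f"transcript ID {transcript_id!r} does not match the "
            "'<prefix>_c<cluster>_g<gene>_i<isoform>' scheme"
        )
    gene_id = f"{m['prefix']}_c{m['cluster']}_g{m['gene']}"
    return gene_id, f"c{m['cluster']}_g{m['gene']}", m["isoform"]


def gene_id_of(transcript_id: str) -> str:
    return parse_transcript_id(transcript_id)[0]


def select_longest_isoform(transcripts: list[Transcript]) -> dict[str, Transcript]:
    """One transcript per gene: maximal length, ties to the smallest isoform ID."""
    chosen: dict[str, Transcript] = {}
    for t in transcripts:
        gene_id = gene_id_of(t.id)
        best = chosen.get(gene_id)
        if (
            best is None
            or len(t.seq) > len(best.seq)
            or (len(t.seq) == len(best.seq) and t.id < best.id)
        ):
            chosen[gene_id] = t
    return chosen


def translate(cds: str) -> str:
    """Translate a CDS with the standard code; codons containing N become 'X'.

    A trailing stop codon is trimmed from the protein; internal stops are
    rendered '*' (callers enforce their absence).
    """
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    cds = cds.upper()
    aa = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        aa.append(CODON_TABLE.get(codon, "X"))
    if aa and aa[-1] == "*":
        aa.pop()
    return "".join(aa)


def _frame_runs(seq: str, offset: int):
    """Yield (start, n_codons, has_stop) maximal stop-free codon runs in one frame.

    ``start`` indexes into ``seq``; the run spans ``n_codons`` non-stop codons
    and ``has_stop`` marks whether a stop codon immediately follows (the run
    is then extended by that codon when reported as a CDS).
    """
    n = len(seq)
    run_start = offset
    run_len = 0
    for i in range(offset, n - 2, 3):
        codon = seq[i : i + 3]
        if codon in STOP_CODONS:
            if run_len:
                yield run_start, run_len, True
            run_start = i + 3
            run_len = 0
        else:
            run_len += 1
    if run_len:
        yield run_start, run_len, False


def find_orf(t: Transcript, min_protein_aa: int = MIN_PROTEIN_AA) -> CodingRegion | None:
    """Longest open reading frame over six frames, or None below the length cutoff.

    ORFs need not begin with ATG and need not end with a stop when the run
    hits the contig edge.  Ties are broken toward the forward strand, then the
    smallest start coordinate.
    """
    seq = t.seq.upper()
    if not _VALID_SEQ_RE.match(seq):
        raise ValueError(f"transcript {t.id!r} contains non-IUPAC characters")
    rc = reverse_complement(seq)
    n = len(seq)

    best: tuple[int, int, int] | None = None  # (-n_codons, strand_rank, start_fwd)
    best_payload = None
    for strand, s in (("+", seq), ("-", rc)):
        for offset in (0, 1, 2):
            for run_start, n_codons, has_stop in _frame_runs(s, offset):
                if n_codons < min_protein_aa:
                    continue
                span = 3 * n_codons + (3 if has_stop else 0)
                if strand == "+":
                    start_fwd, end_fwd = run_start, run_start + span
                else:
                    end_fwd = n - run_start
                    start_fwd = end_fwd - span
                key = (-n_codons, 0 if strand == "+" else 1, start_fwd)
                if best is None or key < best:
                    best = key
                    cds = s[run_start : run_start + span]
                    best_payload = (strand, start_fwd, end_fwd, cds)
    if best_payload is None:
        return None
    strand, start, end, cds = best_payload
    return CodingRegion(
        transcript_id=t.id,
        strand=strand,
        start=start,
        end=end,
        cds=cds,
        protein=translate(cds),
    )


def find_coding_regions(
    transcripts: dict[str, Transcript], min_protein_aa: int = MIN_PROTEIN_AA
) -> dict[str, CodingRegion]:
    """ORF-call each gene's chosen transcript; genes without a qualifying ORF drop out."""
    regions: dict[str, CodingRegion] = {}
    for gene_id, t in transcripts.items():
        cr = find_orf(t, min_protein_aa=min_protein_aa)
        if cr is not None:
            regions[gene_id] = cr
    return regions
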