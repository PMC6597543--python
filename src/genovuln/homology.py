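"""Duplicated-gene classification from protein homology tables and P_D.

A gene is a *candidate duplicate* when its longest-isoform protein hits
another protein of the same transcriptome at E-value < 1e-4 with query
coverage > 30% (coverage on amino-acid lengths); otherwise it is a candidate
singleton.  Candidates are promoted to duplicated/singleton only when the
protein also hits the plant protein database (E-value < 1e-4, no coverage
requirement); genes without plant homology are excluded from every index.
P_D is the duplicated fraction of the non-excluded genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable

import pandas as pd

EVALUE_MAX = 1e-4
QCOV_MIN_PCT = 30.0

#: standard 12-column tabular output of a protein search, plus query length
BLAST_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
    "qlen",
]


class GeneLabel(str, Enum):
    DUPLICATED = "duplicated"
    SINGLETON = "singleton"
    EXCLUDED = "excluded_no_plant_homology"


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    evalue: float
    query_length: int

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative E-value {self.evalue} for {self.query_id}")
        if not 0 <= self.percent_identity <= 100:
            raise ValueError(f"percent identity {self.percent_identity} outside [0, 100]")
        if self.alignment_length < 1:
            raise ValueError(f"alignment length {self.alignment_length} < 1")

    @property
    def query_coverage_pct(self) -> float:
        return 100.0 * self.alignment_length / self.query_length


class NoDataError(RuntimeError):
    """An index is undefined because its denominator is empty."""


def read_blast_tab(path: str | Path) -> list[HomologyHit]:
    """Read 13-column tabular hits (outfmt-6 + qlen); '#' comment lines ignored."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=BLAST_COLUMNS)
    if df["qlen"].isna().any():
        raise ValueError(f"{path}: query length column missing — coverage incomputable")
    return [
        HomologyHit(
            query_id=row.qseqid,
            subject_id=row.sseqid,
            percent_identity=float(row.pident),
            alignment_length=int(row.length),
            evalue=float(row.evalue),
            query_length=int(row.qlen),
        )
        for row in df.itertuples()
    ]


def classify_duplication(
    self_hits: Iterable[HomologyHit],
    plantdb_hits: Iterable[HomologyHit],
    genes: Iterable[str],
    evalue_max: float = EVALUE_MAX,
    qcov_min_pct: float = QCOV_MIN_PCT,
) -> dict[str, GeneLabel]:
    """Label every gene duplicated / singleton / excluded_no_plant_homology.

    The within-set rule is directed: A's label depends only on A's own query
    rows; self-alignments (query == subject) never count.
    """
    genes = set(genes)

    candidate_dup: set[str] = set()
    for hit in self_hits:
        if hit.query_id not in genes:
            raise KeyError(f"within-set hit references unknown gene {hit.query_id!r}")
        if hit.query_id == hit.subject_id:
            continue
        if hit.evalue < evalue_max and hit.query_coverage_pct > qcov_min_pct:
            candidate_dup.add(hit.query_id)

    has_plant: set[str] = set()
    for hit in plantdb_hits:
        if hit.query_id not in genes:
            raise KeyError(f"plant-DB hit references unknown gene {hit.query_id!r}")
        if hit.evalue < evalue_max:
            has_plant.add(hit.query_id)

    labels: dict[str, GeneLabel] = {}
    for gene in genes:
        if gene not in has_plant:
            labels[gene] = GeneLabel.EXCLUDED
        elif gene in candidate_dup:
            labels[gene] = GeneLabel.DUPLICATED
        else:
            labels[gene] = GeneLabel.SINGLETON
    return labels


def compute_pd(labels: dict[str, GeneLabel]) -> float:
    """P_D = duplicated / (duplicated + singleton); excluded genes do not count."""
    n_dup = sum(1 for v in labels.values() if v is GeneLabel.DUPLICATED)
    n_single = sum(1 for v in labels.values() if v is GeneLabel.SINGLETON)
    if n_dup + n_single == 0:
        raise NoDataError("no genes with plant homology: P_D undefined")
    return n_dup / (n_dup + n_single)


def write_gene_classes(labels: dict[str, GeneLabel], path: str | Path) -> None:
    df = pd.DataFrame(
        sorted((g, v.value) for g, v in labels.items()), columns=["gene_id", "label"]
    )
    df.to_csv(path, sep="\t", index=False)


def read_gene_classes(path: str | Path) -> dict[str, GeneLabel]:
    df = pd.read_csv(path, sep="\t")
    return {row.gene_id: GeneLabel(row.label) for row in df.itertuples()}
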