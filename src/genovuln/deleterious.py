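"""Deleterious-variant load from PROVEAN and SIFT effect-score tables.

Amino-acid changes at nonsynonymous heterozygous SNVs are classed deleterious
when the PROVEAN score is <= -2.5 (boundary inclusive) or the SIFT score is
< 0.05 (strict).  Variants SIFT could not evaluate are dropped from both the
numerator and the denominator of the SIFT proportion; PROVEAN always scores.
The reference->alternate direction is scored: with two heterozygous alleles
the ancestral one is unknowable without outgroups, but a change is judged on
the magnitude of its predicted impact, which is direction-insensitive at the
|2.5| threshold.  Per-gene proportions are averaged (unweighted) into the
specimen value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .homology import NoDataError
from .variants import AnnotatedSNV, Effect, Zygosity

PROVEAN_THRESHOLD = -2.5
SIFT_THRESHOLD = 0.05

SCORE_COLUMNS = ["transcript_id", "pos_1based", "ref_aa", "alt_aa", "provean_score", "sift_score"]


@dataclass(frozen=True)
class EffectScore:
    """PROVEAN/SIFT scores for one amino-acid variant.

    ``pos_1based`` is the 1-based protein position (codon index + 1);
    ``sift_score`` is None when SIFT could not evaluate the variant.
    """

    transcript_id: str
    pos_1based: int
    ref_aa: str
    alt_aa: str
    provean_score: float
    sift_score: float | None

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.transcript_id, self.pos_1based, self.ref_aa, self.alt_aa)


def classify_provean(score: float, threshold: float = PROVEAN_THRESHOLD) -> str:
    return "deleterious" if score <= threshold else "neutral"


def classify_sift(score: float | None, threshold: float = SIFT_THRESHOLD) -> str:
    if score is None or (isinstance(score, float) and math.isnan(score)):
        return "unevaluated"
    return "deleterious" if score < threshold else "tolerated"


def read_scores(path: str | Path) -> list[EffectScore]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing score columns {missing}")
    out = []
    for row in df.itertuples():
        sift = None if pd.isna(row.sift_score) else float(row.sift_score)
        out.append(
            EffectScore(
                transcript_id=row.transcript_id,
                pos_1based=int(row.pos_1based),
                ref_aa=row.ref_aa,
                alt_aa=row.alt_aa,
                provean_score=float(row.provean_score),
                sift_score=sift,
            )
        )
    return out


def write_scores(scores: Iterable[EffectScore], path: str | Path) -> None:
    rows = [
        {
            "transcript_id": s.transcript_id,
            "pos_1based": s.pos_1based,
            "ref_aa": s.ref_aa,
            "alt_aa": s.alt_aa,
            "provean_score": s.provean_score,
            "sift_score": "" if s.sift_score is None else s.sift_score,
        }
        for s in scores
    ]
    pd.DataFrame(rows, columns=SCORE_COLUMNS).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class DeleteriousResult:
    per_gene: dict[str, float]
    specimen_mean: float
    n_genes: int
    n_variants_evaluated: int


def _variant_key(a: AnnotatedSNV) -> tuple[str, int, str, str]:
    return (a.transcript_id, a.codon_index + 1, a.ref_aa, a.alt_aa)


def deleterious_fraction(
    annotated: Iterable[AnnotatedSNV],
    scores: Iterable[EffectScore],
    method: str,
    gene_of_transcript: dict[str, str] | None = None,
    provean_threshold: float = PROVEAN_THRESHOLD,
    sift_threshold: float = SIFT_THRESHOLD,
) -> DeleteriousResult:
    """Per-gene deleterious proportion among evaluated nonsynonymous het SNVs.

    ``method`` is 'provean' or 'sift'.  Every score row must match an
    annotated nonsynonymous SNV (orphan rows are an error); unscored SNVs do
    not enter the denominator, matching score tables produced only for
    submitted variants.  Raises :class:`NoDataError` when no gene has an
    evaluated variant.
    """
    if method not in ("provean", "sift"):
        raise ValueError(f"unknown method {method!r}")

    scores = list(scores)
    nonsyn = {
        _variant_key(a): a
        for a in annotated
        if a.snv.zygosity is Zygosity.HET and a.effect in (Effect.MISSENSE, Effect.NONSENSE)
    }
    orphans = [s.key for s in scores if s.key not in nonsyn]
    if orphans:
        raise KeyError(
            f"{len(orphans)} score rows match no annotated nonsynonymous SNV, "
            f"first: {orphans[:3]}"
        )

    per_gene_counts: dict[str, list[int]] = {}
    n_eval = 0
    for s in scores:
        if method == "provean":
            call = classify_provean(s.provean_score, provean_threshold)
        else:
            call = classify_sift(s.sift_score, sift_threshold)
            if call == "unevaluated":
                continue
        gene = (
            gene_of_transcript[s.transcript_id]
            if gene_of_transcript is not None
            else s.transcript_id
        )
        dele, total = per_gene_counts.get(gene, (0, 0))
        per_gene_counts[gene] = [dele + (call == "deleterious"), total + 1]
        n_eval += 1

    per_gene = {g: d / t for g, (d, t) in per_gene_counts.items() if t > 0}
    if not per_gene:
        raise NoDataError(f"no evaluated nonsynonymous SNVs for method {method!r}")
    mean = sum(per_gene.values()) / len(per_gene)
    return DeleteriousResult(
        per_gene=per_gene,
        specimen_mean=mean,
        n_genes=len(per_gene),
        n_variants_evaluated=n_eval,
    )
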