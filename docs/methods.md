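# Methods

## Scope and data model

The package computes six genome-vulnerability indices per specimen from four
inputs: a de novo transcript assembly (FASTA with cluster/gene/isoform
structured IDs), variant calls against those transcripts (VCF), homology
tables (13-column BLAST tabular: the standard 12 columns plus query length),
and per-variant effect-score tables (PROVEAN and SIFT). Read mapping,
variant calling, homology searching and effect scoring themselves are
upstream tools; this package consumes their outputs. The unit of analysis
is the gene (cluster+gene fields of the transcript ID); all indices are
computed on the single longest isoform per gene.

## Coding regions

Gene identity is parsed from `<prefix>_c<cluster>_g<gene>_i<isoform>` IDs;
among a gene's isoforms the longest sequence wins, with length ties broken
toward the lexicographically smallest isoform ID so the choice is stable.
The reading frame is the longest stop-free codon stretch over all six frames
(both strands, three offsets). The rule is deliberately edge-tolerant: no
ATG requirement and no terminal-stop requirement, because assembled contigs
are routinely 5'- or 3'-incomplete. Ties go to the forward strand, then the
smallest start coordinate. ORFs shorter than 50 amino acids are discarded,
and so are their genes. Translation uses the standard genetic code; any
codon containing N translates to X, and SNVs falling in such codons are
"unassessable" and excluded from all counts rather than guessed.
Coordinates are 0-based half-open internally and 1-based in every emitted
TSV/VCF.

## Duplication classification and P_D

A gene is *candidate duplicated* when any within-transcriptome protein hit
(self-alignments ignored) satisfies E-value < 1e-4 **and** query coverage
> 30%, where coverage = 100·alignment_length/query_length on amino-acid
lengths; otherwise it is a candidate singleton. The rule is directed: a
gene's label depends only on its own query rows, never inferred from the
reciprocal direction. Candidates become duplicated/singleton only if the
gene also hits the plant protein database at E-value < 1e-4 (no coverage
condition for that search); genes without plant homology are excluded from
every downstream index. P_D = duplicated / (duplicated + singleton). All
thresholds are strict inequalities exactly as written.

## SNV filtering and effect classification

Only biallelic single-nucleotide records with RMS mapping quality strictly
greater than 30 are kept (MQ = 30 exactly is rejected); indels,
multi-allelic records and missing/half genotype calls are dropped and
counted in a per-run log. Heterozygosity is read solely from the genotype
field. Each SNV is mapped into its transcript's coding region
(strand-aware; alleles complemented on the minus strand), the alternate
allele substituted into the reference codon, and the translations compared:
synonymous (same residue), nonsense (alternate is a stop), otherwise
missense. Multiple SNVs in one codon are annotated independently against
the reference codon; phase is not modelled. Per transcript:
syn/kb = 1000·n_syn/CDS length, nonsyn fraction = (missense+nonsense)/all
coding het SNVs, nonsense fraction = nonsense/nonsynonymous.

The specimen value of each index is the unweighted mean over transcripts:
syn/kb over every retained transcript (zero-SNV transcripts included, since
absence of heterozygosity is signal), the two composition fractions only
over transcripts where they are defined. One denominator-population choice
deserves note: all indices, including syn/kb, are computed over the
plant-homologous gene universe, so that every index describes the same gene
set; restricting to that universe is required for the deleterious indices
anyway.

## Deleterious load at heterozygous sites

PROVEAN calls a variant deleterious at score ≤ −2.5 (boundary inclusive);
SIFT at score < 0.05 (strict), with SIFT-unevaluable variants removed from
numerator and denominator both — consequently PROVEAN denominators are
always at least SIFT denominators. Scores are taken for the
reference→alternate direction: with two heterozygous alleles the ancestral
state is unknowable without outgroups, but calls at these thresholds are
effectively direction-insensitive, so no polarization is attempted. The
proportion deleterious is computed per gene over its evaluated
nonsynonymous SNVs, and the specimen value is the unweighted mean over
genes with at least one evaluated variant. A dataset with no evaluated
variants yields an explicit no-data result, distinct from 0.

## Interspecies substitutions

Each species of a congeneric pair contributes an integrated reference: the
longest CDS per gene plus a heterozygosity mask holding every position with
a heterozygous genotype in the pooled VCF. The mask deliberately ignores
the MQ filter: any read-backed evidence of within-species polymorphism
disqualifies a site from being called a fixed difference. Orthologs are
reciprocal best protein hits with identity strictly > 80% in both
directions (ties broken by E-value, then identity·length). The two
proteins are globally aligned (BLOSUM62, gap open −10, extend −0.5) and the
alignment back-projected to codons; columns within two codons of any gap
are discarded as alignment-uncertain. A substitution site is a gap-free
codon column where the CDSs differ and no base of either codon is masked;
it is synonymous or nonsynonymous by comparing the encoded residues
(stop-containing or ambiguous columns are skipped). Site discovery is
symmetric under swapping the two species.

Deleterious-substitution proportions are computed per gene, separately with
each species as the score-table query. For PROVEAN the numerator is
score ≤ −2.5 and the default denominator is the nonsynonymous substitutions
with score < 0; this literal "negative scores" denominator is one of two
defensible readings of the procedure, so a switch
(`provean_denominator = negative_scores | all_nonsyn`) exposes the other.
For SIFT: numerator score < 0.05 over evaluated substitutions.

## Statistical layer

Species value = arithmetic mean of specimen values (a single specimen
passes through). Within each genus the full bipartite set of EIE×NE pairs
is compared — for the bundled study system that is 2+6+1+1 = 10 pairs.
Congeneric contrasts use a two-sided Welch (unequal-variance) t-test on the
pooled per-gene value distributions; the published analysis says only
"t tests", so Welch is the package's choice and Student's form is available
by flag. Cross-genus trends use the two-sided exact binomial (sign) test
with success probability 0.5 on the pair direction vector; tied pairs abort
with an error rather than being silently dropped. Two-sidedness is
confirmed by the published values themselves: 10/10 concordant pairs give
p = 2/1024 = 0.002 (one-sided would be 0.001) and 9/10 give 0.021 (not
0.011). No multiple-testing correction is applied, matching the published
analysis; reported tables round to 3 decimals while comparisons always use
unrounded values. The paralog-exclusion control reruns every index
restricted to candidate-singleton genes.

The bundled reference table (`genovuln.reference`) carries the published
per-specimen index values. Recomputing species averages from those printed
3-d.p. rows reproduces the published average rows to within one unit in the
third decimal (the published averages were taken over unrounded values);
the two single-specimen species reproduce exactly, and every pair direction
— hence every binomial p-value — is insensitive to this rounding.

## Synthetic-data generator

The generator emulates exactly the statistical structure the indices
measure, not the sequencing process: no reads, expression levels, assembly
errors or polyploid subgenomes.

* **Genes.** CDS lengths are normal around `mean_cds_len_bp` (sd 15%,
  floor 53 codons); codon content is uniform over the 61 sense codons, with
  ATG start and a random stop — composition targets are enforced by site
  selection, not codon bias. Each gene gets 1–3 isoforms (shorter ones are
  3' truncations); the 5' UTR is frame-aligned and ends in a stop codon so
  the ORF caller cannot extend upstream of the planted start, and every
  emitted gene is verified to ORF-call back to its planted coding region
  (resampled on the rare failure), which is what makes ledger comparisons
  exact.
* **Families.** Each gene is flagged duplicated with probability
  `duplicated_fraction`; flagged genes pair into two-member families (an odd
  leftover joins the previous family, a lone flagged gene is demoted)
  sharing a cluster ID and a 2%-diverged CDS copy. Homology tables are
  emitted from this family structure with full coverage and tiny E-values,
  and every gene receives a plant-database hit.
* **Variants.** Per gene the SNV count is binomial at `het_snv_rate` over
  coding positions (terminal stop excluded); each SNV draws its target
  class (nonsynonymous with `nonsyn_target_fraction`, nonsense given
  nonsynonymous with `nonsense_given_nonsyn`) and a matching site is found
  by rejection sampling with an exhaustive fallback. A `low_mq_fraction` of
  records get MQ ≤ 30 to exercise the filter. VCFv4.2, GT 0/1, MQ as INFO.
* **Scores.** Nonsynonymous variants that pass MQ receive a PROVEAN score
  uniform on (−8, −2.5] with probability `deleterious_fraction_provean`,
  else on (−2.4, 4); SIFT analogously on [0, 0.05) vs [0.05, 1], with a
  `sift_missing_rate` of rows left blank.
* **Species pairs.** An ortholog set is copied and per-site substituted at
  `interspecies_divergence` (never creating stops); the ledger records every
  substituted codon with its effect class. Pooled heterozygous SNVs are
  planted in both species, and a `masked_substitution_fraction` of
  substitution codons additionally receive a het call, so the
  het-exclusion rule is exercised; the ledger marks which sites end up
  masked. Per-direction score tables cover the scorable (nonsynonymous,
  unmasked) substitutions.

Determinism: every stream derives from `numpy.random.default_rng` seeded by
the config seed plus CRC32-hashed string labels, so identical configs give
byte-identical output files.

What passing synthetic tests does **not** show: robustness to assembly
chimerism and fragmentation, genotype-calling error, expression-dependent
coverage, real codon bias, or paralog collapse during assembly — on real
data those affect the indices in ways the generator does not model.

## Study conditions used in the experiments

Parameter recovery runs one 500-gene specimen (duplicated fraction 0.70,
het SNV rate 2×10⁻³/bp, nonsynonymous target 0.55, nonsense 0.04, PROVEAN
deleterious 0.35, SIFT 0.25) and checks each pipeline estimate (a) equals
the value recomputed from the truth ledger and (b) sits within 3 standard
errors of the configured target. The genus-contrast experiment simulates
ten congeneric pairs with three specimens of 300 genes per species under
`EIE_LIKE` vs `NE_LIKE` conditions (duplicated fraction 0.68 vs 0.78, het
rate 0.8 vs 1.6 ×10⁻³, nonsynonymous 0.62 vs 0.50, nonsense 0.06 vs 0.012,
PROVEAN 0.40 vs 0.28, SIFT 0.30 vs 0.18). These contrasts mirror the
direction and approximate magnitude of the published species averages, with
SNV densities scaled up so that a 300-gene transcriptome carries enough
variants for each index's direction to be resolved; the problem sizes keep
the whole validation suite under a minute. The substitution experiment
uses 150 genes at 2% divergence (~2,400 unmasked substitution sites); the
paralog-exclusion control plants a 4× SNV surplus on the duplicated half of
a 120-gene set.

## Numerical and degenerate-input conventions

Thresholds are exact and strict/inclusive as stated above; no epsilons are
applied to them. Undefined fractions (no coding SNVs, no nonsynonymous
SNVs, no evaluated scores, no non-excluded genes) propagate as NaN or
raise explicit no-data errors at aggregation boundaries — they are never
coerced to 0. Zero-variance t-test inputs with equal means report p = 1 by
convention. Score-table rows that match no annotated variant are an error
(orphans indicate a wiring bug), as are homology rows naming unknown genes
and VCF records on transcripts absent from the assembly.

## Known limitations

Per-variant effect scores are consumed, never computed, so score quality is
inherited from upstream tools. The ortholog step assumes a one-to-one
orthology induced by reciprocal best hits; in-paralogs created after the
split can shadow the true ortholog. The t-test layer pools per-gene values
across specimens rather than modelling specimen as a random effect. The
binomial layer treats the ten congeneric pairs as independent although
pairs sharing a species are not; this matches the published procedure and
is one reason the package also reports per-pair t-tests.
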