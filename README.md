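# genovuln

Genome-vulnerability indices for endangered plants, computed from de novo
RNA-seq transcriptome assemblies.

## The problem

Endangered island endemic (EIE) plants persist in small, isolated
populations where genetic drift outpaces purifying selection. The
expectation is that, relative to non-endangered (NE) widespread congeners,
their expressed genomes show (i) lower heterozygosity at putatively neutral
sites, (ii) a larger share of nonsynonymous — and especially
loss-of-function — variation, (iii) a heavier load of predicted-deleterious
amino-acid variants, both within individuals (heterozygous SNVs) and fixed
between species (homozygous substitutions), and (iv) a smaller proportion of
duplicated genes (*P*<sub>D</sub>), a correlate of environmental
adaptability. This package implements that comparison for transcriptome
data, for conservation genomicists who have assemblies, variant calls,
homology tables and variant-effect scores but no reference genome.

## The indices

Per specimen, on the longest isoform of each gene (ORF ≥ 50 aa, retained
only with plant-protein homology at *E* < 10⁻⁴):

| index | definition |
|---|---|
| syn/kb | mean over transcripts of heterozygous synonymous SNVs per kb of CDS |
| nonsyn fraction | mean over transcripts of nonsynonymous / all coding het SNVs |
| nonsense fraction | mean over transcripts of nonsense / nonsynonymous het SNVs |
| PROVEAN fraction | mean per-gene share of nonsynonymous SNVs with PROVEAN score ≤ −2.5 |
| SIFT fraction | same with SIFT score < 0.05 (unevaluable variants dropped) |
| *P*<sub>D</sub> | duplicated / (duplicated + singleton) genes, where duplicated means a within-transcriptome BLASTP hit at *E* < 10⁻⁴ and query coverage > 30% |

SNVs enter only with RMS mapping quality strictly > 30 and a biallelic
single-nucleotide record; heterozygosity comes from the genotype field.
Species values are specimen means. Within each genus every EIE species is
compared with every NE congener (t-tests on per-gene distributions), and the
direction vector over all congeneric pairs feeds a two-sided exact binomial
(sign) test against a fair coin.

Between a species pair, orthologs are reciprocal best protein hits at > 80%
identity (longest CDS per gene); species-specific homozygous substitutions
are codon columns of the protein-guided alignment where the sequences differ
and neither species has a heterozygous call; deleterious-substitution
proportions are computed reciprocally with each species as the PROVEAN/SIFT
query.

A synthetic-data generator (`genovuln.simulate`) emits FASTA/VCF/homology/
score inputs with controllable duplicated fraction, SNV density and
composition, deleterious fractions and interspecies divergence, plus a truth
ledger, so every stage is testable by parameter recovery.

## Worked example

Simulate one specimen and compute its indices:

```
$ genovuln simulate --outdir demo --seed 5 --species syn
$ genovuln indices --fasta demo/syn_sp1.fasta --vcf demo/syn_sp1.vcf \
    --self-hits demo/syn_sp1.self.tsv --plant-hits demo/syn_sp1.plant.tsv \
    --scores demo/syn_sp1.scores.tsv --out demo/out
{"pd": 0.745, "syn_per_kb": 0.195, "nonsyn_fraction": 0.577, "nonsense_fraction": 0.045, "provean_fraction": 0.345, "sift_fraction": 0.28}
```

Here 74.5% of retained genes have a within-set homolog, the specimen carries
0.195 heterozygous synonymous SNVs per kb of coding sequence, 57.7% of its
coding het SNVs change the protein, 4.5% of those introduce a stop, and
34.5% (PROVEAN) / 28.0% (SIFT) of scored amino-acid variants are predicted
deleterious.

The statistical layer over the bundled published index table (12 species,
four genera, 35 specimens) prints:

```
$ python analysis/01_reference_stats.py
            index expected_direction  n_pairs  n_concordant  p_two_sided
               pd          eie_lower       10             9        0.021
       syn_per_kb          eie_lower       10            10        0.002
  nonsyn_fraction         eie_higher       10            10        0.002
nonsense_fraction         eie_higher       10            10        0.002
 provean_fraction         eie_higher       10            10        0.002
    sift_fraction         eie_higher       10            10        0.002
```

i.e. every congeneric EIE–NE pair is concordant for five of the six indices
(sign test p = 0.002), and 9 of 10 for *P*<sub>D</sub> (p = 0.021).

The numbered scripts under `analysis/` run the full narrative: `01` the
published statistical layer, `02` an end-to-end simulated four-genus study,
`03` parameter recovery and the ten-genus-pair contrast, `04` the
interspecies substitution analysis, `05` the paralog-exclusion control.

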