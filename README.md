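# cishap

Haplotype-based analysis of rare variants on common pigmentation-trait
allele backgrounds at the *OCA2* locus.

## The problem

*OCA2* is the second most common locus for autosomal-recessive
oculocutaneous albinism (OCA type 2). Patients carry two rare variant
alleles — missense and nonsense SNVs, small indels, splice-region
variants, and a striking number of large structural variants — but those
rare alleles frequently sit *in cis* with common GWAS pigmentation
alleles that themselves reduce *OCA2* function: rs1800404-A (the
synonymous p.Ala355= allele, which promotes exon 10 skipping) and
rs12913832-G (the "blue-eye" enhancer allele, which lowers *OCA2*
transcription), each by roughly 20% per copy. Classifying rare variants
one at a time misses this combinatorial structure.

`cishap` provides the pieces of a haplotype-first analysis of such a
cohort, for genetics researchers and variant-curation pipelines:

* **Cohort model** — variants, biallelic proband records with
  multi-variant cis allele calls, SV junction/repeat annotation, and a
  packaged transcription of the study cohort table (106 probands,
  74 distinct variants).
* **Phasing** — cis/trans resolution of variant pairs by Mendelian
  segregation in trios (exhaustive transmission enumeration, no
  recombination within the locus) and by read-fragment co-observation.
* **Haplotype catalog** — maximal pairwise-cis member sets merged across
  probands, with each observation classified phase-validated /
  genotype-consistent / inconsistent, cohort enrichment, and haplotype
  frequencies from phased population panels.
* **Splice scoring** — weight-matrix (WMM) and first-order weight-array
  (WAM) splice-site scorers over 162 bp windows (80 bp each side of the
  GT/AG consensus dinucleotide), strand-aware window construction, the
  compound cis-impact rule and the strongest-site rule.
* **Saturation screen** — every single-base substitution across a
  window's flanks (3 × 159 = 477 per site), scored alone and in cis with
  an anchor allele, classified against the identity diagonal and the
  reference score.
* **Dosage-expression model** — multiplicative per-allele retention:
  `TPM = baseline · r^dosage · exp(ε)`; closed-form log-linear fit; the
  effective-expression calculus for multi-anchor haplotypes.
* **CNV calling** — exon-level copy number from SNP-array Log R Ratios
  against a control distribution.
* **Synthetic data** — seeded generators for every input (cohort +
  trios + fragments, phased panels, splice training sets and windows,
  expression and LRR tables) so the whole pipeline is testable offline.

## The core model

A haplotype is a set of variants on one chromosome. For a pair of sites
with trio genotypes, every parental transmission `(f, m)` with
`f + m = proband genotype` (no recombination) is enumerated; the pair is
**cis** iff every consistent transmission places both alternate alleles
on one transmitted chromosome.

Splice-site strength is a summed log-odds score
`S(x) = Σ_i log2 f_i(x_i) / q(x_i)` over a motif span (9-mer donor,
23-mer acceptor, or the full window); the compound cis impact of a rare
variant *v* with anchor *a* is `S(x + v + a) − S(x_ref)`, and for a
variant inside two windows only the site with the higher reference score
is reported.

Effective full-length expression of a haplotype with anchor retention
factors `r_k` is `Π_k r_k` — e.g. rs1800404-A (0.80) together with
rs12913832-G (0.80) leaves 0.64 of full-length transcript.

## Worked example

Cohort summary of the packaged table:

```
$ cishap cohort-stats
{
  "n_probands": 106,
  "n_distinct_variants": 74,
  "n_distinct_svs": 11,
  "sv_carriers": 41,
  "class_tally": {
    "cxsv": 2, "deep_intronic": 1, "frameshift_indel": 5,
    "inframe_indel": 4, "missense": 34, "nonsense": 8,
    "splice_region": 11, "sv_deletion": 6, "sv_duplication": 3
  },
  ...
}
```

106 probands carry 74 distinct *OCA2* alleles; 11 are large structural
variants and 41 probands (39%) carry at least one SV. The most frequent
alleles are c.1327G>A (37 chromosomes), the exon 7 deletion (29),
c.1465A>G (13), c.2228C>T (11) and the cis pair c.79G>A; c.1320G>C (8).

Effective expression of the two-common-anchor haplotype:

```
$ cishap effective --haplotype rs1800404,rs12913832
0.6400
```

i.e. a chromosome carrying both anchors produces ~64% of full-length
transcript before any rare-variant effect is considered.

Simulate a full scenario and fit the dosage model:

```
$ cishap simulate --seed 7 --out sim/
$ cishap dosage-fit --expr sim/expression.tsv
{
  "baseline": 96.49617380519055,
  "retention": 0.7418170119980169,
  "percent_reduction": 25.818298800198313,
  "se_retention": 0.01560106370221929
}
```

The generator plants a 27% per-allele reduction (retention 0.73); the
log-linear fit recovers it from 60 samples.

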