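# Methods

This note documents the models implemented in `cishap`, the parameters
that matter, the synthetic-data scenario the tests run against, and the
numerical conventions and open design choices.

## Cohort model

A `Variant` is identified by its normalized HGVS-c label where one
exists, otherwise by a normalized genomic/symbolic label. Normalization
collapses whitespace and unicode dashes, strips thousands separators
inside numeric offsets, and drops redundant deleted-base suffixes
(`c.1555delG` → `c.1555del`). The two complex structural variants (the
143 kb inverted-duplication with and without the accompanying 184 kb
deletion) are distinct identities (`cxsv_143kb_184kb_del`,
`cxsv_143kb_invdup`), because the cohort table distinguishes them.

A proband record holds two allele calls; each call is an ordered cis
list, so `c.79G>A; c.1320G>C` is one chromosome with two member
variants, and the distinct-allele tally counts members individually.
Homozygotes are represented as two identical calls and contribute two
allele counts.

Coordinates are 1-based inclusive internally. BED repeat intervals stay
half-open 0-based as read; SV junction endpoints are converted to
0-based points before the containment test, so an endpoint equal to a
BED `end` coordinate is deliberately *not* flagged. Rarity uses a strict
`MAF < 0.01` comparison; a missing MAF is reported as `unknown`, never
silently rare.

The packaged variant annotation table records real coordinates for the
structural variants (parsed from their genomic labels). The small
variants' genomic coordinates are synthetic placeholders derived
deterministically from the coding position (the locus is minus-strand,
so ascending coding position maps to descending genomic coordinate);
they preserve genomic order for catalog display but are not liftover
coordinates. Anchor-allele population frequencies not printed in the
source table (rs1800404, rs12913832, rs1800414) are approximate global
values chosen once; they satisfy the `anchor ⇒ MAF ≥ 0.01` invariant
and do not enter any reproduced statistic.

## Trio phasing

For a pair of sites, each parent may place on the transmitted
chromosome any allele compatible with its genotype (`0→{0}`, `1→{0,1}`,
`2→{1}`; a missing genotype is unconstrained). With no recombination
assumed inside the locus (a single-gene region), the set of consistent
configurations is all `(paternal, maternal)` two-site haplotypes whose
sum reproduces the proband's genotypes. The pair is **cis** if every
consistent configuration has some chromosome carrying both alternate
alleles, **trans** if none does, **ambiguous** if both occur, and a
**Mendelian error** if no configuration is consistent (which covers
de novo alleles: they are flagged, never guessed). Parental origin is
reported per variant only when identical across all consistent
configurations. Homozygosity at one site forces a cis call regardless
of parental genotypes, which is also applied as a genotype-only
deduction when no trio or fragment evidence exists.

## Fragment phasing

Fragments covering both sites are tabulated as (alt,alt), (alt,ref),
(ref,alt), (ref,ref). A cis call requires at least `min_support = 2`
double-alt fragments and a conflicting fraction (single-alt
observations among all alt-involving co-observations) of at most
`max_conflict = 1/3`; trans is symmetric and additionally requires both
single-alt configurations to be observed. The 1/3 tolerance means
supporting observations must outnumber conflicts at least two to one.
It is set well above the conflict rate implied by a realistic 2%
per-observation error (≈ 2·2e ≈ 8% of alt-involving observations),
because a tolerance near that noise floor would reject a large fraction
of genuinely cis pairs at 30× depth; with 1/3 the per-pair failure
probability at those error rates is ~10⁻⁵, while a 50/50 cis/trans
mixture still resolves to ambiguous. When trio and fragment evidence
are both resolved and disagree, the pair is flagged as a conflict
rather than averaged.

## Haplotype catalog

Per proband, cis-resolved pairs form a graph over carried variants;
every maximal clique of size ≥ 2 is a candidate haplotype, and identical
member sets merge across probands. Curated allele calls that already
assert a multi-variant cis list contribute their member sets directly.
Every proband is then classified against every emitted haplotype:
**phase-validated** (carries every member, all pairs cis),
**genotype-consistent** (carries every member, ≥ 1 pair unresolved),
**inconsistent** (≥ 1 pair resolved trans or conflict-flagged). Matching
is chromosome-level: a homozygote whose two calls each contain the
member set contributes two observations. Members are stored in
transcript order (descending genomic coordinate on this minus-strand
locus) and display names are protein-level (`p.[Gly27Arg;Ala355=;…]`)
with non-coding members keeping their ids. Truncating members 5′ of an
anchor remain in the stored member set; a display filter implements the
figure-style exclusion separately.

Cohort enrichment is `allele_count / (2·n_probands)` divided by a
caller-supplied reference MAF; the reference stratum is deliberately a
parameter because enrichment folds depend strongly on it. Panel
haplotype frequency is the fraction of 2N phased panel chromosomes
matching every required allele of a pattern, unconstrained elsewhere.

## Splice scoring

Windows are 80 bp on each side of the consensus dinucleotide
(L = 162 by default; configurable). Windows are stored in transcript
orientation with 1-based indices; construction from plus-strand genomic
sequence reverse-complements minus-strand loci and carries a coordinate
map, so the same genomic edit can be located in any window that covers
it.

Two scorers are provided behind one interface:

* **WMM** — per-position frequencies with Laplace pseudocount
  (`(n_b + pc/4)/(N + pc)`, default `pc = 1`) against a decoy-derived
  background composition (uniform when no decoys are given); score is
  the summed log2 odds. Score *differences* depend only on edited
  positions, which the screen exploits and the tests verify against
  full rescoring.
* **WAM** — the first position uses the marginal; later positions use
  frequencies conditioned on the preceding base against a first-order
  decoy background, capturing adjacent-position dependence (and hence
  non-additive compound impacts for adjacent edits).

Motif spans are (3 exonic, 6 intronic) for donors — a 9-mer including
the GT — and (3, 20) for acceptors — a 23-mer including the AG — or the
full window. The trained external classifier whose windowed scores the
study reports is not reimplemented and its absolute score values and
above-diagonal counts are not reproduction targets; the scorers here
are reference implementations trained on synthetic or user-supplied
site sets.

The compound impact of a variant with an anchor is
`(S(v) − S(ref), S(v + a) − S(ref))`. When a variant maps into more
than one window, only the site whose *reference* sequence scores higher
is reported; an exact tie breaks deterministically acceptor-before-donor
and is logged. The reference-score criterion is this package's
documented interpretation of "strongest site"; the source method does
not state one.

## Saturation screen

All three alternative bases at every window position except the two
dinucleotide positions and the anchor position: `3·(L − 2 − 1) = 477`
records for L = 162. Records at the anchor position are excluded
entirely. Each record stores score alone, score in cis with the anchor,
and the reference score; classification uses strict inequalities, so a
point exactly on the diagonal is in neither diagonal class. The screen
is deterministic: regeneration is bit-identical. (The window has 160
flanking positions; the printed description of the analogous experiment
says "80 positions" while its variant count requires all 160 — the
arithmetic, 477, is followed here.)

## Dosage-expression model

`TPM = baseline · r^dosage · exp(ε)`, `ε ~ N(0, σ²)` on the log scale.
The multiplicative form is chosen over an additive one because the
modelled effects are proportional per-allele reductions; an additive
fit is available behind a flag for sensitivity checks. The fit is a
closed-form simple regression of log TPM on dosage
(`retention = exp(slope)`, standard errors by the delta method); a
group-means variant (regression on per-dosage mean log TPM) is provided
because it is not stated whether the source estimate was per-sample or
per-group — both agree exactly on noiseless data. Zero TPM is a hard
error directing the caller to apply a pseudo-TPM offset.

Default retention factors: 0.80 per rs1800404-A and 0.80 per
rs12913832-G for the effective-expression calculus (two anchors ⇒
0.64), while the expression-fit simulation truth is 0.73 (a 27%
per-allele reduction). Both are configuration values, never hard-coded
in computation.

## CNV calling

Per region, `z = (mean sample LRR − mean of control-sample means) / sd
of control-sample means`. Copy number 2 when `z > −3`; otherwise 1 when
the sample mean exceeds the homozygous floor of −1.5 LRR and 0 at or
below it. The source method states neither control-set size nor
thresholds; the defaults follow standard Illumina LRR expectations
(CN1 ≈ −0.45, CN0 ≤ −1.5) and are configurable. Identical control means
are a hard error. The rule is monotone: lowering every sample probe
never raises the call.

## Synthetic scenario ("oca2-like")

The default scenario fixes the study conditions the tests run under:

* **Haplotype pool** — six recurring multi-variant haplotypes over the
  five GWAS anchors and packaged rare variants, echoing the catalog's
  recurring haplotypes (e.g. `rs1800404 + c.1327G>A` at 0.22,
  `c.79G>A + rs1800404 + c.1320G>C` at 0.10, `rs1800401 + exon7_del` at
  0.18, `c.79G>A + exon14_del` at 0.08, the two-common-anchor haplotype
  at 0.14 — its reported panel frequency — and
  `rs1800407 + c.1239+5G>C` at 0.08); the remainder is the reference
  haplotype. Chromosomes are drawn i.i.d.; there is no LD or coalescent
  structure, so tests exercise estimator correctness, not
  population-genetic realism.
* **Cohort** — 60 probands by default; parents are built backwards from
  the proband's chromosomes so Mendelian transmission is exact;
  fragments co-cover each carried variant pair at depth 30 with 2%
  per-observation error (0 in the error-free recovery tests).
* **Splice** — consensus-peaked donor 9-mer and acceptor 23-mer
  frequency tables; full-window training sets add a mild exonic
  composition signal so window-wide scorers assign small non-zero
  weights outside the core motifs. The window pair is laid out with a
  50 bp exon, shorter than the 80 bp flank, so the two 162 bp windows
  overlap across the exon and a single exonic anchor falls inside both
  — the geometry that gives 477 enumerated variants per site. The
  segment is placed on the minus strand to exercise reverse-complement
  construction.
* **Expression** — 20 samples per dosage 0/1/2, baseline 100 TPM,
  retention 0.73, log-noise SD 0.15.
* **LRR** — shifts 0 / −0.45 / −2.0 for CN 2/1/0, probe SD 0.15,
  4 probes per region, 20 control samples.
* **Determinism** — every generator draws from
  `default_rng([seed, stream_constant])` with a fixed per-generator
  constant, so outputs are pure functions of the configuration and
  adding a generator never perturbs another's stream.

What passing tests show — and do not show: the generators reproduce the
statistical structure the estimators assume (exact trios, independent
fragment errors, log-normal expression noise, Gaussian probe noise).
Real data add genotyping error, related individuals, LD between
anchors, batch effects and mappability artifacts that these tests do
not cover.

## Problem sizes

The test suite and the acceptance script use the sizes above: 200 seeds
for the Monte-Carlo recovery checks (dosage fit, panel frequency,
fragment phasing), 500 planted samples for CNV accuracy, panels of
2504 individuals, training sets of 400–800 sites. These match the
documented study conditions where stated and are otherwise the
package's chosen defaults.

## Known limitations

* No statistical population phasing (no EM/HMM imputation): phase comes
  only from trios, fragments, genotype-forced deductions and curated
  cis assertions, as in the modelled analysis.
* HGVS handling covers the label patterns present in the packaged
  table; it is not a general HGVS parser and performs no liftover.
* The enrichment fold depends on the caller-supplied reference MAF; no
  stratified reference populations are bundled.
* Small-variant genomic coordinates in the packaged annotation table
  are order-preserving placeholders (see above).
* CNV calling is per-region only; no segmentation or B-allele-frequency
  modelling.
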