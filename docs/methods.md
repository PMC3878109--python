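# Methods

## Model and procedure

The package analyses allele-specific expression (ASE) in F1 hybrids of
inbred (fully homozygous) parents. Because the parents are inbred, every
discriminating SNP has the two parents as opposite homozygotes, the F1 is
heterozygous at all of them, and read-backed allele assignment requires no
phasing: a read carrying the maternal parent's allele at a gene-body SNP is
evidence for maternal-allele transcription. Per gene, maternal and paternal
assigned reads are summed over all SNPs in the gene body (weighting SNPs by
their coverage; per-SNP direction conflicts are flagged as `discordant`, not
resolved), giving counts (M, P) on which all classification operates.

Classification is rule-based, not model-based. With defaults: genes with
M + P < 10 are *unclassified*; genes whose minor allele has 0 reads are
*monoallelic*; genes with major/minor > 2 are *preferential*; the rest are
*biallelic*. A ratio of exactly 2 falls to biallelic — "more than two-fold"
is read strictly, and the complementary "less than two-fold" class absorbs
the boundary conservatively. Zero denominators are replaced by 0.001 before
ratio computation, the same substitution used for fold changes against
silent genes. These rules are deliberately simple threshold predicates;
their correctness is checked exhaustively against a literal brute-force
restatement for every (M, P) with M + P ≤ 200.

Reciprocal crosses (A×B and B×A) disambiguate the cause of allelic bias.
For each gene biased (monoallelic or preferential) in both orientations, the
call is *genotype-dependent* when the favored allele's parental genotype is
the same in both (the cis-regulation signature), *parent-of-origin* when the
favored role (maternal/paternal) is the same while the genotype flips
(imprinting-like), *inconsistent* otherwise, and *untestable* when either
orientation is biallelic or unclassified.

Upstream, genotypes at candidate sites are called by a per-base Bayesian
model: each observed base contributes likelihood (1 − e) if it matches a
genotype allele and e/3 otherwise, with e its Phred error probability;
heterozygotes emit each allele with probability 1/2; the prior over
{RR, RA, AA} is uniform (the original sequencing pipeline's
platform-calibrated prior is not recoverable, and with ≥ 4 supporting reads
the likelihood dominates). The site quality used by the filters is the
Phred-scaled posterior error of the best genotype. Six reliability filters
then apply: quality ≥ 20; candidates ≥ 5 bp apart (both members of a closer
pair are dropped — the conservative reading, since no rule selects a
survivor); ≥ 4 supporting reads; depth < 10,000; > 5 bp from an intron–exon
junction; flanking copy number < 4 (accepted as a precomputed column;
estimating copy number is out of scope). Depth and copy bounds are strict
and the junction bound exclusive, as literally worded.

Expression is RPKM = 10⁹ · reads / (library size × gene length). The
differential-expression p-value is the Audic–Claverie two-library exact
test: conditional on x reads in library 1, the count y in library 2 follows
a negative binomial with r = x + 1 and success probability n₁/(n₁ + n₂);
the two-sided p doubles the smaller tail. The citation trail behind the
original analysis names no formula, so this test — the standard one for
two-library count comparisons of that era — is used and is swappable.
Benjamini–Hochberg controls the FDR across genes; a DEG needs fold > 2
(strict) and FDR < 0.05. Fold changes are computed on RPKM, the test on raw
counts, each quantity on its natural scale. Parental divergence classes:
I (< 2-fold), II (2–10-fold, both boundaries inclusive), III (> 10-fold),
IV (expressed in exactly one parent); "expressed" defaults to ≥ 1 read
(RPKM > 0) and is configurable. Genes silent in both parents are excluded.

Mid-parent heterosis is MPH = 100 · (mean(F1) − MP) / MP with
MP = (mean(P1) + mean(P2))/2, the conventional mid-parent formula. The
non-additive expression fraction tests each gene's F1 counts against a
mid-parent pseudo-sample (each parent's counts scaled to the F1 library
size, averaged, rounded) using the same DEG machinery. Because counts carry
only relative abundance, a globally uniform fold change is invisible to
this (or any count-based) test — the composition effect; the procedure
detects genes deviating from mid-parent *relative to the rest of the
transcriptome*, which is what a non-additivity fraction can mean for
RNA-seq.

The cis diagnostic correlates log₂(parental RPKM ratio) with
log₂(M/P) per gene (Pearson), zero sides substituted by 0.001. Pure cis
regulation makes the two equal up to counting noise (r → 1); pure trans
makes the allelic ratio 0 independent of the parental ratio (r → 0). The
correlation is reported for all analyzable genes and for the ASE-only
subset, and for the DEG-count-vs-MPH correlation across crosses the small-n
caveat (three crosses) is explicit: the p-value is descriptive.

## Synthetic data: what it emulates, and what it does not

The generator produces, from one seed: a random reference with tandem
non-overlapping gene models (1-based closed GFF3 coordinates, lengths
uniform in 500–3000 bp); Poisson(4)-distributed gene-body SNPs whose
per-parent alleles are independent fair coin flips (so any cross pair
discriminates ~half the sites, mirroring per-pair SNP sets); parental
expression log-normal on the RPKM scale (log₂ mean 4, sd 2); and per-gene
regulatory labels — *parent-silent* (3%, zero expression in one random
parent, cis behavior in the F1), *genotype-dependent monoallelic* (2%, only
the source parent's allele expressed in both reciprocal orientations),
*cis* (40% of the remainder, F1 allelic fraction = maternal/(maternal +
paternal) parental expression), *trans* (25%, allelic fraction 1/2 despite
parental divergence), and *neutral*. These default proportions reproduce the
observed rice-hybrid regime (≈ 3.7% monoallelic, ≈ 24% preferential, ≈ 72%
biallelic, ASE ≈ 27% of analyzable genes, cis correlation ≈ 0.73) at the
default depth. F1 informative depth per gene is Poisson(50) split uniformly
across the cross's discriminating SNPs; maternal counts are binomial, or
beta-binomial with intra-class correlation `overdispersion` (default 0 — an
optional realism knob, not part of the emulated design). Per-sample gene
read counts are Poisson around the RPKM-implied rate at a 5·10⁶-read
library. F1 total expression is additive (mid-parent) except for an
optional non-additive subset (`frac_nonadditive`, default 0, deviating by
`nonadditive_fold`). Phenotypes are Gaussian replicates (sd 0.5 g, 30
replicates) around fixed parental fresh-mass means with the F1 mean at
(1 + MPH/100) × mid-parent; negative draws are resampled. All draws come
from sub-streams keyed by (purpose, sample, gene), so one seed reproduces
every file byte-for-byte and adding a cross perturbs nothing else.

Deliberately not emulated: read sequences, alignment and mapping bias (the
analysis consumes allele counts, and truth alignment replaces the aligner);
sequencing error in allele assignment (available only as the spike-in path
in the base-resolved counter); genomic sequence realism (repeats, paralogs
— the copy-number filter column is synthetic); library-preparation
overdispersion between biological replicates (single library per sample);
linkage between SNPs beyond shared gene membership; and any coupling
between expression divergence and phenotype. Passing recovery tests
therefore demonstrates the correctness of the counting/classification
machinery under the stated statistical model, not robustness to alignment
artifacts or biological confounders in real data.

A gene whose genotype-dependent source parent is not in a given cross
behaves neutrally there (fraction 1/2); the pattern is defined only for
crosses carrying the source genotype. Genes silent in both parents of a
cross emit no reads and no defined allelic fraction.

## Numerical and design choices

* Tie-breaks: allelic ratio exactly 2 → biallelic; divergence ratio exactly
  2 or 10 → class II; fold exactly 2 → not a DEG. M = P ties have no
  favored allele.
* Degenerate inputs: zero-depth pileup → no-call; M + P = 0 → error (no
  transcripts to classify); mid-parent mass 0 → NaN MPH; < 3 points →
  NaN correlation; empty gene set → empty tables with headers.
* The genotype posterior caps site quality at Phred 1000; posteriors are
  normalized in log space.
* Worked-example inputs (per-cross monoallelic counts and class III/IV
  percentages from the published rice study) ship as data in
  `hybase.reference_data`; the package recomputes their pooled total
  (143 + 129 + 141 = 413), sampling percentage (134/413 = 32.4%),
  validation percentage (123/134 = 91.8%) and class averages (51.6%,
  30.2%) at reporting precision (one decimal), as a check of the summary
  conventions.
* Gene-level aggregation sums allele counts across SNPs rather than
  averaging per-SNP fractions, weighting evidence by coverage; in
  real-pileup mode a read spanning two SNPs is counted once per SNP it
  covers (a known double-count caveat; synthetic mode emits per-SNP counts
  directly).
* The "≥ 10 reads" analyzability rule applies to the per-gene sum of
  informative reads, not per SNP.
* Pipeline outputs are written atomically (temp file + rename; bundles via
  staged directory rename), and both per-cross and pooled statistics are
  always emitted, since pooled-vs-averaged reporting of ASE→DEG shares is a
  known ambiguity in this analysis style.

## Problem sizes

Default runs use 2,000 genes and six crosses (~15 s); the acceptance script
uses 2,000 genes for recovery, 1,000 for the cis-only complementation
check, an exhaustive 20,301-case classifier grid, 101 filter candidate
sets, and 200 phenotype replicates — all chosen so the full suite completes
in well under a minute while keeping multinomial/binomial sampling error
small relative to the tolerances tested.

## Known limitations

Rule-based ASE classification has no explicit error model: at depth ~50 a
truly balanced gene is occasionally preferential by chance and a truly
monoallelic call can be diluted by a single stray read (the
`mono_max_minor_reads` knob exists for sequencing-error tolerance but
defaults to 0). The Audic–Claverie test assumes Poisson counts and
understates biological replicate variance; with single libraries per
sample, as here, that is the information available. The n = 3 cross-level
correlation between DEG counts and heterosis is descriptive. The
non-additive fraction is relative-abundance-based (see composition effect
above). Multi-allelic SNPs, indels and isoform-level ASE are out of scope.
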