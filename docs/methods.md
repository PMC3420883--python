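# Methods

This note documents the models, estimators, numerical choices and
limitations behind `tas2rpop`, in the spirit of a statistical-methods
appendix. Everything stated here is computed by the test suite or the
analysis drivers; nothing is asserted from memory.

## Data model and conventions

The unit of observation is a phased chromosome: one haploid coding-sequence
haplotype per sampled chromosome per gene. CDS coordinates are 1-based with
the A of the annotated ATG start codon as position 1. Alignments use the
alphabet {A, C, G, T, N, -}; `N` is treated exactly like a gap for
statistics (complete deletion, below) because quality-filtered consensus
sequences leave its interpretation open. A chromosome flagged as a
whole-gene deletion for gene *g* is absent from *g*'s alignment; the flag
(not the sequence) carries the copy-number information, and such
chromosomes are excluded from every per-gene denominator.

Derived-allele polarity is "non-reference": the reference haplotype (an
external reference or a designated chromosome) defines the ancestral state.
This approximates network-based polarity estimation; reports record the
convention.

## Diversity statistics

All distances are uncorrected proportions. No Jukes–Cantor correction is
applied: within- and between-subspecies distances here are of order 10⁻³,
where the correction is far below reporting precision.

* π — mean pairwise difference per site within a population, computed from
  per-column allele counts (algebraically identical to the all-pairs
  Hamming mean, which the tests verify by brute force).
* Complete deletion: any column containing `-` or `N` is dropped before a
  statistic is computed, per analysis unit — per gene and population for π;
  across the union of both populations for d_XY and F_ST; codon-wise
  (together with the start and terminal stop codons) for π_S/π_N.
* π_S, π_N — Nei–Gojobori: per codon and position, the synonymous site
  fraction is the share of the 3 possible substitutions preserving the
  amino acid (changes to stop codons count as nonsynonymous); pairwise
  codon differences average over all mutational pathways, excluding
  pathways through stop codons unless every pathway is blocked. Site counts
  are averaged over all haplotypes compared. Pathway and site computations
  are memoised; pairwise sums collapse identical haplotypes with
  multiplicities and visit only polymorphic codons.
* d_XY — mean per-site difference over all between-population pairs.
* Per-site F_ST — Hudson–Slatkin–Maddison 1 − H_w/H_b with unbiased
  within-population heterozygosity 2k(n−k)/(n(n−1)) and the sample-size-
  weighted mean for H_w. Sites with H_b = 0 are NA, never 0. The estimator
  attains 1 exactly iff both samples are monomorphic for different alleles;
  that fixed-difference value is the only estimator-independent published
  anchor and is used as such.
* Concatenated class statistics drop chromosomes deletion-flagged for any
  member gene, keeping the alignment rectangular; π of a concatenation then
  equals the length-weighted mean of per-gene π over gap-free sites
  (verified as an exact identity in the tests).

Reports print diversity values ×100 with a scale column; all internal
computation and all tests use raw proportions.

## Functional-status classification

A haplotype is a segregating pseudogene if any of: (i) no ATG at positions
1–3 and no in-frame ATG at 4–6 (the alternative-start rescue keeps such
alleles functional); (ii) an internal stop codon before the terminal codon,
read in the frame of the realized start; (iii) total CDS length ≢ 0 mod 3
(frameshift). Whole-gene deletions are a separate non-functional mechanism.
Loss of the terminal stop codon is catalogued as its own variant class but
does not by itself mark a haplotype non-functional (a run-on product may
retain function, and no such published allele forced a decision).

Protein-level haplotype classes key on the predicted translation for
functional haplotypes; pseudogene classes key on a lesion signature
(frameshift remainder, missing start, first premature-stop codon index)
plus the translated-through product, so independent nonsense alleles stay
distinct classes even when their truncated products coincide.

Variant effects are classified on the reference reading frame, with
loss_of_start and gain_of_stop taking precedence over (non)synonymous;
multi-base substitutions within one codon of one haplotype are classified
by direct translation of the carrier codon. Indels are left-aligned and
reported at the first affected CDS position.

## Coalescent null for Tajima's D

D = (k̄ − S/a₁) / √(e₁S + e₂S(S−1)) with the standard constants. D is NA
when S = 0 and also when n < 4: for n = 2 and n = 3 the variance constants
c₁ and c₂ vanish identically, so the statistic is undefined (the
implementation and the brute-force oracle agree on this).

The null distribution is simulated, vectorised across replicates, as:
Kingman genealogies (with j lineages, waiting time ~ Exp(j(j−1)/2) in
units of 2N generations; uniformly random pair merges), branch lengths
accumulated by descendant class; mutations per class ~ Poisson(θ̂/2 ×
class length) with θ̂ = S_obs/a₁; D recomputed from the implied
site-frequency configuration. Conditioning on θ̂ with Poisson mutations is
the default; a fixed-S mode exists for sensitivity analysis. Replicates
with S = 0 keep an undefined D and remain in the denominator of the tail
fractions as non-exceedances (conservative). The two-sided p-value is
2·min(lower, upper) capped at 1 and floored at 1/replicates with a flag.
The simulator is cross-checked against msprime genealogies in the test
suite (matching mean and spread of the null D), its per-class branch
lengths against the E[L_i] = 2/i expectation, and the whole test attains
a type-I error of ≈0.045 at α = 0.05 over 500 synthetic neutral loci.

## Class-level selection tests

π_N/π_S uses a two-sided Fisher exact test on the 2×2 table
[rounded mean nonsynonymous differences, rounded mean synonymous
differences] vs [nonsynonymous sites − differences, synonymous sites −
differences]. The published analyses cite this contrast without printing
the table; rounding mean pairwise counts to integers is this package's
stated construction and is recorded in the output metadata. If rounding
ever produces a negative cell (saturated divergence), no test is run.

The D-distribution comparison uses a two-sided Wilcoxon rank-sum test
(exact enumeration when the combined sample is ≤ 20 without ties, normal
approximation with tie correction otherwise), with NA D values removed
listwise.

## Haplotype-sharing null

Sampling is multinomial from the per-gene metapopulation frequency vector —
frequencies, not a finite urn — because the null is "no differentiation
given the observed haplotype pool". Two pooling modes are provided:
`mean_of_frequencies` (default; unweighted average of the two populations'
frequency vectors) and `pooled_counts` (combined counts over combined
chromosomes); the phrase "mean frequencies for the total metapopulation"
admits both readings, so the drivers report both. Every observed class
participates, including singletons and whole-gene-deletion classes. The
tail probability is read from a Gaussian fitted to the replicate totals so
that values below Monte Carlo resolution remain reportable; the empirical
fraction is emitted alongside. Under panmictic synthetic data the observed
total falls inside the null 95% interval in ≥ 90% of datasets; under the
study-default divergence the lower-tail probability is ≪ 10⁻⁴.

## Gene-conversion tract detection

An informative site for candidate haplotype h requires: the donor-locus
consensus differs from the recipient consensus (majority over the other
recipient haplotypes); h carries the donor state; and that state is a
strict minority among the other recipients. The minority condition (rather
than full absence) lets co-carriers of one conversion event corroborate
rather than mask each other — the catalogued tracts have two carriers —
while still excluding shared ancestral polymorphism. Tracts are maximal
runs of consecutive informative sites with no intervening discordant
diagnostic site, reported at the outermost informative sites (true
endpoints between diagnostic sites are unidentifiable), and require
min_support = 2 informative sites by default to suppress single-site
homoplasy. Donor consensus is the column majority with ties broken toward
the donor reference. Paralogs must share a coordinate frame (equal-length
CDS, true for the receptor-cluster paralogs); unequal lengths require a
supplied pairwise alignment — no internal aligner is implemented.

## Synthetic-data generator

The generator emulates the survey design: 28 coding loci of 876–1002 bp
(19 "old" + 9 "human cluster"), populations of 92 and 20 phased
chromosomes, θ = 0.0015 per site (giving per-gene π of order 0.1%, the
magnitude seen in receptor resequencing at this depth), and a lesion set
covering every catalogued class. Design choices:

* Background variation per gene is one neutral Kingman coalescent sample of
  all chromosomes jointly, with infinite-sites mutations on finite sequence
  (positions resampled on collision). Background and divergence mutations
  are constrained never to create or destroy start/stop codons, so the
  truth record is the exhaustive list of non-functional lesions; this
  constraint does not touch the site-frequency spectrum, so neutrality-test
  calibration is unaffected.
* Structure: each population additionally receives
  Poisson(divergence_scale × θ_locus) private substitutions, each at a
  uniform(0,1] frequency materialized as an exact carrier count.
  divergence_scale = 0 is exact panmixia; 0.5 (default) yields ~70%
  subspecies-private protein classes and a continuous per-site F_ST
  spectrum, comparable to the study's observations. This is a
  phenomenological two-parameter stand-in, not a fitted demographic model:
  no migration, no within-population substructure, no growth.
* Lesion frequencies are materialized as ⌊f·n⌉ carrier chromosomes, never
  Bernoulli draws, so truth frequencies are exact and tests can assert
  equality.
* Paralog groups share one ancestral ORF diverged by ~4% per site, enough
  that a 73-bp tract typically contains ≥ 2 diagnostic sites; tract-recall
  guarantees are conditional on ≥ 2 diagnostic sites inside the injected
  interval, since tracts without internal diagnostic sites are
  information-theoretically undetectable.
* One named random substream per gene and per concern (keyed by
  CRC32-label under the global seed) makes datasets extensible: adding a
  gene or toggling a pipeline stage never perturbs other streams.
* Insertion lesions add alignment columns; they are applied after all
  CDS-coordinate lesions of the same gene, and the stored per-gene
  reference gains matching gap columns. Combining an insertion and a
  conversion tract on the same gene is not supported.

What passing tests on this generator do *not* show: behaviour under real
demography (bottlenecks, migration), recombination within genes, recurrent
mutation, sequencing or phasing error, or alignment ambiguity — real-data
runs should treat those as open validation questions.

The non-coding reference loci (26 loci, ~861 bp, same populations, same θ
and divergence) supply the empirical F_ST null and the non-coding D
distribution. Under the default divergence their F_ST 95th percentile is
≈ 0.76; the published 0.6/5% point is a property of the real reference
panel, not a constraint the generator reproduces.

## Problem sizes in the shipped tests

The test suite runs the sharing-coverage check on 20 panmictic datasets at
full study size with 1,000-replicate nulls, the type-I calibration on 500
neutral loci with 10,000-replicate nulls cached by S, tract recall on 40
random injections, and oracle equivalence on alignments of n ≤ 6 and ≤ 30
codons; these sizes keep the full suite under half a minute while leaving
every estimate's Monte Carlo error well inside the asserted bounds. The
analysis drivers default to the full 10,000 replicates for both nulls.

## Known limitations

* The per-site F_ST estimator family differs across published software;
  only the fixed-difference value 1 is estimator-independent, and no
  attempt is made to match other printed per-SNV values exactly.
* The Fisher-table construction for π_N/π_S and the informative-site
  criteria for conversion tracts are this package's explicit
  interpretations of under-specified published procedures; both are
  recorded in output metadata and documented above.
* The sharing null treats genes as independent (no linkage between tandem
  paralogs) and conditions on observed class frequencies, ignoring their
  sampling error.
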