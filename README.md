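# tas2rpop

Population-genetic analysis of bitter-taste-receptor (*TAS2R*) haplotype
diversification between chimpanzee subspecies.

Chimpanzee subspecies differ in which bitter plants they eat, and bitter
perception is mediated by the ~28-member TAS2R receptor family. Given phased
coding-sequence haplotypes of every *TAS2R* from western (*P. t. verus*) and
eastern (*P. t. schweinfurthii*) chimpanzees, this package asks: how much of
the haplotype repertoire is subspecies-specific, is that specificity
explainable by sampling alone, and what forms of natural selection —
balancing, purifying, or none — shaped each receptor class (the recently
duplicated "human cluster" on chromosome 12 versus the phylogenetically old
receptors)?

The package implements the full analysis as a reusable library plus numbered
analysis drivers, and ships a synthetic-data generator that emulates the
survey design (92 + 20 phased chromosomes over 28 coding loci, segregating
pseudogenes, whole-gene deletions, paralog gene conversion) so every stage
is testable end to end without any external download.

## What it computes

**Variant catalogue and functional status.** Variants are called against a
reference haplotype and classified as synonymous, nonsynonymous, loss of
start codon, gain of stop codon, loss of stop codon, or indel. A haplotype
is a segregating pseudogene if it lost the ATG at positions 1–3 (with no
rescuing in-frame ATG at 4–6), gained a premature stop, or carries a
frameshift (net indel length ≢ 0 mod 3); chromosomes lacking the whole gene
(CNV, no amplicon) form their own non-functional class.

**Diversity and differentiation.** Within-subspecies nucleotide diversity
π (mean pairwise differences per site, gap/N columns removed by complete
deletion), synonymous and nonsynonymous diversity π_S and π_N with
Nei–Gojobori site counting and mutational-pathway averaging, between-
subspecies divergence d_XY, and per-SNV F_ST in the Hudson–Slatkin–Maddison
form

F_ST = 1 − H_w / H_b,  H_w = Σ n_i·2k_i(n_i−k_i)/(n_i(n_i−1)) / Σ n_i,
H_b = (k_A(n_B−k_B) + k_B(n_A−k_A)) / (n_A n_B),

which equals 1 exactly iff both samples are internally monomorphic for
different alleles. Coding SNVs are screened against the empirical F_ST
distribution of putatively neutral non-coding loci.

**Neutrality tests.** Tajima's D per gene and subspecies, with a two-sided
p-value from 10,000 neutral-coalescent replicates (no recombination,
Poisson mutations at rate θ̂/2 per unit branch length, θ̂ = S/a₁ by
Watterson); class-level π_N/π_S with a two-sided Fisher exact test; and a
two-sided Wilcoxon rank-sum comparison of the per-gene D distribution
against the non-coding reference loci.

**Haplotype-sharing null.** The bespoke Monte Carlo null for the total
number of haplotype classes shared between the two subspecies: assuming no
differentiation, each replicate redraws 92 and 20 chromosomes per gene by
multinomial sampling from the observed metapopulation class frequencies;
the observed shared total is placed in the lower tail of a Gaussian fitted
to the replicate totals.

**Gene-conversion tracts.** Betrán-style detection of ectopic conversion
between paralogs: maximal runs of ≥ 2 consecutive donor-diagnostic sites on
a recipient haplotype, with tract endpoints at the outermost informative
sites.

## Worked example

Generate the study-like synthetic dataset and run the analyses:

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_catalog.py
python analysis/03_diversity.py
python analysis/04_neutrality.py --seed 1
python analysis/05_sharing_null.py --seed 1
python analysis/06_conversion.py
```

Output (seed 1, abridged):

```
wrote 28 gene alignments (26118 aligned bp), 26 reference loci, 13 injected lesions -> results/data
  protein    (all): 197/278 unique to one subspecies, 81 shared
old            concatenated (17667 bp): pi_w=0.181 pi_e=0.181 d_xy=0.234 (x100)
human_cluster  concatenated (8451 bp): pi_w=0.126 pi_e=0.166 d_xy=0.184 (x100)
257 coding SNVs vs 236 neutral reference SNVs: 11 F_ST outliers at the 5% empirical tail (max F_ST=1.000)
  eastern  human_cluster  pi_N/pi_S=2.174 (Fisher p=0.54)  median D=-0.875 (Wilcoxon p=0.15)
nucleotide (mean_of_frequencies): expected shared = 173.2 +/- 5.8, observed = 86, Gaussian lower-tail p = 4.69e-51
protein    (mean_of_frequencies): expected shared = 146.9 +/- 5.1, observed = 81, Gaussian lower-tail p = 5.20e-38
  gene24 <- gene23: 524-580 (57 bp, 7 informative sites) [matches injection]
  gene28 <- gene27: 142-268 (127 bp, 12 informative sites) [matches injection]
```

Reading this: about 70% of protein haplotype classes are private to one
subspecies; under the no-differentiation null one would expect ~147 shared
protein classes but only 81 are observed, so the subspecies-specific
repertoire is far beyond sampling noise (p ≪ 10⁻⁴). Per-SNV F_ST flags the
sites driving differentiation, d_XY exceeds within-subspecies π, and both
injected conversion tracts are recovered inside their true intervals with
the correct carrier chromosomes. All tables land in `results/tables/`;
diversity values print ×100.

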