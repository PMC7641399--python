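# Methods

This note documents the statistical procedures, their assumptions, the
defaults that matter, and the design choices that were genuinely open.

## Data model

Genotypes are unordered pairs of two-field HLA allele names (group:protein,
e.g. `B*39:06`), one pair per locus per individual. Deeper typing fields
are dropped on parse; a trailing `G` marks a g-group (alleles identical
over the typed exons, reported under the lowest-numbered name) and is kept
as part of the two-field name — after reduction, g-group alleles are
ordinary alleles. Untyped loci are empty cells; the individual is dropped
at that locus only, so per-locus chromosome counts n may differ within a
population. Allele order within a genotype is non-semantic and is
canonicalized by lexicographic sort on read.

Reference panels are per-population allele frequency tables with
migrant / uncertain-origin flags; flagged populations are excluded from
mean-frequency computation, and an allele absent from a population counts
as frequency zero in the mean (so the mean is over populations, not over
carriers).

## Diversity

Sample heterozygosity uses the unbiased estimator
H = (n/(n−1))(1 − Σ pᵢ²). The correction is exposed as a flag
(`corrected=False` gives the plug-in value) because summary tables in the
literature do not always state which convention they use. Regional
contrasts are a one-way ANOVA over regions followed by Tukey's HSD;
regions with a single population are skipped with a warning, and the Aché
outlier population is excluded by default from regional summaries (flag
`exclude`), never from per-population tables. The individual-level
association is, per population, an ordinary least-squares regression of
the proportion of homozygous microsatellite loci on the count of
homozygous HLA loci (0–4), flagged at a Bonferroni threshold of
0.05 / (populations tested). The class trend {0, 1, 2+} is a linear
regression on class scores {0, 1, 2}; an empty class is merged upward. A
score-based trend test was chosen over a rank test because the class means
are the quantity displayed and compared.

## Exact Hardy–Weinberg test

The test conditions on allele counts: P(f | c) = n!·Π c_a!·2^h /
((2n)!·Π f_ij!). Arrays are ordered by conditional probability (the
classical exact-test convention), not by heterozygote count; the p-value
is the total probability of arrays no more probable than the observed
one. Array spaces of at most `max_tables` (default 10⁶) arrays are
enumerated exactly, with a proportional node budget so hopeless margins
bail out early; larger spaces use seeded i.i.d. permutation of the 2n
gametes (default 100,000 draws — no burn-in is needed because the
permutations are independent), with p = (hits + 1)/(draws + 1).
Per-genotype diagnostics are standardized residuals
(obs − exp)/√exp against the Hardy–Weinberg expectation at sample allele
frequencies, flagged two-sided at |residual| > 1.96 — the threshold is a
diagnostic convention, not an inferential claim, and an expected count of
zero is reported as undefined. Note the exact conditional test is
discretely conservative: under a neutral null its rejection rate at
α = 0.05 sits at or below the nominal level.

## Ewens–Watterson test

Conditional on (n, k) the Ewens configuration law is parameter-free:
P(config) ∝ n!/(Π_j j^{a_j} a_j!) over partitions of n into k parts, the
normalizer being the unsigned Stirling number of the first kind. The
package enumerates all partitions when their number is at most 10⁵
(cached per (n, k), since the null is shared by all samples of the same
shape) and otherwise samples configurations by a Chinese-restaurant
construction with θ calibrated so E[k] matches, rejecting on k — exact
where cheap, unbiased where not. F_exp is the conditional mean of
Σ (nᵢ/n)², and p = Pr(F ≤ F_obs) is the lower tail, so small p indicates
balancing selection (too-even frequencies) and p near 1 directional
selection. Two-tailed significance uses p < 0.025 or p > 0.975.

## Tajima's D

D = (π − S/a₁)/√(e₁S + e₂S(S−1)) with the standard constants; π averages
over all C(n,2) sequence pairs with multiplicity; alignment columns
containing any gap are excluded (complete deletion) before S and π are
computed. Sequence recoding expands each allele call into its aligned
sequence with multiplicity equal to its copy count and raises a named
error listing any allele absent from the sequence map. The p-value is
Pr(D_sim ≥ D_obs) over neutral coalescent genealogies (msprime,
haploid samples, 10⁴ replicates by default; the pipeline uses 2,000 to
keep full runs fast): mutations are placed branch-length-weighted, with
the count fixed at the observed S by default (`conditioning="fixed_s"`),
or Poisson with Watterson's θ̂ (`"poisson"`) — both are offered because
conditioning conventions differ across tools, and on test cases the two
p-values agree to within a few hundredths.

## AMOVA differentiation and Z_ST

F_ST comes from a two-level AMOVA treating the 2n chromosomes as units,
with squared distance 0/1 under allele identity; R_ST replaces this with
(size_i − size_j)² on microsatellite repeat sizes. Both are computed from
closed-form pair sums over allele counts, so no explicit distance matrix
is built. Negative estimates are retained as computed; two populations
identically monomorphic return 0 by convention, flagged. Region
summaries average pairwise values over all within-region or
between-region population pairs; the HLA mean column is the arithmetic
mean of the per-locus values (not an F_ST on concatenated data).

Z_ST standardizes an HLA F_ST for one population pair against that same
pair's genome-wide microsatellite F_ST distribution:
Z_ST = (F_ST,HLA − mean)/SD, with the mean and sample SD computed per
population pair. The empirical p counts microsatellite loci with
*strictly* greater F_ST, divided by the panel size; markers monomorphic
within the pair contribute F_ST = 0 rather than being dropped so the
denominator stays fixed. Region aggregation averages −log p within
region pairs, flooring p = 0 at half the panel resolution before taking
logs; −log p = 3 is marked as the 0.05-level line for a 678-locus panel.

## Allele classification

For each allele observed in the Native cohort, the unweighted mean
frequency across Native populations (absent = 0) is compared with the
mean across non-flagged reference populations. Endemic requires a
reference mean of exactly zero; LFD requires ratio ≥ 3 (the boundary is
inclusive); copies are total allele copies summed over Native
populations. Endemic/LFD calls with ≤ 3 copies are flagged poorly
supported; an LFD allele poorly supported in both the primary comparison
and an optional secondary validation split is removed (demoted to
"other"). When no secondary split is supplied the removal filter degrades
to the primary-only flag with a warning; removing the filter can only
grow the LFD list. Regional category means are unweighted averages of
per-population frequency sums over the populations of a region, with the
Aché excluded from every cell (its exclusion is a single flag, applied
uniformly rather than per-locus); the continental column averages over
all included Native populations directly.

## EM haplotypes and ASH

Two-locus haplotype frequencies are estimated by gene-counting EM on
unphased genotypes; only double heterozygotes are phase-ambiguous. The
log-likelihood is asserted non-decreasing at every iteration; convergence
is a log-likelihood change below 10⁻⁸ with a 10,000-iteration cap, and
the best of ten seeded Dirichlet restarts plus a linkage-equilibrium and
a uniform start is returned. ASH uses the plug-in (uncorrected)
heterozygosity of the conditional partner distribution, bounded by
1 − 1/m for m partner alleles. Category summaries average allele-level
ASH records with equal weight across populations and locus pairs (the
alternative — averaging within populations first — is noted but not
used); frequency strata are (0.05, 0.10] and (0.10, 1], measured in the
population where the ASH value is computed, and per-locus category rows
include alleles of every frequency.

## Synthetic data generator

The generator emulates the study conditions: 24 populations (one
Siberian, 23 Native American over NAM/MEA/SAA/SAL), 15–25 individuals
each, four HLA loci with Ewens-drawn ancestral frequency spectra
(θ = 4/10/5/6 for A/B/C/DRB1, making HLA-B the most diverse), a
678-marker microsatellite panel on a 21-size stepwise support
(μ = 5·10⁻⁴ per gamete per generation), and a 50-population worldwide
reference panel (one flagged migrant population) standing in for a
published meta-analysis panel. Drift is simulated on allele frequencies
(multinomial Wright–Fisher), not genealogies — cheap, and adequate for
heterozygosity clines and allele-classification behaviour. The founder
chain (SIB → NAM → MEA → SAA → SAL; bottlenecks of 300/80/80/80/60
diploids for 40 generations each, then 50-diploid, 10-generation
population-specific drift) produces the expected monotone heterozygosity
decline. Endemic alleles are injected after the split from the reference
panel (so their panel frequency is exactly zero) at target frequencies of
0.06–0.10 in chosen region sets; LFD alleles are real panel alleles
(panel mean 0.002–0.04) boosted about 4-fold in all Native regions.
Planted alleles and chain-order expectations are recorded in a truth
object that the classification-recall and cline-recovery checks score
against.

What the generator does **not** emulate: real HLA mutation/recombination
processes, balancing selection (all loci drift neutrally, so tests should
*not* reject), linkage between HLA loci beyond what the two-locus
constructor plants, genotyping error and allele-naming ambiguity, or the
actual American demographic history (dates, standstills, admixture).
Passing tests therefore demonstrate calibration and recovery of planted
signal under drift-only conditions, not performance on real data.

Two-locus samples are built from h_ab = p_a p_b + D with D = D'·D_max
attached to the first allele pair and the remaining cells adjusted
proportionally so both marginals are exact; infeasible D' raises. Star
sequences give every allele one private substitution off a shared
ancestor (paired, in sampling, with a skewed allele spectrum — the
negative-D regime); balanced-clade sequences split alleles across a deep
split of max(4, L/20) fixed differences (positive-D regime).

## Problem sizes and runtimes

The default end-to-end synthetic run (24 populations, 678 markers, 2,000
Tajima replicates, 10⁵-step HWP Monte-Carlo) completes in about three
minutes on one CPU. The acceptance script uses 2,000 Ewens-Watterson
calibration replicates, 100 Tajima sign replicates per regime, 100
founder-chain replicates, five classification-recall cohorts and a
100-replicate HWP calibration, all seeded from its `--seed` argument.

## Known limitations

* The exact HWP p-value is conservative for sparse tables; no mid-p
  variant is offered.
* The Ewens–Watterson Monte-Carlo fallback rejects on k, which becomes
  slow for k far from E[k(θ)] at large n (not reached at the study's
  sample sizes, where enumeration applies).
* AMOVA is two-level only; no hierarchical (region/population/individual)
  decomposition and no permutation p for F_ST itself — the microsatellite
  background comparison is the inference device.
* EM haplotypes are limited to locus pairs; no per-individual phase
  output.
* Cross-locus "mean HLA" summaries average whichever loci are typed,
  which mixes slightly different sample sizes per locus.
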