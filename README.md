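# hla-popstruct

Population-genetic analysis of HLA class I/II variation against a
genome-wide neutral-marker background, for researchers studying how
demographic history (serial founder effects, bottlenecks, expansions) and
natural selection jointly shape variation at the most polymorphic human
loci. The package targets the study design used for Native American
cohorts: multilocus HLA genotypes (HLA-A, -B, -C, -DRB1 at two-field
resolution) and a genome-wide microsatellite panel typed in the same
individuals, compared against a worldwide reference allele-frequency
panel.

## What it computes

* **Diversity** — per-population allele counts *k* and unbiased sample
  heterozygosity *H* = (n/(n−1))(1 − Σ pᵢ²); population-level Pearson
  correlation of HLA vs. microsatellite heterozygosity; Tukey-HSD regional
  contrasts; individual-level regressions of microsatellite homozygosity
  on the number of homozygous HLA loci, and the class trend {0, 1, 2+}.
* **Hardy–Weinberg proportions** — the conditional exact test: the
  probability of a genotype array given allele counts is
  P(f|c) = n!·Πc_a!·2^h / ((2n)!·Πf_ij!); the p-value sums the probability
  of arrays no more probable than the observed one (full enumeration for
  small array spaces, seeded gamete permutation otherwise), with
  standardized-residual diagnostics per genotype.
* **Neutrality** — the Ewens–Watterson homozygosity test: F = Σ p̂ᵢ²
  against its Ewens-sampling-formula distribution conditional on (n, k),
  enumerated exactly over partitions of n into k parts (Monte-Carlo
  otherwise), lower-tail p so small p indicates balancing selection; and
  Tajima's D = (π − S/a₁)/√(e₁S + e₂S(S−1)) on sequence-recoded samples
  with a coalescent-simulation p-value (msprime genealogies, fixed-S
  mutation placement by default).
* **Differentiation** — two-level AMOVA F_ST over chromosomes with
  allele-identity distance (R_ST with squared allele-size distance for
  microsatellites), region-pair means, and the empirical standardization

      Z_ST = (F_ST,HLA − mean F_ST,msat) / SD(F_ST,msat)

  per population pair, with an empirical p equal to the proportion of
  microsatellite loci whose F_ST exceeds the HLA value.
* **Allele geography** — classification of every allele as *endemic*
  (absent from the reference panel), *LFD* (≥ 3-fold more common in the
  Americas), or *other*, with a poorly-supported flag at ≤ 3 copies and a
  two-dataset removal filter; per-population category frequency sums and
  regional means.
* **Haplotypes** — EM ("gene counting") estimation of two-locus haplotype
  frequencies from unphased genotypes, and allele-specific heterozygosity
  ASH(a) = 1 − Σ_b (h_ab/p_a)², summarized by allele category and
  frequency stratum.
* **Synthetic data** — a serial-founder cohort generator (Wright–Fisher
  drift on allele frequencies along a SIB → NAM → MEA → SAA → SAL chain,
  stepwise-mutating microsatellites, planted endemic/LFD alleles, LD-bearing
  two-locus samples, star / balanced-clade allele sequences) with a
  ground-truth record, so every analysis stage runs and is testable with
  no external data.

## Worked example

Generate a synthetic study and run the stages (each driver prints what it
found and writes TSVs under `results/`):

```bash
python analysis/01_simulate.py
python analysis/02_diversity.py
python analysis/03_hwp.py
python analysis/04_neutrality.py
python analysis/05_differentiation.py
python analysis/06_allele_geography.py
python analysis/07_haplotypes.py
```

Output from a run with the default seed:

```
wrote synthetic bundle to results/inputs
  populations: 24  individuals: 500
  founder chain: SIB -> NAM -> MEA -> SAA -> SAL
  expected msat heterozygosity along the chain:
    SIB: 0.833
    NAM: 0.664
    MEA: 0.539
    SAA: 0.457
    SAL: 0.356
...
  1 of 96 tests significant at the 0.05 level (chance expectation: 4.8)
...
  Ewens-Watterson: 5 of 96 tests significant (two-tailed 0.05)
...
  planted-allele recall: 14/14
  category burden vs msat heterozygosity (Pearson r):
    A: r = -0.87
    B: r = -0.81
```

The heterozygosity column shows the serial-founder cline (diversity
decays with distance from the source); the HWP and Ewens–Watterson counts
sit at their neutral chance expectation, as they should for a cohort
simulated without selection; planted endemic/LFD alleles are recovered
perfectly; and populations that experienced more drift (lower
microsatellite heterozygosity) carry a higher burden of private and
boosted alleles — the negative correlations in the last block.

The same stages are available as a CLI over a YAML config
(`hla-popstruct simulate|diversity|hwp|neutrality|fst|classify|haplo|all
--config run.yaml --seed N --out DIR`).

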