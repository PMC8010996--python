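# recqtl

Recessive QTL mapping for bull fertility: sliding-window haplotype
association on phased genotypes, carrier-compatibility fine-mapping of
sequence variants, and derivation of the underlying fertility and
semen-quality phenotypes.

## The problem

Male fertility in dairy cattle can be quantified objectively because semen
from each artificial-insemination sire is used in thousands of
inseminations whose success (the 56-day non-return rate, NRR56) is
recorded.  The trait's additive heritability is low (~10%), but recessive
haplotypes of moderate frequency can depress the fertility of homozygous
carriers by large amounts while leaving heterozygotes untouched — an
architecture that additive GWAS misses.  `recqtl` implements the full
analysis for detecting such loci, for analysts working with phased SNP
panels and insemination/semen records (and, since such data are usually
access-restricted, a synthetic breeding-population generator that
reproduces the statistical structure the analysis assumes).

## The method

**Haplotype scan.**  A window of 50 contiguous SNPs slides in steps of 15
along the phased autosomal haplotypes.  Within each window, every
haplotype with frequency above 1% (among the 2N phased chromosomes) is
tested one-vs-rest with the linear model

```
y = μ + Σⱼ aⱼ PCⱼ + b·HT + c·k + e
```

where PCⱼ are the top 10 principal components of the genomic relationship
matrix (VanRaden method 1 on SNPs with MAF > 0.5%), HT is the haplotype
dosage — copy count under additive coding, homozygosity indicator under
recessive coding (tested only when ≥ 0.5% of individuals are homozygous) —
and k an optional conditional covariate such as the recessively coded
status of a previously mapped haplotype.  Significance is Bonferroni
(α = 0.05 over the realized test count) and calibration is summarized by
the genomic inflation factor λ.

**Fine-mapping.**  Carrier status (0/1/2 copies of the top haplotype) is
inferred by exact string matching.  Sequence variants within ±3 Mb are kept
as candidates when, for either allele orientation, their allele frequency
is > 0.8 in homozygous carriers, within [0.4, 0.6] in heterozygotes and
< 0.05 in non-carriers; variants passing MAF (> 0.05) and imputation
quality (r² > 0.4) filters are additionally tested under recessive coding,
and the QTL is dissected by conditional analysis.

**Phenotypes.**  Bull fertility is derived from 0/1 non-return outcomes via
Henderson's mixed-model equations (fixed: month, parity, price class,
breed combination, technician; random: herd, bull), standardized to
100 ± 12, low outliers (> 5 SD) removed, cohorts merged after z-scoring.
Semen-quality records pass a fixed filter cascade (age 400–1000 days,
known interval ≤ 8 days, motility ≥ 70%, ≥ 15 M sperm per straw, …, ≥ 8
ejaculates per bull); sperm-morphology exams are counted over 16 defect
categories with major/minor and compensatory/non-compensatory aggregates
and a breeding-suitability rule (≥ 75% normal and ≤ 20% non-compensatory:
suitable; 65–74% normal: processed with compensation; below: fail).

## Worked example

```
python examples/01_simulate_and_scan.py
```

```
true QTL window:     chr3 SNPs 301-350, frequency 0.184
recessive top hit:   chr3 SNPs 301-350, p = 3.34e-06, effect -0.76 SD, 39 homozygotes
additive top hit:    p = 0.000185
tests: 3055 recessive, Bonferroni threshold 1.64e-05
genomic inflation lambda = 1.066
```

A recessive haplotype embedded at frequency 0.18 with a −0.8 SD homozygote
effect is recovered exactly at its true window; the recessive model's
p-value (3.3 × 10⁻⁶, below the Bonferroni threshold) is two orders of
magnitude below the additive model's, the estimated effect (−0.76 SD) sits
within sampling error of the simulated truth, and λ ≈ 1 shows the
remaining tests are calibrated.  `examples/02–04` walk through
fine-mapping, the non-return-rate phenotype and the semen-quality cascade
the same way.

A thin CLI mirrors the pipeline stages
(`recqtl simulate|scan|finemap|phenotype|semen-qc`); the library API is
the primary interface.

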