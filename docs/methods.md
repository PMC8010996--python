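# Methods

## Scope and model

`recqtl` maps recessive quantitative trait loci for male fertility in
artificial-insemination cattle from phased SNP genotypes.  The analysis
chain is: phenotype derivation (non-return rate → mixed-model bull
effects → standardization → cohort merge), population-structure
correction (GRM → top principal components), a sliding-window haplotype
association scan under additive and recessive inheritance with optional
conditional covariates, and sequence-variant fine-mapping by
carrier-compatibility filtering plus recessive association.  Because the
motivating data (SNP-array genotypes, insemination and semen records of
breeding bulls) are access-restricted, the package ships a first-class
synthetic generator that reproduces the structure each stage assumes; all
statements below about what passing tests demonstrate are statements about
that synthetic structure.

## Haplotype scan

Windows cover 50 contiguous SNPs and advance in steps of 15 within each
chromosome; trailing partial windows are dropped so haplotype complexity
is comparable across windows.  Within a window, haplotypes are the
distinct allele strings among the 2N phased chromosomes; each string with
frequency strictly above 1% is tested one-vs-rest, so a window with H
eligible haplotypes contributes H tests to the family-wise correction.
The test is ordinary least squares of the phenotype on an intercept, the
top 10 GRM principal components, an optional conditional covariate, and
the haplotype dosage; p-values are two-sided t-tests with
n − (#coefficients) degrees of freedom (no normal approximation).
Recessive coding is the indicator of carrying two copies and is attempted
only when at least 0.5% of individuals are homozygous (boundary
inclusive); additive coding is the copy count.  Implementation note: the
scan residualizes the phenotype and each dosage against the covariate
block once per scan (Frisch–Waugh–Lovell), which reproduces the full OLS
coefficient, standard error and p-value exactly (asserted against the
direct fit and against an independent OLS implementation in the tests)
while keeping the per-test cost at one vector product.

Multiple testing is Bonferroni on the realized test count of each scan,
consistent with correcting a 186,278-test scan at 2.68 × 10⁻⁷ and a
12.86 M-variant study at 3.89 × 10⁻⁹.  The genomic inflation factor is
the median of the 1-df chi-square quantiles of the p-values divided by
the null median (≈ 0.4549).  Tie-breaking for the top haplotype is
smallest p, then highest frequency, then lexicographic allele string.

## Relatedness

The GRM is VanRaden's first method, G = ZZᵀ / Σ 2pⱼ(1 − pⱼ), on SNPs with
MAF strictly above 0.5% — the construction the common PLINK/GCTA workflow
uses.  Principal components are eigenvectors of G itself (not of the
dosage matrix), descending by eigenvalue; for cohorts above ~600 the top-k
pairs come from a Lanczos solver with a fixed start vector so results are
deterministic.  The Haseman–Elston regression (cross-products of
standardized phenotypes on off-diagonal GRM entries) is included as a
method-of-moments heritability check for synthetic-data validation; its
standard error is a leave-one-individual-out jackknife, because the
~N²/2 pairs are dependent and the naive OLS standard error undercovers
(observed directly during development at h² = 0.1).  REML/GREML variance
estimation is deliberately out of scope.

## Fine-mapping

Carrier status is the exact string-match copy count of the top haplotype.
The compatibility screen keeps variants within a ±3 Mb margin whose
per-carrier-class allele frequencies fit complete linkage with a recessive
haplotype: > 0.8 in homozygous carriers, within [0.4, 0.6] in
heterozygotes, < 0.05 in non-carriers.  Boundary semantics are read
literally (strict for > and <, inclusive for the interval).  Because the
haplotype-linked allele may be either reference or alternate, both
orientations are tested and the passing one is reported; the filter is
therefore invariant to allele relabelling.  An empty carrier class yields
an indeterminate verdict, never a pass.  A `slack` parameter (default 0)
relaxes all three thresholds as a crude genotyping-error allowance.
Variant association uses the same OLS machinery with recessive coding
keyed to the minor allele, after MAF (> 0.05) and imputation-quality
(r² > 0.4) filters.

## Fertility phenotype

Non-return outcomes are 0/1 per first insemination, with y = 1 meaning no
re-insemination within 56 days (the success orientation).  The mixed model
has fixed insemination month, parity class, semen-price class, breed
combination and technician, and random herd and bull; it is fitted on the
observed 0/1 scale by Henderson's mixed-model equations, following the
classical sire-evaluation practice, with variance ratios
λ = σ²ₑ/σ²ᵤ supplied by configuration (defaults herd 9, bull 19; no
components are published for the source evaluation, so these are
conventions, and the solutions are BLUPs given them).  Fixed effects use
treatment coding with the first level dropped; a rank-deficient design
raises an error naming the aliased columns.  Bull solutions are deviations
from the mean non-return rate; standardization is an affine rescale to
100 ± 12, outlier removal drops bulls strictly more than 5 SD below the
mean, and cohorts are merged after within-cohort z-scoring.  The
generator, by contrast, draws outcomes from a logistic model — the
recovery tests (rank correlation > 0.8 at 500 inseminations per bull)
deliberately span this model mismatch.

## Semen quality and morphology

The ejaculate filter cascade runs in a fixed order (age strictly inside
400–1000 days; interval to the preceding ejaculate known, which removes
each bull's first record; volume recorded; unmixed; processed; interval
≤ 8 days; first ejaculate per day, earliest record winning ties; motility
≥ 70%; head/tail anomaly scores in {0,1,2,3}; ≥ 15 M sperm per straw and
not sex-sorted; collector and handler known; genotype available; finally
≥ 8 surviving records per bull) and reports bull/ejaculate counts after
every step; counts are non-increasing by construction.  Morphology exams
count sperm over 16 defect categories; categories 0–2 (head shape,
vacuoles, condensed DNA) are non-compensatory, 3–15 compensatory, with
major = {0,1,2,5,7,8,9,12,14} and minor the complement.  Exams with fewer
than 150 assessed sperm (the evidently failing 50-sperm exams included)
are excluded from proportion traits but still counted in the
examination-number trait.  Suitability: ≥ 75% normal and ≤ 20%
non-compensatory is suitable; normal in [65, 75) with ≤ 20%
non-compensatory is processed with dose compensation; anything else fails;
"passed the examination" means normal ≥ 65 and non-compensatory ≤ 20.

## Synthetic generator

Panels are founder mosaics: each haplotype copies one of `n_founders`
founder templates and re-draws its template with probability
`switch_rate` per SNP, producing block LD with mean block length
1/switch_rate SNPs.  Defaults (8 founders, switch rate 0.005, SNP spacing
~5 kb) give 4–10 haplotypes above 1% per 50-SNP window, matching the
density implied by a 186,278-haplotype genome scan, and make recessive
tests (≥ 0.5% homozygotes) broadly eligible.  Founder allele frequencies
are uniform on [maf_floor, 1 − maf_floor].  The causal haplotype is an
existing window string; copies are drawn i.i.d. Binomial(2, q) per
individual and minimally adjusted to put the realized frequency within
tolerance of the target (default 0.18 ± 0.02), so homozygote counts are
near, but not exactly, Hardy–Weinberg.  Phenotypes are latent-scale with
variance ~1: homozygote effect (default −0.8 SD) + polygenic term
(per-SNP i.i.d. effects scaled to sample variance h², default 0.10,
causal window excluded) + Gaussian residual.  Sequence variants copy the
causal-haplotype indicator with probability exp(−distance/500 kb) per
haplotype, one designated variant being perfectly concordant (r² = 1);
insemination outcomes are Bernoulli on a logistic scale around a 65% mean
with configurable factor effects; morphology exams are multinomial with a
doubled head-shape probability in homozygous carriers (5.4% → 10.8%,
emulating the reported ~2× elevation).  Every generator is seeded and
bit-reproducible.

What the generator does **not** emulate: pedigree/family structure and
admixture (so the PC correction is exercised mechanically, not
stressed), genotyping and phasing error, linkage disequilibrium decay
beyond the founder-block scale, selection, and sex chromosomes.  Passing
tests therefore demonstrate correctness of the statistical machinery and
power under the stated generative conditions, not robustness to every
property of real array data.

## Numerical choices and problem sizes

Exact OLS/t inference throughout; perfect fits and constant dosages are
flagged rather than assigned p-values; p-values are clipped into (0, 1].
The MME system is assembled sparse and solved directly.  Window
coordinates are 1-based inclusive; haplotype frequency is allele (not
diplotype) frequency over 2N chromosomes.

The test suite scales its simulation studies to keep runtime short: the
power/recovery study runs 20 replicates at N = 1200 bulls and M = 6000
SNPs (the recessive contrast is strongly powered there: ~39 homozygotes
give a standard error of ~0.17 SD for a −0.8 SD effect), and null
calibration pools p-values over 10 replicates at N = 1000, M = 5000
because a single scan's λ has sampling noise of ~0.1 due to overlapping
windows.  `scripts/acceptance.py` additionally runs the mapping study at
full cohort size (N = 3736, M = 20,000, 5 replicates) with principal
components computed from a 4×-thinned marker subset, the standard
LD-pruning practice.

## Known limitations

The linear (observed-scale) mixed model for a binary outcome is the
classical convention, not a probability model; bull solutions are shrunken
means, and the variance ratios are user configuration.  The
compatibility filter's genotyping-error slack is a single symmetric
threshold shift, not an error model.  The Haseman–Elston estimator is for
validation only and is noisier than REML.  Windows at chromosome ends
shorter than 50 SNPs are never tested.
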