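# Methods

This note documents the models, numerical choices and limitations behind
`recessivescan`, in the spirit of a statistical-software methods appendix.

## Phenotype construction

Raw ejaculate records pass through a fixed-order filter cascade mirroring
routine AI-lab practice: interval-to-previous-collection known; age at
collection in [400, 1000] days; volume and motility recorded; no recorded
rejection cause; motility ≥ 70%; volume > 1 ml; concentration
> 0.3×10⁹/ml; not pooled; first ejaculate per (bull, day); collector
recorded; plausible anomaly scores (0–3); sperm per straw in [15, 25]
million; finally ≥ 8 ejaculates per bull and (when a genotype list is
supplied) a join to genotyped bulls. Counts are order-dependent, so the
order is fixed and only overridable behind an explicit argument. The two
AI-minimum thresholds (volume, concentration) sit directly after the
motility rule because raw datasets usually encode them inside rejection
causes rather than as separate columns. The GWAS phenotype is the per-bull
arithmetic mean of the filtered records; the residual-based alternative
(age + interval + collector + season fixed effects) is provided and its
correlation with the raw means reported.

The bull-fertility (NRR56) index is a linear probability model on the
binary 56-day non-return outcome with month, parity, straw-price,
breed-combination, technician, herd and bull effects, all fixed; bull
effects are centred and standardized to mean 100, SD 12, and bulls more
than 3 SD below the mean are flagged and dropped (they plausibly carry
distinct recessive conditions and would distort association tests). A
linear (rather than logistic) model keeps the bull effect on the
probability scale and matches how national evaluations summarize
non-return rates; at desk scale all effects are fixed because the
random/fixed split of the production systems is not part of this package's
contract.

## Variance components

The repeated-records animal model is
`y = Xb + Z_u u + Z_p p + e`, `u ~ N(0, A σ_g²)`, `p ~ N(0, I σ_pe²)`,
`e ~ N(0, I σ_e²)`, with `X` holding intercept, age, collection interval,
collector and season (calendar quarter). `A` is built by the tabular
method; `A⁻¹` by Henderson's rules with inbreeding taken from the tabular
diagonal. Restricted maximum likelihood is maximized by EM on Henderson's
mixed-model equations; the diagonal permanent-environment block is
absorbed, so each iteration factors only a (p + q)-dimensional system. The
restricted log-likelihood is computed from the same factorization
(`−2l_R = (N−p−q−m)·ln σ_e² + q·ln σ_g² + m·ln σ_pe² + ln|A| + ln|C| + y'Py`)
and is checked in tests against the dense-covariance formula. EM steps
never decrease `l_R`; because plain EM converges geometrically, an
Aitken-style extrapolation is attempted every third iteration and accepted
only if the restricted likelihood does not drop, preserving monotonicity
while cutting iteration counts several-fold. Convergence is declared at a
maximum relative parameter change of 10⁻⁸ by default (10⁻⁶ is used in the
large simulation tests; the ratios are insensitive at that level).
Components are floored at 10⁻¹² of the phenotypic variance and reported as
0 at the boundary, which also keeps the variance *ratios* invariant under
affine rescaling of `y`. Standard errors, when requested, come from a
parametric bootstrap at the fitted components (off by default).

## Haplotype-window association scan

Phased haplotypes are scanned in windows of 50 contiguous SNPs stepped by
15; only complete windows are tested and windows never span chromosomes.
Within a window, a haplotype is an exact 50-allele string; a bull's copy
count is the number of its phased chromosomes matching the string.
Haplotypes with frequency > 1% are tested one-vs-rest by OLS of the
phenotype on intercept + top-10 GRM principal components + the model
predictor (copy count / carrier indicator / homozygote indicator). The
recessive test additionally requires homozygotes in at least
`ceil(0.01·N)` bulls. The per-test statistics use the
Frisch–Waugh–Lovell residualization of the shared covariate block, which
is algebraically identical to the full regression (verified against
statsmodels to 10⁻¹⁰) and makes genome scans cheap. The Bonferroni
denominator is the number of haplotype tests actually performed for the
trait/model, not the number of windows. Genomic inflation is
`λ = median(qchisq(1−p, 1)) / qchisq(0.5, 1)`. The conditional scan adds
the top haplotype's status coding (homozygosity indicator under the
recessive model, copy count under the additive model) as a covariate in
every regression; a constant conditioning covariate is ignored with a
warning. Genotype QC precedes PCs: samples then SNPs with > 20%
missingness, MAF < 0.005, and Hardy–Weinberg exact-test (Wigginton-style
recurrence, mid-p off) P < 10⁻⁵ are removed. PCs are computed once and
reused across traits and models.

## Shared autozygosity and variant filtration

From the most associated window, the shared segment among homozygous
carriers is extended marker-by-marker in both directions while every
carrier is homozygous and all carriers agree; boundaries are the outermost
conforming markers (not midpoints to the first violating ones), and the
length is `end_bp − start_bp`. Missing genotypes default to "conforming"
because the intended input panels are imputed to completeness; a strict
"break" mode exists. Recessive-compatibility filtration keeps a variant
when its alternate-allele frequency is ≥ 0.8 in homozygous carriers,
within [0.4, 0.6] in heterozygotes, and ≤ 0.05 in non-carriers — all
bounds inclusive, frequencies pooled over called alleles in a group (not
averaged per sample), missing genotypes excluded from denominators, and a
group with no called alleles failing closed. Each alternate allele of a
multi-allelic record is assessed separately. Consequence strings are read
from existing CSQ/ANN annotation when present, never computed.

## Cryptic splice-donor analysis

Donor strength is a position-weight-matrix score over the −3..+6 context
(9-mer) with the invariant GT required at +1/+2: the sum of
`log2(f/0.25)` using generic vertebrate donor-site base frequencies
shipped as `data/donor_pwm.tsv` (Shapiro–Senapathy-style values; the
+1/+2 rows use 0.991 so log-odds stay finite). A donor *gain* is an
exonic GT whose alt-allele context contains the variant, scores at least
0 bits (configurable) and scores strictly above the reference context.
The truncation is the distance from the cryptic cleavage point to the
natural exon end; `truncation mod 3` decides in-frame vs frameshift, and
for in-frame calls the deleted residues follow from the cumulative coding
length (`first = ceil(c1/3)`, `count = truncation/3`). When the truncation
is not codon-aligned, the hybrid junction codon can make the deleted
interval ambiguous by one residue; tests therefore check that excising
the reported interval reproduces the truncated translation. Genes are
represented on the plus strand; minus-strand genes are expected to be
reverse-complemented at ingest. Junction support in RNA-seq requires two
consecutive aligned blocks (CIGAR split at N only) ending exactly at the
donor exon end and starting exactly at the acceptor, with ≥ 6 aligned
bases on each side; overlapping reads matching neither junction are
tallied as unassigned, so wt + mt + unassigned equals the number of reads
overlapping the wild-type junction interval.

## Synthetic-data generator

The generator's defaults encode the study conditions the analyses are
validated under: ~800 bulls; a 50-SNP QTL haplotype at frequency 0.24
implanted by independent Binomial draws per chromosome (hence
Hardy–Weinberg carrier counts); motility means 86.37 / 86.37 / 82.77% for
0/1/2 copies with phenotypic SD 2.33% (a ≈1.55 SD purely recessive shift;
other traits carry no QTL by default); heritability 0.25 and repeatability
0.43 on a unit internal variance, applied as affine transforms per trait;
8–40 ejaculates per bull over ages 400–1000 days with collector, quarterly
season, age and interval effects; and pedigrees of founder sires/dams with
polygenic values drawn down the pedigree with Mendelian-sampling variance.
Background linkage comes from a two-founder copying model (per-SNP switch
probability 0.02), the simplest structure that yields multi-SNP haplotype
sharing for window tests; an optional per-allele copy-noise rate exists
but defaults to 0 because exact-string haplotype frequencies are the
scanned quantity. The QTL haplotype sits inside a longer identical
ancestral segment (default 120 markers; marker spacing is exponential
with mean 4 kb) whose flanking markers are forced polymorphic so the
shared-autozygosity search has a well-defined truth. Generators for the
candidate-region VCF and the junction SAM construct their outputs so the
downstream counts are known exactly (a configured number of
rule-compatible variants with the violation type recorded in INFO; exact
wild-type/mutant read counts with guaranteed overhangs). Every generator
is a pure function of its `SimConfig` seed and writes a JSON ground-truth
manifest.

What the generator does *not* emulate: coalescent LD decay, genotyping
error, imputation artefacts, the X chromosome, multi-allelic markers,
selection or non-random mating, trait-specific QTL pleiotropy and
seasonality beyond four calendar quarters. Passing tests therefore show
that the estimators are correct and calibrated under the stated model, not
that real cattle data meet those assumptions.

## Problem sizes used in tests and the acceptance script

Simulation-based checks run at desk scale chosen for statistical
resolution: null-scan calibration uses 800 bulls over 6–10 chromosomes of
2,000 SNPs (≈2,600 recessive tests, so the median-based λ has SE ≈ 0.05);
power uses 20 seeds of 800 bulls on 2×800 SNPs; REML recovery uses 10
seeds of 800 bulls × 20 records (≈16,000 records, ~870 pedigree animals).
The acceptance script emulates the 794-bull mapping cohort with a 595-
marker ancestral segment at 4 kb spacing, so the expected shared segment
is ≈2.4 Mb.

## Known limitations

- EM-REML is single-trait; no genomic (marker-based) relationship REML.
- The scan is fixed-effects OLS with PC correction, not a mixed-model
  association; residual stratification beyond the PCs inflates λ.
- Haplotype identity is exact string match; genotyping error fragments
  haplotypes and would bias frequencies downward on real data.
- The donor PWM is a generic vertebrate model for detection and ranking,
  not a calibrated splice-strength predictor; acceptor sites and branch
  points are out of scope.
- The fertility model treats herd as fixed, which is only appropriate at
  the cohort sizes used here.
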