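# Methods

This note records the statistical model, the conventions chosen where the
analysis left genuine freedom, the synthetic-data generator's assumptions,
and the numerical choices that affect results.

## Association model

Each SNP–probe test is an ordinary least squares fit of normalized
expression y on additive allele dosage d ∈ [0, 2] with an intercept:

    y_i = α + β d_i + ε_i ,   ε_i ~ iid N(0, σ²).

Reported statistics: β̂ and its standard error, R² (the squared Pearson
correlation of y and d — for simple OLS identical to the model R²), and
the two-sided P value of t = β̂/SE on n−2 degrees of freedom, which is
algebraically the Pearson-correlation test. Spearman's ρ and its P are
reported alongside as a rank-based companion; significance decisions use
the Pearson-based P. Complete-case analysis is applied per pair. Residual
diagnostics (skewness, excess kurtosis, a Breusch–Pagan-type LM score of
squared residuals on dosage) are attached as metadata and never used to
drop results automatically — they flag, a reviewer decides.

Degenerate inputs: a monomorphic dosage raises an undefined-statistic
error; constant expression against a polymorphic dosage is reported as
slope 0, R² 0, P 1 with a flag. Nominal P values are floored at 1e-300 so
numerically perfect fits stay in (0, 1].

## Genotype QC

Filters are strict exclusions in a fixed order with first-failing-rule
attribution: sample call rate → variant call rate → MAF → INFO → region
blacklist → quality blacklist. Defaults: call rate ≥ 0.98 (samples and
variants; the sample-level bound is separately configurable for small
variant panels, where a single missing call would otherwise condemn a
sample), MAF ≥ 0.01, INFO ≥ 0.8. Comparisons carry a 1e-12 guard so a
variant sitting exactly on a threshold survives floating-point noise.

The INFO score is the measured-information ratio

    INFO = 1 − mean_i(v_i) / (2 p̄ (1 − p̄)),

where v_i is sample i's posterior genotype variance and p̄ the posterior
mean allele frequency; it is defined as 1 when p̄ ∈ {0, 1} and clamped to
[0, 1]. When posterior triples are unavailable, the dosage-variance
fallback var(d)/(2 p̄ (1 − p̄)) (clamped) is used. Both are accepted
dialects of the imputation-quality metric; the filter threshold, not the
dialect, carries the analysis content.

The HLA region is excluded by default as the chromosomal interval
chr6:25,000,000–35,000,000 (1-based inclusive), overridable in config —
the exclusion is motivated by probe cross-hybridization and copy-number
confounding there, and no exact coordinates are canonical. Raw-intensity
cluster-separation metrics are not computable from dosages; they enter
only as an externally supplied per-variant quality blacklist.

## Expression preparation

The eQTL fit is agnostic to the exact normalizer as long as the matrix is
variance-stabilized with comparable per-sample distributions, so the
default pipeline is log2(x+1) followed by quantile normalization across
samples (ties mapped to the mean of the tied reference values, which
makes the transform idempotent). A rank-based inverse-normal transform
(Blom offset 3/8) is available when fully Gaussian marginals are wanted
for P-value robustness; `none` passes pre-normalized input through.
Cross-platform probe harmonization is an id-intersection; cohort merging
is column-aligned concatenation with cohort-of-origin batch labels, and
the pipeline order is merge → normalize → batch-correct.

Batch correction subtracts per-probe batch means and restores the grand
mean (equivalent to regression on batch indicators); batches with one
sample cannot contribute an offset estimate and are left uncorrected with
a warning. A PCA check (probe-centered, top-k components) reports the R²
of each component on batch indicators before and after correction.

## Risk loci, LD blocks, cis/trans

LD is the composite r²: the squared Pearson correlation of dosage vectors
over complete pairs. It requires no phase information and applies equally
to imputed dosages — a deliberate choice over haplotype-phase EM
estimators. Proxy search is confined to a 1-Mb window around the index
SNP (configurable; the biologically relevant proxies of a risk SNP are
local). Membership is inclusive at r² = 0.8; the index SNP is always a
member with r² = 1; a block may legitimately contain only its index.

A probe is cis to a locus iff it is on the block's chromosome and its
start site lies within 4 Mb of the block *span* (edge distance, 0 inside
the span), with "within" read inclusively; everything else — including
all other chromosomes — is trans, and the trans family is genome-wide.
Probes lacking coordinates are excluded from classification and logged.

## Min-P permutation procedure

The multiplicity correction is experiment-wide: per replicate, ONE random
permutation of the sample linkage between the genotype matrix and the
entire expression matrix (covariates, when present, travel with the
expression side), a full rescan of the test family, and the minimum
nominal P recorded. The single shared permutation preserves LD among SNPs
and co-expression among probes, so the null distribution of the minimum
reflects the family's effective number of tests — this is what makes the
procedure exact under the global null and less conservative than
independence-based bounds on correlated families.

Threshold convention: for level α the threshold is the k-th smallest of
the R replicate minima with k = floor(α(R+1)); a nominal P is significant
iff P ≤ threshold (inclusive). This order-statistic rule is integer-
deterministic and gives rejection probability exactly k/(R+1) under
exchangeability with continuous statistics. R < 100 is refused (the α
quantiles are unstable); the study-scale default is R = 10,000. The
empirical adjusted P is single-step: (1 + #{min P ≤ p})/(R+1), floored at
1/(R+1). Cis and trans scans use separate families and separate nulls.

## Covariate robustness

Covariates (age, sex, CRP, swollen joint count by default; ESR, DAS28,
diagnosis and activation surrogates acceptable) enter one at a time:
expression ~ dosage + covariate, categorical covariates one-hot against a
reference level, complete cases, designs rejected when the standardized
condition number exceeds 1e8 (naming the offending columns). The record
compares the adjusted slope with the base slope; "unchanged" means
|Δ| < 0.1·|β̂_base| by default — a configurable operationalization, not a
canonical rule. A SNP × covariate interaction model with its P value is
included as an explicitly labelled extension. Left-censored CRP values
("<5") are encoded at the interval midpoint 2.5 by default. Stratified
scans refuse strata below 20 samples (configurable).

## Synthetic cohort generator

The generator emulates the *statistical structure* the analysis assumes,
not the measurement process:

- **Genotypes.** Within a locus, haplotype alleles follow a first-order
  Markov copying chain: allele j copies allele j−1 with probability
  ld_decay ρ, else is drawn fresh at that variant's target frequency
  (uniform over maf_range). Adjacent-pair dosage r² is then ≈ ρ² and
  decays geometrically with marker distance — enough to exercise
  r²-graded proxy logic without a recombination map. Because copying
  mixes frequencies, the chain's marginal frequency
  m_j = ρ·m_{j−1} + (1−ρ)·f_j is recorded as each variant's target MAF.
  Dosages are sums of two independent haplotypes (no population
  structure, no Hardy–Weinberg violations). Optional imputation noise
  mixes the one-hot genotype with its HWE prior, yielding posterior
  triples (hence sub-unity INFO) and soft dosages.
- **Expression.** values = planted slopes × dosage + per-(batch, probe)
  offsets + covariate effects (on standardized covariates) + Gaussian
  noise; probes of one locus share a latent noise factor giving pairwise
  correlation probe_cor. Probes are anchored inside their locus, so
  planted effects are cis under the 4-Mb rule; the truth ledger records
  every planted (variant, probe, slope, label) exactly once. Covariate
  effects default to zero so the covariate-robustness null is the
  generator's native state.
- **Metadata.** Age, sex, CRP (left-censored below 5 → 2.5), ESR, swollen
  joint count, a three-class diagnosis drawn at the 124:113:107 mix of an
  early-arthritis clinic cohort, batch labels and standardized activation
  surrogates (CD25, CD69, IFN-γ).

What the generator does *not* emulate — microarray intensity artifacts,
probe cross-hybridization, population stratification, realistic
recombination — bounds what passing tests show: they validate the
statistical machinery (calibration, recovery, accounting), not robustness
to platform-specific measurement pathology.

One seed fixes every output bit-identically; fixtures round-trip through
the package readers exactly (floats written at 17 significant digits and
parsed in round-trip mode).

## Calibration study sizes

The family-wise error rate study uses 400 global-null cohorts of n = 100
samples, one locus family of 20 SNPs (ρ = 0.7) × 10 probes (pairwise
correlation 0.3) = 200 tests, thresholds from R = 199 replicates — sizes
at which the full stack runs in well under a minute while the ±2 binomial
SE acceptance band at α = 5% (±2.2 points) remains meaningful. The
independent-test limit check uses one cohort with ρ = 0 and uncorrelated
probes, m = 200, R = 2,000: the α = 5% threshold is compared with
1 − 0.95^(1/200) and the replicate minima with Beta(1, 200). Parameter
recovery plants slope 0.5 at MAF 0.3, noise SD 1, n = 250 over 500
replicates. Null-cohort MAFs are drawn U(0.05, 0.5), a realistic post-QC
spectrum.

## Known limitations

- No mixed models or kinship correction: samples are assumed unrelated.
- No conditional/stepwise secondary-signal analysis or colocalization.
- The Spearman statistics are descriptive; thresholds key off Pearson P.
- The trans scan is a straight extension of the cis machinery; power
  considerations at genome scale (test-family size, storage) are the
  caller's concern.
- VCF support covers DS/GP dosage fields, not called-genotype-only files.
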