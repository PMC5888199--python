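# permqtl

Cell-type eQTL mapping at disease risk loci, with experiment-wide
significance from the min-P permutation procedure.

## The problem

Genome-wide association studies of immune-mediated diseases such as
rheumatoid arthritis (RA) identify risk loci whose lead SNPs are mostly
noncoding: they tag linkage-disequilibrium (LD) blocks containing several
genes, and the causal gene is unknown. Expression quantitative trait locus
(eQTL) analysis in the relevant cell types — e.g. CD4+ T and B lymphocytes
— asks whether the risk alleles shift the expression of nearby genes,
prioritizing candidates for functional follow-up.

`permqtl` implements that analysis end to end for a cohort with genotype
dosages, a normalized expression matrix and clinical metadata:

- **genotype QC** (`permqtl.genoqc`): strict exclusion of samples and
  variants with call rate < 98%, variants with MAF < 0.01 or imputation
  INFO < 0.8 (posterior-variance form, with a dosage-variance fallback),
  plus region blacklists (the HLA interval by default) and per-variant
  quality blacklists, with first-failing-rule accounting;
- **expression preparation** (`permqtl.exprprep`): log2 variance
  stabilization + quantile normalization (or rank-based inverse-normal),
  per-probe batch regression, PCA audit of residual batch structure, probe
  blacklists and cross-platform intersection/merging;
- **risk-locus geometry** (`permqtl.loci`): expansion of index SNPs into
  LD blocks (dosage r² ≥ 0.8, inclusive), and cis/trans classification of
  probes by whether their start site lies within 4 Mb (inclusive) of the
  block span on the same chromosome;
- **association scan** (`permqtl.assoc`): per SNP–probe ordinary least
  squares of expression on additive dosage. For each pair it reports the
  slope β̂ and its SE, R² = r², the two-sided P from t = β̂/SE on n−2 df,
  Spearman's ρ, and residual diagnostics; Benjamini–Hochberg adjustment
  and lead-SNP-per-gene summaries included;
- **experiment-wide significance** (`permqtl.permnull`): R permutation
  replicates, each breaking the genotype↔expression sample linkage with a
  *single* shared permutation so LD and co-expression are preserved; the
  minimum nominal P per replicate forms the null, the α-level threshold is
  its floor(α(R+1))-th order statistic, and empirical adjusted P values are
  (1 + #{min P ≤ p})/(R + 1);
- **covariate robustness** (`permqtl.covars`): refits with age, sex, CRP,
  swollen joint count (or any metadata column) one at a time, slope deltas
  with an interaction-P extension, and diagnosis-stratified scans;
- **synthetic cohorts** (`permqtl.synthio`): a generator producing diploid
  genotypes with Markov-copying LD, expression with planted cis effects,
  batch/covariate structure and co-expression, plus clinic-style metadata
  and a truth ledger — the substrate for every calibration result below.

The pipeline (`permqtl.pipeline.run_pipeline`, YAML-configured) chains the
stages and writes TSV/JSON artifacts with provenance records; a thin CLI
(`permqtl simulate|qc|normalize|map-loci|scan|permute|covars|report|run`)
wraps the same functions.

## Worked example

`examples/` contains one narrative script per capability. For instance:

```bash
python examples/04_permutation_thresholds.py
```

prints, for a simulated two-locus cohort (n = 200, LD 0.9, one planted
cis effect of slope 0.6):

```
test family: 60 unique SNP-probe pairs, R=1999
  alpha=0.05: permutation threshold 1.556e-03 (Sidak bound for 60 independent tests: 8.545e-04)
  alpha=0.10: permutation threshold 3.277e-03 (Sidak bound for 60 independent tests: 1.754e-03)

observed min nominal P: 8.602e-07
7 SNP-probe pairs reach experiment-wide significance at alpha=5%:
     rsid    probe_id    p_nominal  p_perm
rs0000002 ILMN_000000 1.744252e-06  0.0005
...
(planted effect: rs0000005 -> ILMN_000000)
```

The permutation thresholds sit *above* the Šidák bound because the
family's SNPs are in LD and its probes co-expressed — the procedure prices
in the true effective number of tests. The planted variant and its tight
proxies are the significant pairs; `p_perm` is the empirical experiment-
wide adjusted P (floor 1/(R+1) = 0.0005 here).

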