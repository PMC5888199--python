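"""Synthetic cohort generator.

Emulates the data structure a risk-locus eQTL study consumes: biallelic
diploid genotypes organised in loci with tunable linkage disequilibrium,
expression probes anchored near each locus with optional planted additive
cis effects, batch and clinical-covariate structure, and Table-1-style
patient metadata (age, sex, acute-phase markers, joint counts, diagnosis
class). A truth ledger records every planted effect for parameter-recovery
tests.

Haplotype model
---------------
Within a locus, haplotype alleles follow a first-order Markov copying chain:
the allele at variant j copies variant j-1 with probability ``ld_decay`` and
is otherwise drawn fresh at that variant's target frequency. Adjacent
haplotypes therefore correlate at ~``ld_decay`` and pairwise dosage r^2
decays geometrically with marker distance. Diploid dosages are the sum of
two independent haplotypes.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, GenotypeMatrix
from .errors import ConfigurationError

#: Diagnosis strata mirroring an early-arthritis clinic cohort.
DIAGNOSIS_CLASSES = ("RA", "non-RA inflammatory", "noninflammatory")
#: Observed class mix (124 / 113 / 107 of 344 patients).
DIAGNOSIS_PROBS = (124 / 344, 113 / 344, 107 / 344)

#: Transcript surrogates of CD4+ T-cell activation carried in the metadata.
ACTIVATION_SURROGATES = ("cd25", "cd69", "ifng")

_LOCUS_SPACING_BP = 5_000
_LOCUS_BASE_POS = 1_000_000


@dataclass
class SimConfig:
    """Parameters of one synthetic cohort.

    ``effect_sizes`` are per-allele expression slopes planted one per locus
    (cycling over loci, then probes); an empty tuple gives a global-null
    cohort. ``probe_cor`` sets the pairwise correlation of the noise shared
    by probes of one locus, emulating co-expression. ``covar_effects`` maps
    metadata column names to slopes applied (on the standardized covariate)
    to every probe; the default of no covariate effect makes the
    covariate-robustness null recoverable. ``imputation_error`` > 0 softens
    hard genotypes into posterior triples so the INFO filter has traction.
    """

    n_samples: int = 200
    n_loci: int = 5
    snps_per_locus: int = 10
    probes_per_locus: int = 4
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_decay: float = 0.8
    effect_sizes: Sequence[float] = ()
    noise_sd: float = 1.0
    probe_cor: float = 0.0
    batch_effect_sd: float = 0.0
    n_batches: int = 2
    covar_effects: Mapping[str, float] = field(default_factory=dict)
    imputation_error: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 10:
            raise ConfigurationError("n_samples must be >= 10")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(
                f"maf_range must lie within (0, 0.5], got {self.maf_range}"
            )
        if not (0.0 <= self.ld_decay <= 1.0):
            raise ConfigurationError("ld_decay must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if not (0.0 <= self.probe_cor < 1.0):
            raise ConfigurationError("probe_cor must be in [0, 1)")
        if self.n_loci < 1 or self.snps_per_locus < 1 or self.probes_per_locus < 1:
            raise ConfigurationError("counts must be positive")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if not (0.0 <= self.imputation_error < 1.0):
            raise ConfigurationError("imputation_error must be in [0, 1)")


@dataclass
class TruthEntry:
    rsid: str
    probe_id: str
    slope: float
    label: str  # "cis" or "trans" under the 4-Mb window convention


@dataclass
class TruthLedger:
    """Every planted variant-probe effect, exactly once."""

    entries: list[TruthEntry] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.rsid, e.probe_id, e.slope, e.label) for e in self.entries],
            columns=["rsid", "probe_id", "slope", "label"],
        )


def _locus_chrom(locus: int) -> str:
    # one locus per autosome, cycling past 22 (HLA region is on 6; synthetic
    # positions start at 1 Mb so they never intersect the default blacklist)
    return str(locus % 22 + 1)


def _simulate_haplotypes(rng, n_hap: int, freqs: np.ndarray, rho: float) -> np.ndarray:
    L = len(freqs)
    H = np.empty((n_hap, L), dtype=np.int8)
    H[:, 0] = rng.random(n_hap) < freqs[0]
    for j in range(1, L):
        fresh = rng.random(n_hap) < freqs[j]
        if rho >= 1.0:
            H[:, j] = H[:, j - 1]
        elif rho <= 0.0:
            H[:, j] = fresh
        else:
            copy = rng.random(n_hap) < rho
            H[:, j] = np.where(copy, H[:, j - 1], fresh)
    return H


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Draw diploid dosages with block LD per :class:`SimConfig`.

    Variant metadata records 1-based, strictly increasing positions within
    each locus and the chain's marginal allele frequency folded to [0, 0.5]
    as ``target_maf``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    n, L = cfg.n_samples, cfg.snps_per_locus
    lo, hi = cfg.maf_range

    dosage_cols, meta_rows, rsids = [], [], []
    posteriors = [] if cfg.imputation_error > 0 else None
    for locus in range(cfg.n_loci):
        freqs = rng.uniform(lo, hi, L)
        rho = cfg.ld_decay
        h1 = _simulate_haplotypes(rng, n, freqs, rho)
        h2 = _simulate_haplotypes(rng, n, freqs, rho)
        dos = (h1 + h2).astype(float)

        # marginal frequency of the copying chain at each variant
        marg = np.empty(L)
        marg[0] = freqs[0]
        for j in range(1, L):
            marg[j] = rho * marg[j - 1] + (1 - rho) * freqs[j]

        if cfg.imputation_error > 0:
            e = cfg.imputation_error
            hwe = np.stack(
                [(1 - marg) ** 2, 2 * marg * (1 - marg), marg**2], axis=1
            )  # (L, 3)
            onehot = np.eye(3)[dos.astype(int)]  # (n, L, 3)
            post = (1 - e) * onehot + e * hwe[None, :, :]
            dos = post @ np.array([0.0, 1.0, 2.0])
            posteriors.append(post)

        if cfg.missing_rate > 0:
            miss = rng.random(dos.shape) < cfg.missing_rate
            dos = np.where(miss, np.nan, dos)
            if posteriors is not None:
                posteriors[-1] = np.where(miss[:, :, None], np.nan, posteriors[-1])

        # 50 Mb offset per pass over the autosomes keeps positions increasing
        base = _LOCUS_BASE_POS + (locus // 22) * 50_000_000
        for j in range(L):
            rsid = f"rs{locus:03d}{j:04d}"
            rsids.append(rsid)
            meta_rows.append(
                {
                    "chrom": _locus_chrom(locus),
                    "pos": base + j * _LOCUS_SPACING_BP,
                    "ref": "A",
                    "alt": "G",
                    "target_maf": float(min(marg[j], 1 - marg[j])),
                    "locus": locus,
                }
            )
        dosage_cols.append(dos)

    samples = [f"S{i:04d}" for i in range(n)]
    dosages = pd.DataFrame(
        np.concatenate(dosage_cols, axis=1), index=samples, columns=rsids
    )
    variants = pd.DataFrame(meta_rows, index=pd.Index(rsids, name="rsid"))
    post = np.concatenate(posteriors, axis=1) if posteriors is not None else None
    return GenotypeMatrix(dosages, variants, post)


def _simulate_metadata(rng, cfg: SimConfig) -> pd.DataFrame:
    n = cfg.n_samples
    age = np.clip(np.round(rng.normal(54, 13, n)), 18, 90)
    sex = (rng.random(n) < 0.7).astype(int)  # 1 = female, ~70% of cohort
    crp = np.exp(rng.normal(np.log(9.0), 0.9, n))
    crp = np.where(crp < 5.0, 2.5, np.round(crp, 1))  # "<5" -> midpoint 2.5
    esr = np.round(np.exp(rng.normal(np.log(18.0), 0.8, n)), 0)
    sjc = np.clip(rng.poisson(2.0, n), 0, 28)
    diagnosis = rng.choice(DIAGNOSIS_CLASSES, size=n, p=DIAGNOSIS_PROBS)
    batch = rng.integers(0, cfg.n_batches, n)
    meta = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "crp": crp,
            "esr": esr,
            "sjc": sjc,
            "diagnosis": diagnosis,
            "batch": [f"B{b}" for b in batch],
        },
        index=[f"S{i:04d}" for i in range(n)],
    )
    meta.index.name = "sample_id"
    for surrogate in ACTIVATION_SURROGATES:
        meta[surrogate] = rng.standard_normal(n)
    return meta


def _planted_effects(cfg: SimConfig) -> list[tuple[int, int, int, float]]:
    """Map effect_sizes to (locus, snp index, probe index, slope)."""
    planted = []
    for i, beta in enumerate(cfg.effect_sizes):
        locus = i % cfg.n_loci
        probe_idx = (i // cfg.n_loci) % cfg.probes_per_locus
        snp_idx = cfg.snps_per_locus // 2
        planted.append((locus, snp_idx, probe_idx, float(beta)))
    return planted


def simulate_expression(
    geno: GenotypeMatrix, cfg: SimConfig
) -> tuple[ExpressionMatrix, TruthLedger, pd.DataFrame]:
    """Build expression = planted effects + batch + covariates + noise.

    Probes are anchored inside their locus (so planted effects are cis under
    the 4-Mb rule); probe noise within a locus shares a latent factor giving
    pairwise correlation ``probe_cor``. Returns the matrix (already on a
    normalized scale), the truth ledger, and the sample metadata frame.
    """
    if geno.n_samples != cfg.n_samples:
        raise ConfigurationError("genotype sample count does not match SimConfig")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    n = cfg.n_samples
    meta = _simulate_metadata(rng, cfg)

    probe_ids, probe_rows = [], []
    for locus in range(cfg.n_loci):
        base = _LOCUS_BASE_POS + (locus // 22) * 50_000_000
        for k in range(cfg.probes_per_locus):
            pid = f"ILMN_{locus:03d}{k:03d}"
            probe_ids.append(pid)
            snp_anchor = (k * cfg.snps_per_locus) // cfg.probes_per_locus
            probe_rows.append(
                {
                    "gene_symbol": f"GENE{locus}_{k}",
                    "chrom": _locus_chrom(locus),
                    "start_pos": base + snp_anchor * _LOCUS_SPACING_BP + 500,
                    "blacklisted": False,
                    "locus": locus,
                }
            )
    probes = pd.DataFrame(probe_rows, index=pd.Index(probe_ids, name="probe_id"))

    P = len(probe_ids)
    values = np.zeros((n, P))

    # correlated noise: one latent factor per locus
    c = cfg.probe_cor
    for locus in range(cfg.n_loci):
        cols = np.arange(
            locus * cfg.probes_per_locus, (locus + 1) * cfg.probes_per_locus
        )
        shared = rng.standard_normal(n)
        eps = rng.standard_normal((n, len(cols)))
        values[:, cols] += cfg.noise_sd * (
            np.sqrt(c) * shared[:, None] + np.sqrt(1 - c) * eps
        )

    # batch offsets: one draw per (batch, probe)
    if cfg.batch_effect_sd > 0:
        offsets = rng.normal(0.0, cfg.batch_effect_sd, (cfg.n_batches, P))
        batch_idx = meta["batch"].str.lstrip("B").astype(int).to_numpy()
        values += offsets[batch_idx]

    # covariate effects on standardized covariates, applied to all probes
    for name, beta in cfg.covar_effects.items():
        if name not in meta.columns:
            raise ConfigurationError(f"covariate '{name}' not in metadata")
        x = pd.to_numeric(meta[name]).to_numpy(dtype=float)
        x = (x - x.mean()) / (x.std() or 1.0)
        values += float(beta) * x[:, None]

    # planted additive cis effects
    ledger = TruthLedger()
    dos = geno.dosages.to_numpy()
    for locus, snp_idx, probe_idx, beta in _planted_effects(cfg):
        col = locus * cfg.snps_per_locus + snp_idx
        if col >= geno.n_variants:
            raise ConfigurationError("planted effect refers to absent variant")
        pcol = locus * cfg.probes_per_locus + probe_idx
        d = dos[:, col]
        d = np.where(np.isnan(d), np.nanmean(d), d)
        values[:, pcol] += beta * d
        rsid = geno.rsids[col]
        pid = probe_ids[pcol]
        vpos = int(geno.variants.loc[rsid, "pos"])
        ppos = int(probes.loc[pid, "start_pos"])
        same_chrom = geno.variants.loc[rsid, "chrom"] == probes.loc[pid, "chrom"]
        label = "cis" if same_chrom and abs(ppos - vpos) <= 4_000_000 else "trans"
        ledger.entries.append(TruthEntry(rsid, pid, beta, label))

    expr = ExpressionMatrix(
        pd.DataFrame(values, index=meta.index, columns=probe_ids),
        probes,
        state="normalized",
    )
    return expr, ledger, meta


def simulate_cohort(cfg: SimConfig):
    """Convenience wrapper returning (genotypes, expression, truth, metadata)."""
    geno = simulate_genotypes(cfg)
    expr, truth, meta = simulate_expression(geno, cfg)
    return geno, expr, truth, meta


def write_fixture(
    geno: GenotypeMatrix,
    expr: ExpressionMatrix,
    meta: pd.DataFrame,
    dir_path,
    truth: TruthLedger | None = None,
    genotype_format: str = "tsv",
) -> dict[str, Path]:
    """Write a cohort as plain-text files that round-trip through permqtl.io.

    Emits genotypes (TSV dosage matrix, variants x samples, or a VCF with
    DS/GP FORMAT fields), expression TSV (probes x samples), probe
    annotation TSV, sample metadata TSV and, when given, the truth TSV.
    """
    if geno.n_samples == 0 or expr.n_samples == 0:
        raise ConfigurationError("refusing to write an empty cohort")
    out = Path(dir_path)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    if genotype_format == "tsv":
        from .io import write_genotypes_tsv

        paths["genotypes"] = write_genotypes_tsv(geno, out / "genotypes.tsv")
    elif genotype_format == "vcf":
        from .io import write_genotypes_vcf

        paths["genotypes"] = write_genotypes_vcf(geno, out / "genotypes.vcf")
    else:
        raise ConfigurationError(f"unknown genotype format '{genotype_format}'")

    expr_path = out / "expression.tsv"
    expr.values.T.to_csv(
        expr_path, sep="\t", index_label="probe_id", float_format="%.17g"
    )
    paths["expression"] = expr_path

    ann_path = out / "probes.tsv"
    cols = ["gene_symbol", "chrom", "start_pos"]
    expr.probes[cols].to_csv(ann_path, sep="\t", index_label="probe_id")
    paths["probes"] = ann_path

    meta_path = out / "samples.tsv"
    meta.to_csv(meta_path, sep="\t", index_label="sample_id")
    paths["metadata"] = meta_path

    if truth is not None:
        truth_path = out / "truth.tsv"
        truth.to_frame().to_csv(truth_path, sep="\t", index=False)
        paths["truth"] = truth_path
    return paths


def fixture_digest(paths: Mapping[str, Path]) -> dict[str, str]:
    """SHA-256 of each emitted file, for determinism audits."""
    return {
        key: hashlib.sha256(Path(p).read_bytes()).hexdigest()
        for key, p in sorted(paths.items())
    }
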