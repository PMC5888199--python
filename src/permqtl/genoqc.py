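"""Genotype quality control.

Implements the standard post-imputation filter battery for an eQTL study:
sample call rate, variant call rate, minor allele frequency and imputation
INFO score, plus chromosomal-interval blacklists (by default the HLA region,
excluded because of probe cross-hybridization and copy-number confounding)
and an externally supplied per-variant quality blacklist (stand-in for
platform-specific metrics such as raw-intensity cluster separation).

All thresholds are strict exclusions — a variant sitting exactly on a
threshold survives — and every exclusion is attributed to the first failing
rule in a fixed order: sample call rate, variant call rate, MAF, INFO,
region blacklist, quality blacklist.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import GenotypeMatrix, HLA_REGION
from .errors import EmptyResultError, UndefinedStatisticError, ValidationError

FILTER_ORDER = ("call_rate", "maf", "info", "region_blacklist", "quality_blacklist")


@dataclass
class QCThresholds:
    """Strict lower bounds; values below are excluded.

    ``min_sample_call_rate`` defaults to ``min_call_rate`` (the same 98%
    rule applies to samples and variants); it can be set separately, e.g.
    for small variant panels where a single missing call would otherwise
    condemn a sample.
    """

    min_call_rate: float = 0.98
    min_maf: float = 0.01
    min_info: float = 0.8
    min_sample_call_rate: float | None = None

    @property
    def sample_call_rate(self) -> float:
        return (
            self.min_call_rate
            if self.min_sample_call_rate is None
            else self.min_sample_call_rate
        )


@dataclass
class QCReport:
    """Per-rule exclusion accounting with first-failing-rule attribution."""

    samples_total: int = 0
    samples_removed_call_rate: int = 0
    variants_total: int = 0
    variants_removed: dict[str, int] = field(
        default_factory=lambda: {rule: 0 for rule in FILTER_ORDER}
    )
    survivors_samples: int = 0
    survivors_variants: int = 0

    def check_conservation(self) -> bool:
        ok_s = self.samples_total == self.survivors_samples + self.samples_removed_call_rate
        ok_v = self.variants_total == self.survivors_variants + sum(
            self.variants_removed.values()
        )
        return ok_s and ok_v


def compute_call_rate(dosages) -> float:
    """Fraction of non-missing entries."""
    d = np.asarray(dosages, dtype=float)
    if d.size == 0:
        raise UndefinedStatisticError("empty dosage vector")
    return float(np.mean(~np.isnan(d)))


def compute_maf(dosages) -> float:
    """Folded allele frequency min(p, 1-p) with p = mean(dosage)/2."""
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise UndefinedStatisticError("MAF undefined: all dosages missing")
    p = float(np.mean(d)) / 2.0
    return min(p, 1.0 - p)


def compute_info(posteriors) -> float:
    """IMPUTE-style measured-information ratio from genotype posteriors.

    info = 1 - mean(v_i) / (2 p (1-p)) where v_i is each sample's posterior
    genotype variance and p the posterior mean allele frequency; 1.0 by
    convention when p is 0 or 1, and clamped to [0, 1].
    """
    post = np.asarray(posteriors, dtype=float)
    if post.ndim != 2 or post.shape[1] != 3:
        raise ValidationError("posteriors must be an (n, 3) array")
    keep = ~np.isnan(post).any(axis=1)
    post = post[keep]
    if post.shape[0] == 0:
        raise UndefinedStatisticError("INFO undefined: all posteriors missing")
    if np.any(np.abs(post.sum(axis=1) - 1.0) > 1e-6) or np.any(post < -1e-9):
        raise ValidationError("posterior triples must be nonnegative and sum to 1")
    g = np.array([0.0, 1.0, 2.0])
    mean_g = post @ g
    var_g = post @ (g**2) - mean_g**2
    p = float(np.mean(mean_g)) / 2.0
    if p <= 0.0 or p >= 1.0:
        return 1.0
    info = 1.0 - float(np.mean(var_g)) / (2.0 * p * (1.0 - p))
    return float(np.clip(info, 0.0, 1.0))


def compute_info_from_dosages(dosages) -> float:
    """Dosage-variance fallback var(d) / (2 p (1-p)), clamped to [0, 1]."""
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise UndefinedStatisticError("INFO undefined: all dosages missing")
    p = float(np.mean(d)) / 2.0
    if p <= 0.0 or p >= 1.0:
        return 1.0
    return float(np.clip(np.var(d) / (2.0 * p * (1.0 - p)), 0.0, 1.0))


def annotate_variants(geno: GenotypeMatrix) -> GenotypeMatrix:
    """Attach per-variant maf, info and call_rate columns."""
    dos = geno.dosages.to_numpy(dtype=float)
    n = dos.shape[0]
    nonmiss = (~np.isnan(dos)).sum(axis=0)
    call_rate = nonmiss / n
    with np.errstate(invalid="ignore"):
        p = np.nanmean(dos, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    info = np.empty(geno.n_variants)
    for j in range(geno.n_variants):
        if nonmiss[j] == 0:
            info[j] = np.nan
            continue
        if geno.posteriors is not None:
            info[j] = compute_info(geno.posteriors[:, j, :])
        else:
            info[j] = compute_info_from_dosages(dos[:, j])
    variants = geno.variants.copy()
    variants["call_rate"] = call_rate
    variants["maf"] = maf
    variants["info"] = info
    return GenotypeMatrix(geno.dosages, variants, geno.posteriors)


def _in_region(chrom, pos, regions) -> bool:
    return any(
        str(chrom) == str(c) and start <= pos <= end for c, start, end in regions
    )


def apply_filters(
    geno: GenotypeMatrix,
    thresholds: QCThresholds | None = None,
    region_blacklist=(),
    quality_blacklist=(),
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the QC battery; returns the surviving matrix and the report.

    Sample call rate is filtered first (variant statistics are then computed
    on the surviving samples); each excluded variant is attributed to the
    first rule it fails. Raises :class:`EmptyResultError` rather than
    returning a silently empty matrix.
    """
    thr = thresholds or QCThresholds()
    quality_blacklist = set(quality_blacklist)
    report = QCReport(
        samples_total=geno.n_samples, variants_total=geno.n_variants
    )

    eps = 1e-12  # guard so values sitting exactly on a threshold survive fp noise
    dos = geno.dosages.to_numpy(dtype=float)
    sample_cr = np.mean(~np.isnan(dos), axis=1)
    keep_samples = sample_cr >= thr.sample_call_rate - eps
    report.samples_removed_call_rate = int((~keep_samples).sum())
    report.survivors_samples = int(keep_samples.sum())
    if report.survivors_samples == 0:
        raise EmptyResultError("no samples survive the call-rate filter")
    geno = geno.subset(samples=np.array(geno.sample_ids)[keep_samples])

    geno = annotate_variants(geno)
    var = geno.variants
    keep = []
    for rsid, row in var.iterrows():
        if row["call_rate"] < thr.min_call_rate - eps:
            report.variants_removed["call_rate"] += 1
        elif row["maf"] < thr.min_maf - eps:
            report.variants_removed["maf"] += 1
        elif row["info"] < thr.min_info - eps:
            report.variants_removed["info"] += 1
        elif _in_region(row["chrom"], row["pos"], region_blacklist):
            report.variants_removed["region_blacklist"] += 1
        elif rsid in quality_blacklist:
            report.variants_removed["quality_blacklist"] += 1
        else:
            keep.append(rsid)
    report.survivors_variants = len(keep)
    if not keep:
        raise EmptyResultError("no variants survive the QC filters")
    return geno.subset(variants=keep), report


__all__ = [
    "HLA_REGION",
    "QCThresholds",
    "QCReport",
    "compute_call_rate",
    "compute_maf",
    "compute_info",
    "compute_info_from_dosages",
    "annotate_variants",
    "apply_filters",
]
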