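"""Readers and writers for the pipeline's plain-text formats.

Coordinates are 1-based inclusive everywhere in memory; BED exports are
converted to 0-based half-open at the boundary. Genotypes travel either as
a TSV dosage matrix (variants x samples: rsid, chrom, pos, ref, alt, then
one column per sample) or as VCF 4.x with per-sample DS (dosage) and
optionally GP (genotype posterior) FORMAT fields.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, GenotypeMatrix
from .errors import ValidationError
from .loci import LDBlock, RiskLocus

log = logging.getLogger("permqtl.io")

_TSV_META_COLS = ["rsid", "chrom", "pos", "ref", "alt"]


# ---------------------------------------------------------------- genotypes
def write_genotypes_tsv(geno: GenotypeMatrix, path) -> Path:
    path = Path(path)
    df = geno.variants[["chrom", "pos", "ref", "alt"]].copy()
    df.insert(0, "rsid", geno.variants.index)
    dos = geno.dosages.T  # variants x samples
    out = pd.concat([df.reset_index(drop=True), dos.reset_index(drop=True)], axis=1)
    # %.17g guarantees exact float round-trip through the readers
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")
    return path


def write_genotypes_vcf(geno: GenotypeMatrix, path) -> Path:
    """Minimal VCF 4.2 with DS (and GP when posteriors are present)."""
    path = Path(path)
    has_gp = geno.posteriors is not None
    fmt = "DS:GP" if has_gp else "DS"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        if has_gp:
            fh.write(
                '##FORMAT=<ID=GP,Number=3,Type=Float,Description="Genotype posterior">\n'
            )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.sample_ids)
            + "\n"
        )
        dos = geno.dosages.to_numpy(dtype=float)
        for j, (rsid, row) in enumerate(geno.variants.iterrows()):
            fields = [
                str(row["chrom"]),
                str(int(row["pos"])),
                str(rsid),
                str(row.get("ref", "A")),
                str(row.get("alt", "G")),
                ".",
                "PASS",
                ".",
                fmt,
            ]
            for i in range(geno.n_samples):
                d = dos[i, j]
                if np.isnan(d):
                    cell = "." if not has_gp else ".:.,.,."
                else:
                    cell = format(d, "g")
                    if has_gp:
                        gp = geno.posteriors[i, j]
                        cell += ":" + ",".join(format(x, "g") for x in gp)
                fields.append(cell)
            fh.write("\t".join(fields) + "\n")
    return path


def _read_genotypes_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, float_precision="round_trip")
    missing = [c for c in _TSV_META_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"dosage TSV missing columns {missing}")
    if df["rsid"].duplicated().any():
        dups = sorted(df.loc[df["rsid"].duplicated(), "rsid"])
        raise ValidationError(f"duplicate rsids in {path}: {dups}")
    sample_cols = [c for c in df.columns if c not in _TSV_META_COLS]
    dosages = df[sample_cols].to_numpy(dtype=float).T  # samples x variants
    variants = df[["chrom", "pos", "ref", "alt"]].copy()
    variants.index = pd.Index(df["rsid"], name="rsid")
    return GenotypeMatrix(
        pd.DataFrame(dosages, index=sample_cols, columns=variants.index),
        variants,
    )


def _read_genotypes_vcf(path: Path) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ValidationError("cyvcf2 is required to read VCF input") from exc
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rsids, rows, dosage_cols, gp_cols = [], [], [], []
    clamped = 0
    any_gp = False
    def _fmt(variant, key):
        try:
            return variant.format(key)
        except KeyError:  # field not declared in the header
            return None

    for v in vcf:
        rsid = v.ID or f"{v.CHROM}:{v.POS}"
        ds = _fmt(v, "DS")
        gp = _fmt(v, "GP")
        if ds is not None:
            d = np.asarray(ds, dtype=float).reshape(len(samples))
        elif gp is not None:
            g = np.asarray(gp, dtype=float).reshape(len(samples), 3)
            d = g @ np.array([0.0, 1.0, 2.0])
        else:
            raise ValidationError(
                f"{path}: record {rsid} carries neither DS nor GP"
            )
        d = np.where(np.isfinite(d), d, np.nan)
        out_of_range = (d < 0) | (d > 2)
        clamped += int(np.nansum(out_of_range))
        d = np.clip(d, 0.0, 2.0)
        rsids.append(rsid)
        rows.append(
            {"chrom": v.CHROM, "pos": v.POS, "ref": v.REF, "alt": ",".join(v.ALT)}
        )
        dosage_cols.append(d)
        if gp is not None:
            any_gp = True
            gp_cols.append(np.asarray(gp, dtype=float).reshape(len(samples), 3))
        else:
            gp_cols.append(np.full((len(samples), 3), np.nan))
    if clamped:
        log.warning("%d dosages outside [0, 2] clamped while reading %s", clamped, path)
    if len(set(rsids)) != len(rsids):
        raise ValidationError(f"duplicate variant ids in {path}")
    dosages = pd.DataFrame(
        np.column_stack(dosage_cols), index=samples, columns=rsids
    )
    variants = pd.DataFrame(rows, index=pd.Index(rsids, name="rsid"))
    posteriors = np.stack(gp_cols, axis=1) if any_gp else None
    return GenotypeMatrix(dosages, variants, posteriors)


def read_genotypes(path) -> GenotypeMatrix:
    """Read a dosage TSV or a VCF (by extension)."""
    path = Path(path)
    if path.suffix in (".vcf", ".gz", ".bcf"):
        return _read_genotypes_vcf(path)
    return _read_genotypes_tsv(path)


# --------------------------------------------------------------- expression
def read_probe_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"probe_id", "gene_symbol", "chrom", "start_pos"}
    missing = required - set(ann.columns)
    if missing:
        raise ValidationError(f"probe annotation missing columns {sorted(missing)}")
    if ann["probe_id"].duplicated().any():
        dups = sorted(ann.loc[ann["probe_id"].duplicated(), "probe_id"])
        raise ValidationError(f"duplicate probe ids in annotation: {dups}")
    ann = ann.set_index("probe_id")
    if "blacklisted" not in ann.columns:
        ann["blacklisted"] = False
    return ann


def read_expression(path, annotation_path, state: str = "raw") -> ExpressionMatrix:
    """Read an expression TSV; orientation auto-detected via annotation ids.

    Probes without annotation are retained in the matrix (with missing
    coordinates, hence excluded from cis/trans classification) and logged.
    """
    ann = read_probe_annotation(annotation_path)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    known = set(ann.index)
    hits_rows = sum(1 for x in df.index if x in known)
    hits_cols = sum(1 for x in df.columns if x in known)
    if hits_cols > hits_rows:
        values = df  # already samples x probes
    else:
        values = df.T
    values.index = values.index.astype(str)
    if values.columns.duplicated().any():
        dups = sorted(values.columns[values.columns.duplicated()])
        raise ValidationError(f"duplicate probe ids in {path}: {dups}")
    probes = ann.reindex(values.columns)
    unannotated = probes.index[probes["chrom"].isna()].tolist()
    if unannotated:
        log.info(
            "%d probes lack annotation and will be excluded from cis/trans "
            "classification: %s",
            len(unannotated),
            unannotated[:10],
        )
    probes.index.name = "probe_id"
    return ExpressionMatrix(values.astype(float), probes, state=state)


def read_sample_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col="sample_id")
    meta.index = meta.index.astype(str)
    return meta


def read_index_snps(path) -> list[RiskLocus]:
    """Index-SNP TSV: rsid, chrom, pos[, locus_label]."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"rsid", "chrom", "pos"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"index-SNP list missing columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            RiskLocus(
                index_rsid=str(row["rsid"]),
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                locus_label=str(row.get("locus_label", row["rsid"])),
            )
        )
    return out


# ------------------------------------------------------------------ outputs
def write_blocks(blocks: list[LDBlock], bed_path, members_path) -> None:
    """Block spans as BED (0-based half-open) plus a membership TSV."""
    with open(bed_path, "w") as fh:
        for b in blocks:
            chrom, start, end = b.span
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{b.index.locus_label}\n")
    rows = []
    for b in blocks:
        for _, m in b.members.iterrows():
            rows.append(
                {
                    "locus_label": b.index.locus_label,
                    "index_rsid": b.index.index_rsid,
                    "rsid": m["rsid"],
                    "pos": int(m["pos"]),
                    "r2": m["r2"],
                }
            )
    pd.DataFrame(rows).to_csv(members_path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
    return path
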