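"""Risk-locus LD blocks and cis/trans probe classification.

An index SNP tags a risk locus; its LD block is the index plus every
variant within a search window whose dosage correlation satisfies
r^2 >= 0.8 (inclusive). A probe is *cis* to a locus when its start site
lies on the same chromosome within 4 Mb of the block's span (inclusive,
distance measured from the span edges); everything else — including other
chromosomes — is *trans*.

The LD estimator is the composite r^2: the squared Pearson correlation of
dosage vectors over complete pairs. It needs no phase information, so it
applies equally to hard calls and imputed dosages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenotypeMatrix
from .errors import UndefinedStatisticError

DEFAULT_R2_MIN = 0.8
DEFAULT_SEARCH_WINDOW_BP = 1_000_000
DEFAULT_CIS_WINDOW_BP = 4_000_000


@dataclass(frozen=True)
class RiskLocus:
    index_rsid: str
    chrom: str
    pos: int
    locus_label: str


@dataclass
class LDBlock:
    """An index SNP with its r^2-qualified proxies and their genomic span."""

    index: RiskLocus
    members: pd.DataFrame  # columns rsid, pos, r2; includes the index itself
    span: tuple[str, int, int]

    @property
    def member_rsids(self) -> list[str]:
        return list(self.members["rsid"])


def compute_ld_r2(dosages_a, dosages_b) -> float:
    """Composite LD: squared Pearson correlation of two dosage vectors."""
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors must have equal length")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if a.size < 3:
        raise UndefinedStatisticError("fewer than 3 complete pairs")
    if np.var(a) == 0 or np.var(b) == 0:
        raise UndefinedStatisticError("monomorphic input: r^2 undefined")
    r = np.corrcoef(a, b)[0, 1]
    return float(min(r * r, 1.0))


def build_ld_blocks(
    risk_loci: list[RiskLocus],
    geno: GenotypeMatrix,
    r2_min: float = DEFAULT_R2_MIN,
    search_window_bp: int = DEFAULT_SEARCH_WINDOW_BP,
) -> tuple[list[LDBlock], list[str]]:
    """Expand each index SNP into its LD block.

    Candidate proxies are the variants on the index chromosome within
    ``search_window_bp`` of the index position; membership requires
    r^2 >= ``r2_min`` (inclusive). Index SNPs absent from the genotypes
    (and those monomorphic in the cohort) are skipped and reported in the
    second return value.
    """
    blocks: list[LDBlock] = []
    skipped: list[str] = []
    var = geno.variants
    dos = geno.dosages
    for locus in risk_loci:
        if locus.index_rsid not in dos.columns:
            skipped.append(locus.index_rsid)
            continue
        idx_dos = dos[locus.index_rsid].to_numpy(dtype=float)
        if np.nanvar(idx_dos) == 0:
            skipped.append(locus.index_rsid)
            continue
        same_chrom = var["chrom"].astype(str) == str(locus.chrom)
        near = (var["pos"] - locus.pos).abs() <= search_window_bp
        candidates = var.index[same_chrom & near]
        rows = []
        for rsid in candidates:
            if rsid == locus.index_rsid:
                rows.append((rsid, int(var.loc[rsid, "pos"]), 1.0))
                continue
            try:
                r2 = compute_ld_r2(idx_dos, dos[rsid].to_numpy(dtype=float))
            except UndefinedStatisticError:
                continue
            if r2 >= r2_min:
                rows.append((rsid, int(var.loc[rsid, "pos"]), r2))
        members = pd.DataFrame(rows, columns=["rsid", "pos", "r2"]).sort_values(
            "pos", kind="stable", ignore_index=True
        )
        span = (str(locus.chrom), int(members["pos"].min()), int(members["pos"].max()))
        blocks.append(LDBlock(locus, members, span))
    return blocks, skipped


def _span_distance(start: int, span_min: int, span_max: int) -> int:
    if span_min <= start <= span_max:
        return 0
    return min(abs(start - span_min), abs(start - span_max))


def classify_probes(
    blocks: list[LDBlock],
    probes: pd.DataFrame,
    window_bp: int = DEFAULT_CIS_WINDOW_BP,
) -> pd.DataFrame:
    """Assign each annotated probe a cis/trans class per LD block.

    ``probes`` is indexed by probe id with ``chrom`` and ``start_pos``
    columns; probes with missing coordinates are excluded (returned rows
    cover every placed probe x block combination). ``within window`` is
    inclusive: a start exactly ``window_bp`` beyond a span edge is cis.
    """
    placed = probes.dropna(subset=["chrom", "start_pos"])
    rows = []
    for block in blocks:
        chrom, span_min, span_max = block.span
        for pid, prow in placed.iterrows():
            start = int(prow["start_pos"])
            if str(prow["chrom"]) == chrom:
                dist = _span_distance(start, span_min, span_max)
                cls = "cis" if dist <= window_bp else "trans"
            else:
                dist = -1  # distance undefined across chromosomes
                cls = "trans"
            rows.append(
                {
                    "probe_id": pid,
                    "locus_label": block.index.locus_label,
                    "class": cls,
                    "distance_bp": dist,
                }
            )
    return pd.DataFrame(rows, columns=["probe_id", "locus_label", "class", "distance_bp"])


def blocks_from_simulation(
    geno: GenotypeMatrix, r2_min: float = DEFAULT_R2_MIN, search_window_bp: int = DEFAULT_SEARCH_WINDOW_BP
) -> tuple[list[LDBlock], list[str]]:
    """Treat each simulated locus's central variant as the risk index SNP.

    Convenience for synthetic cohorts carrying a ``locus`` column in their
    variant metadata.
    """
    risk = []
    for locus_id, group in geno.variants.groupby("locus", sort=True):
        mid = group.index[len(group) // 2]
        risk.append(
            RiskLocus(
                index_rsid=mid,
                chrom=str(group.loc[mid, "chrom"]),
                pos=int(group.loc[mid, "pos"]),
                locus_label=f"L{locus_id}",
            )
        )
    return build_ld_blocks(risk, geno, r2_min=r2_min, search_window_bp=search_window_bp)
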