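"""Per SNP-probe association scan.

Each test is an ordinary least squares fit of expression on additive allele
dosage with an intercept. The reported R^2 is the squared Pearson
correlation and the nominal P value comes from the two-sided t test of the
slope on n-2 degrees of freedom (algebraically the Pearson correlation
test). Spearman's rho is reported alongside as a rank-based companion
statistic, and residual diagnostics (skewness, excess kurtosis, a
Breusch-Pagan-style heteroscedasticity score) are attached for model-
assumption review — they flag, but never drop, results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._stats import pairwise_ols
from .core import ExpressionMatrix, GenotypeMatrix
from .errors import EmptyResultError, UndefinedStatisticError
from .genoqc import compute_maf
from .loci import LDBlock

RESULT_COLUMNS = [
    "locus_label",
    "rsid",
    "pos",
    "probe_id",
    "gene_symbol",
    "class",
    "n",
    "slope",
    "se",
    "r_squared",
    "p_nominal",
    "rho",
    "p_rho",
    "maf",
    "r2_with_index",
]


@dataclass
class AssociationResult:
    """One SNP-probe linear-model test."""

    rsid: str
    probe_id: str
    n: int
    slope: float
    se: float
    r_squared: float
    p_nominal: float
    rho: float = np.nan
    p_rho: float = np.nan
    maf: float = np.nan
    gene_symbol: str = ""
    locus_label: str = ""
    cls: str = ""
    r2_with_index: float = np.nan
    flagged: bool = False
    diagnostics: dict = field(default_factory=dict)


def _residual_diagnostics(dosage, expression, slope, intercept) -> dict:
    resid = expression - (intercept + slope * dosage)
    n = resid.size
    out = {
        "resid_skewness": float(stats.skew(resid)),
        "resid_kurtosis": float(stats.kurtosis(resid)),
    }
    # Breusch-Pagan LM score: n * R^2 of squared residuals on the dosage
    u2 = resid**2
    vx = np.var(dosage)
    if vx > 0 and np.var(u2) > 0:
        r = np.corrcoef(dosage, u2)[0, 1]
        lm = n * r * r
        out["bp_score"] = float(lm)
        out["bp_p"] = float(stats.chi2.sf(lm, df=1))
    else:
        out["bp_score"] = 0.0
        out["bp_p"] = 1.0
    return out


def fit_snp_probe(
    dosage, expression, compute_spearman: bool = True, diagnostics: bool = True
) -> AssociationResult:
    """OLS of expression on dosage over complete cases.

    Raises :class:`UndefinedStatisticError` for a monomorphic dosage;
    constant expression yields slope 0, R^2 0, P 1 with ``flagged=True``.
    """
    d = np.asarray(dosage, dtype=float)
    y = np.asarray(expression, dtype=float)
    keep = ~(np.isnan(d) | np.isnan(y))
    d, y = d[keep], y[keep]
    if d.size < 3:
        raise UndefinedStatisticError("fewer than 3 complete pairs")
    res = pairwise_ols(d[:, None], y[:, None])
    if res["flag_monomorphic"][0, 0]:
        raise UndefinedStatisticError("monomorphic dosage")
    flagged = bool(res["flag_constant_expression"][0, 0])
    rho = p_rho = np.nan
    if compute_spearman and not flagged:
        rho, p_rho = stats.spearmanr(d, y)
    out = AssociationResult(
        rsid="",
        probe_id="",
        n=int(res["n"][0, 0]),
        slope=float(res["slope"][0, 0]),
        se=float(res["se"][0, 0]),
        r_squared=float(res["r2"][0, 0]),
        p_nominal=float(res["p"][0, 0]),
        rho=float(rho),
        p_rho=float(p_rho),
        maf=compute_maf(d),
        flagged=flagged,
    )
    if diagnostics and not flagged:
        out.diagnostics = _residual_diagnostics(
            d, y, out.slope, float(res["intercept"][0, 0])
        )
    return out


def build_pairs(
    blocks: list[LDBlock], assignments: pd.DataFrame, expr: ExpressionMatrix, mode: str
) -> pd.DataFrame:
    """Enumerate (locus, member SNP, probe) test pairs for one class.

    ``assignments`` is the classify_probes output. Ordering is
    deterministic: locus label, member position, probe id.
    """
    if mode not in ("cis", "trans"):
        raise ValueError("mode must be 'cis' or 'trans'")
    frames = []
    for block in sorted(blocks, key=lambda b: b.index.locus_label):
        label = block.index.locus_label
        probe_ids = assignments.loc[
            (assignments["locus_label"] == label)
            & (assignments["class"] == mode)
            & (assignments["probe_id"].isin(expr.probe_ids)),
            "probe_id",
        ].tolist()
        if not probe_ids:
            continue
        members = block.members.sort_values(["pos", "rsid"], kind="stable")
        for _, mrow in members.iterrows():
            frames.append(
                pd.DataFrame(
                    {
                        "locus_label": label,
                        "rsid": mrow["rsid"],
                        "pos": int(mrow["pos"]),
                        "probe_id": sorted(probe_ids),
                        "r2_with_index": mrow["r2"],
                    }
                )
            )
    if not frames:
        return pd.DataFrame(
            columns=["locus_label", "rsid", "pos", "probe_id", "r2_with_index"]
        )
    return pd.concat(frames, ignore_index=True)


def scan(
    geno: GenotypeMatrix,
    expr: ExpressionMatrix,
    blocks: list[LDBlock],
    assignments: pd.DataFrame,
    mode: str = "cis",
    compute_spearman: bool = True,
) -> pd.DataFrame:
    """Vectorized association scan over every block-member x probe pair.

    Samples are intersected between genotype and expression matrices (in
    genotype order); statistics per pair use pairwise complete cases.
    """
    shared = [s for s in geno.sample_ids if s in set(expr.sample_ids)]
    if not shared:
        raise EmptyResultError("no overlapping samples between genotypes and expression")
    pairs = build_pairs(blocks, assignments, expr, mode)
    if pairs.empty:
        return pd.DataFrame(columns=RESULT_COLUMNS)

    snps = pairs["rsid"].drop_duplicates().tolist()
    probes = pairs["probe_id"].drop_duplicates().tolist()
    G = geno.subset(samples=shared, variants=snps).dosages.to_numpy(dtype=float)
    E = expr.subset(samples=shared, probes=probes).values.to_numpy(dtype=float)
    grid = pairwise_ols(G, E)
    snp_pos = {s: i for i, s in enumerate(snps)}
    probe_pos = {p: i for i, p in enumerate(probes)}
    si = pairs["rsid"].map(snp_pos).to_numpy()
    pj = pairs["probe_id"].map(probe_pos).to_numpy()

    out = pairs.copy()
    out["gene_symbol"] = out["probe_id"].map(expr.probes["gene_symbol"])
    out["class"] = mode
    out["n"] = grid["n"][si, pj].astype(int)
    out["slope"] = grid["slope"][si, pj]
    out["se"] = grid["se"][si, pj]
    out["r_squared"] = grid["r2"][si, pj]
    out["p_nominal"] = grid["p"][si, pj]
    mafs = {s: compute_maf(G[:, snp_pos[s]]) for s in snps}
    out["maf"] = out["rsid"].map(mafs)

    if compute_spearman:
        rho = np.full(len(out), np.nan)
        p_rho = np.full(len(out), np.nan)
        for k, (i, j) in enumerate(zip(si, pj)):
            d, y = G[:, i], E[:, j]
            keep = ~(np.isnan(d) | np.isnan(y))
            if keep.sum() >= 3 and np.var(y[keep]) > 0 and np.var(d[keep]) > 0:
                rho[k], p_rho[k] = stats.spearmanr(d[keep], y[keep])
        out["rho"] = rho
        out["p_rho"] = p_rho
    else:
        out["rho"] = np.nan
        out["p_rho"] = np.nan

    out = out[RESULT_COLUMNS].sort_values(
        ["locus_label", "rsid", "probe_id"], kind="stable", ignore_index=True
    )
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def lead_per_gene(results: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Lead (minimum-P) SNP per probe plus the count of significant SNPs.

    Ties on P break by genomic position via the deterministic result
    ordering (position-sorted members), then rsid.
    """
    if results.empty:
        return pd.DataFrame(
            columns=[
                "probe_id",
                "gene_symbol",
                "locus_label",
                "lead_rsid",
                "maf",
                "p_nominal",
                "r2_with_index",
                "n_significant_snps",
            ]
        )
    rows = []
    for probe_id, group in results.groupby("probe_id", sort=True):
        best = group.sort_values(
            ["p_nominal", "pos", "rsid"], kind="stable"
        ).iloc[0]
        rows.append(
            {
                "probe_id": probe_id,
                "gene_symbol": best["gene_symbol"],
                "locus_label": best["locus_label"],
                "lead_rsid": best["rsid"],
                "maf": best["maf"],
                "p_nominal": best["p_nominal"],
                "r2_with_index": best["r2_with_index"],
                "n_significant_snps": int((group["p_nominal"] <= threshold).sum()),
            }
        )
    return pd.DataFrame(rows).sort_values("p_nominal", ignore_index=True)


def manhattan_table(results: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready table: locus order, -log10 P and class per pair."""
    out = results[["locus_label", "rsid", "pos", "probe_id", "class", "p_nominal"]].copy()
    out["neg_log10_p"] = -np.log10(out["p_nominal"])
    return out
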