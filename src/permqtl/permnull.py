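"""Experiment-wide significance by the min-P permutation procedure.

Each permutation replicate breaks the genotype-expression sample linkage
with ONE random permutation shared by every SNP and probe in the test
family, rescans the whole family, and records the minimum nominal P value.
Sharing a single permutation per replicate preserves LD among SNPs and
co-expression among probes, so the null distribution of the minimum
reflects the true effective number of tests. The alpha-level threshold is
the floor(alpha*(R+1))-th smallest replicate minimum — a conservative,
integer-deterministic order-statistic convention — and a nominal P is
experiment-wide significant iff it is <= the threshold (inclusive).

When covariates are part of the model they travel WITH the expression side
of the permutation, preserving the covariate-expression relationship.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import pairwise_ols
from .assoc import build_pairs
from .core import ExpressionMatrix, GenotypeMatrix
from .errors import EmptyResultError, ValidationError
from .loci import LDBlock

DEFAULT_ALPHAS = (0.05, 0.10)
MIN_REPLICATES = 100


@dataclass
class PermutationNull:
    """Null distribution of the per-replicate minimum nominal P."""

    min_p: np.ndarray
    n_tests: int
    R: int
    seed: int
    observed_min_p: float = np.nan
    alpha_thresholds: dict[float, float] = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "R": self.R,
            "n_tests": self.n_tests,
            "seed": self.seed,
            "observed_min_p": float(self.observed_min_p),
            "alpha_thresholds": {
                str(a): float(t) for a, t in sorted(self.alpha_thresholds.items())
            },
        }


def _family_matrices(geno, expr, blocks, assignments, mode):
    """Unique-SNP and unique-probe matrices plus the pair membership mask."""
    shared = [s for s in geno.sample_ids if s in set(expr.sample_ids)]
    if not shared:
        raise EmptyResultError("no overlapping samples between genotypes and expression")
    pairs = build_pairs(blocks, assignments, expr, mode)
    if pairs.empty:
        raise EmptyResultError(f"no {mode} SNP-probe pairs to test")
    snps = pairs["rsid"].drop_duplicates().tolist()
    probes = pairs["probe_id"].drop_duplicates().tolist()
    G = geno.subset(samples=shared, variants=snps).dosages.to_numpy(dtype=float)
    E = expr.subset(samples=shared, probes=probes).values.to_numpy(dtype=float)
    mask = np.zeros((len(snps), len(probes)), dtype=bool)
    snp_pos = {s: i for i, s in enumerate(snps)}
    probe_pos = {p: i for i, p in enumerate(probes)}
    uniq = pairs[["rsid", "probe_id"]].drop_duplicates()
    mask[uniq["rsid"].map(snp_pos), uniq["probe_id"].map(probe_pos)] = True
    return G, E, mask


def _masked_min_p(G, E, mask) -> float:
    p = pairwise_ols(G, E)["p"]
    vals = p[mask]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise EmptyResultError("every test in the family is degenerate")
    return float(vals.min())


def permute_scan(
    geno: GenotypeMatrix,
    expr: ExpressionMatrix,
    blocks: list[LDBlock],
    assignments: pd.DataFrame,
    R: int = 10_000,
    seed: int = 0,
    mode: str = "cis",
    alphas=DEFAULT_ALPHAS,
) -> PermutationNull:
    """Build the min-P permutation null for one test family.

    Refuses R < 100 (the alpha quantiles are unstable below that). The
    returned object also records the observed (unpermuted) minimum nominal
    P and the thresholds for ``alphas``.
    """
    if R < MIN_REPLICATES:
        raise ValidationError(f"R={R} too small; need at least {MIN_REPLICATES}")
    G, E, mask = _family_matrices(geno, expr, blocks, assignments, mode)
    n = G.shape[0]
    rng = np.random.default_rng(seed)
    min_p = np.empty(R)
    for r in range(R):
        perm = rng.permutation(n)
        min_p[r] = _masked_min_p(G, E[perm], mask)
    null = PermutationNull(
        min_p=min_p,
        n_tests=int(mask.sum()),
        R=R,
        seed=seed,
        observed_min_p=_masked_min_p(G, E, mask),
    )
    null.alpha_thresholds = derive_thresholds(null, alphas)
    return null


def derive_thresholds(null: PermutationNull, alphas=DEFAULT_ALPHAS) -> dict[float, float]:
    """Alpha-level thresholds: the floor(alpha*(R+1))-th smallest min-P."""
    R = len(null.min_p)
    sorted_min_p = np.sort(null.min_p)
    out = {}
    for alpha in alphas:
        k = int(np.floor(alpha * (R + 1)))
        if k < 1:
            raise ValidationError(
                f"R={R} too small for alpha={alpha}: floor(alpha*(R+1)) = 0"
            )
        out[float(alpha)] = float(sorted_min_p[min(k, R) - 1])
    return out


def empirical_adjusted_p(p_observed, null: PermutationNull):
    """Single-step empirical adjusted P: (1 + #{min_p <= p}) / (R + 1).

    Monotone nondecreasing in the observed P; the smallest attainable value
    is 1/(R+1). Accepts a scalar or an array.
    """
    p = np.asarray(p_observed, dtype=float)
    sorted_min_p = np.sort(null.min_p)
    R = len(sorted_min_p)
    counts = np.searchsorted(sorted_min_p, p, side="right")
    adj = (1.0 + counts) / (R + 1.0)
    adj = np.minimum(adj, 1.0)
    return float(adj) if np.isscalar(p_observed) else adj
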