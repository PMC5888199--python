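"""Simulation harnesses validating the permutation procedure's calibration.

These drive the whole stack — cohort simulation, LD-block construction,
cis classification, the association scan and the min-P permutation null —
to measure the empirical family-wise error rate (FWER) of the
experiment-wide thresholds on global-null cohorts, and to compare the
correlated-data thresholds against the independent-test (Sidak) limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import assoc, loci, permnull
from .synthio import SimConfig, simulate_cohort

#: Null-cohort conditions for the FWER study: one risk-locus family of 20
#: LD-correlated SNPs x 10 co-expressed probes (200 tests) in 100 samples.
NULL_COHORT = dict(
    n_samples=100,
    n_loci=1,
    snps_per_locus=20,
    probes_per_locus=10,
    maf_range=(0.05, 0.5),
    ld_decay=0.7,
    probe_cor=0.3,
    effect_sizes=(),
    noise_sd=1.0,
)


def _child_seed(seq: np.random.SeedSequence) -> int:
    return int(seq.generate_state(1, dtype=np.uint32)[0] % (2**31))


def null_cohort_scan(
    cohort_seed: int,
    perm_seed: int,
    R: int = 199,
    alphas=(0.05, 0.10),
    overrides: dict | None = None,
):
    """Simulate one cohort, scan it, and build its permutation null.

    The test family is every locus SNP x every cis probe (LD blocks built
    with r2_min=0 so the family matches the simulated locus exactly).
    Returns (observed results DataFrame, PermutationNull).
    """
    params = dict(NULL_COHORT)
    if overrides:
        params.update(overrides)
    cfg = SimConfig(seed=cohort_seed, **params)
    geno, expr, _, _ = simulate_cohort(cfg)
    blocks, _ = loci.blocks_from_simulation(geno, r2_min=0.0)
    assignments = loci.classify_probes(blocks, expr.probes)
    results = assoc.scan(
        geno, expr, blocks, assignments, mode="cis", compute_spearman=False
    )
    null = permnull.permute_scan(
        geno, expr, blocks, assignments, R=R, seed=perm_seed, alphas=alphas
    )
    return results, null


@dataclass
class FWERResult:
    """Empirical FWER per alpha level over the simulated null cohorts."""

    n_cohorts: int
    R: int
    n_tests: int
    rejections: dict[float, np.ndarray]  # alpha -> bool per cohort
    fwer: dict[float, float] = field(default_factory=dict)

    def __post_init__(self):
        self.fwer = {a: float(np.mean(v)) for a, v in self.rejections.items()}

    def binomial_se(self, alpha: float) -> float:
        return float(np.sqrt(alpha * (1 - alpha) / self.n_cohorts))


def fwer_calibration(
    n_cohorts: int = 400,
    R: int = 199,
    alphas=(0.05, 0.10),
    seed: int = 0,
    overrides: dict | None = None,
) -> FWERResult:
    """Empirical FWER of the permutation thresholds on global-null cohorts.

    For each cohort the experiment-wide threshold at each alpha is derived
    from R permutation replicates, and a family-wise rejection is recorded
    when any observed nominal P falls at or below it. With no planted
    effects the rejection fraction estimates the FWER and should match the
    nominal alpha.
    """
    root = np.random.SeedSequence(seed)
    rejections = {a: np.zeros(n_cohorts, dtype=bool) for a in alphas}
    n_tests = 0
    for i, child in enumerate(root.spawn(n_cohorts)):
        s1, s2 = child.spawn(2)
        results, null = null_cohort_scan(
            _child_seed(s1), _child_seed(s2), R=R, alphas=alphas, overrides=overrides
        )
        obs_min = float(results["p_nominal"].min())
        n_tests = null.n_tests
        for a in alphas:
            rejections[a][i] = obs_min <= null.alpha_thresholds[a]
    return FWERResult(n_cohorts=n_cohorts, R=R, n_tests=n_tests, rejections=rejections)


def sidak_threshold(alpha: float, m: int) -> float:
    """Independent-test limit of the experiment-wide threshold."""
    return 1.0 - (1.0 - alpha) ** (1.0 / m)


def independent_limit(
    R: int = 2000, alpha: float = 0.05, seed: int = 0
) -> tuple[permnull.PermutationNull, float]:
    """Permutation null for one cohort with independent SNPs and probes.

    Returns the null and the matching Sidak threshold; with ld_decay=0 and
    probe_cor=0 the permutation threshold should approach it and the min-P
    distribution should follow Beta(1, m).
    """
    root = np.random.SeedSequence(seed)
    s1, s2 = root.spawn(2)
    _, null = null_cohort_scan(
        _child_seed(s1),
        _child_seed(s2),
        R=R,
        alphas=(alpha,),
        overrides={"ld_decay": 0.0, "probe_cor": 0.0},
    )
    return null, sidak_threshold(alpha, null.n_tests)
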