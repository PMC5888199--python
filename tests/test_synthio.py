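"""Synthetic cohort generator: LD structure, planted effects, determinism."""

import numpy as np
import pandas as pd
import pytest

from permqtl import io, loci, synthio
from permqtl.assoc import fit_snp_probe
from permqtl.errors import ConfigurationError
from permqtl.loci import compute_ld_r2
from permqtl.synthio import SimConfig, fixture_digest, simulate_cohort, simulate_genotypes


def test_invalid_maf_range_rejected():
    with pytest.raises(ConfigurationError):
        SimConfig(maf_range=(0.0, 0.5))
    with pytest.raises(ConfigurationError):
        SimConfig(maf_range=(0.1, 0.6))
    with pytest.raises(ConfigurationError):
        SimConfig(n_samples=5)


def test_perfect_copying_gives_identical_columns():
    cfg = SimConfig(n_samples=50, n_loci=1, snps_per_locus=2, ld_decay=1.0, seed=1)
    geno = simulate_genotypes(cfg)
    a, b = geno.dosages.iloc[:, 0], geno.dosages.iloc[:, 1]
    assert (a == b).all()
    assert compute_ld_r2(a, b) == pytest.approx(1.0)


def test_no_copying_gives_independent_columns():
    cfg = SimConfig(
        n_samples=10_000, n_loci=1, snps_per_locus=2, ld_decay=0.0,
        maf_range=(0.3, 0.5), seed=2,
    )
    geno = simulate_genotypes(cfg)
    r2 = compute_ld_r2(geno.dosages.iloc[:, 0], geno.dosages.iloc[:, 1])
    assert r2 < 0.01


def _oracle_adjacent_r2(rho, maf, n, L, seed):
    """Independent forward simulation of the copying chain, written from
    scratch: mean adjacent-pair dosage r^2."""
    rng = np.random.default_rng(seed)
    haps = []
    for _ in range(2):
        H = np.empty((n, L))
        H[:, 0] = rng.random(n) < maf
        for j in range(1, L):
            copy = rng.random(n) < rho
            H[:, j] = np.where(copy, H[:, j - 1], rng.random(n) < maf)
        haps.append(H)
    dos = haps[0] + haps[1]
    r2s = [
        np.corrcoef(dos[:, j], dos[:, j + 1])[0, 1] ** 2 for j in range(L - 1)
    ]
    return float(np.mean(r2s))


def test_adjacent_r2_matches_forward_simulation_oracle():
    cfg = SimConfig(
        n_samples=5000, n_loci=1, snps_per_locus=10, ld_decay=0.9,
        maf_range=(0.3, 0.3), seed=3,
    )
    geno = simulate_genotypes(cfg)
    dos = geno.dosages.to_numpy()
    observed = np.mean(
        [np.corrcoef(dos[:, j], dos[:, j + 1])[0, 1] ** 2 for j in range(9)]
    )
    expected = _oracle_adjacent_r2(rho=0.9, maf=0.3, n=5000, L=10, seed=99)
    assert observed == pytest.approx(expected, abs=0.03)


def test_seed_fixes_everything_bit_identically():
    cfg = SimConfig(n_samples=40, n_loci=2, snps_per_locus=4, seed=11)
    g1, e1, t1, m1 = simulate_cohort(cfg)
    g2, e2, t2, m2 = simulate_cohort(cfg)
    pd.testing.assert_frame_equal(g1.dosages, g2.dosages)
    pd.testing.assert_frame_equal(e1.values, e2.values)
    pd.testing.assert_frame_equal(m1, m2)
    assert t1.to_frame().equals(t2.to_frame())


def test_realized_maf_within_3_binomial_se_of_target():
    cfg = SimConfig(n_samples=400, n_loci=4, snps_per_locus=8, seed=5)
    geno = simulate_genotypes(cfg)
    n_alleles = 2 * cfg.n_samples
    for rsid, row in geno.variants.iterrows():
        target = row["target_maf"]
        p_hat = geno.dosages[rsid].mean() / 2
        realized = min(p_hat, 1 - p_hat)
        se = np.sqrt(target * (1 - target) / n_alleles)
        assert abs(realized - target) <= 3 * se + 1e-12, rsid


def test_no_ld_means_no_r2_proxies():
    cfg = SimConfig(
        n_samples=1000, n_loci=1, snps_per_locus=10, ld_decay=0.0,
        maf_range=(0.1, 0.5), seed=6,
    )
    dos = simulate_genotypes(cfg).dosages.to_numpy()
    high = sum(
        np.corrcoef(dos[:, i], dos[:, j])[0, 1] ** 2 >= 0.8
        for i in range(10)
        for j in range(i + 1, 10)
    )
    assert high == 0


def test_null_cohort_slopes_center_on_zero():
    cfg = SimConfig(
        n_samples=300, n_loci=3, snps_per_locus=2, probes_per_locus=2,
        effect_sizes=(), noise_sd=1.0, seed=8,
    )
    geno, expr, truth, _ = simulate_cohort(cfg)
    assert not truth.entries
    slopes = [
        fit_snp_probe(geno.dosages.iloc[:, i], expr.values.iloc[:, j],
                      compute_spearman=False, diagnostics=False).slope
        for i in range(6)
        for j in range(6)
    ]
    assert abs(np.mean(slopes)) < 0.05


def test_noiseless_limit_recovers_planted_slope():
    cfg = SimConfig(
        n_samples=100, n_loci=1, snps_per_locus=1, probes_per_locus=1,
        effect_sizes=(1.0,), noise_sd=1e-9, maf_range=(0.3, 0.3), seed=9,
    )
    geno, expr, truth, _ = simulate_cohort(cfg)
    entry = truth.entries[0]
    fit = fit_snp_probe(geno.dosages[entry.rsid], expr.values[entry.probe_id])
    assert fit.slope == pytest.approx(1.0, abs=1e-6)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-6)


def test_truth_labels_agree_with_probe_classifier(planted_cohort):
    _, geno, expr, truth, _ = planted_cohort
    blocks, _ = loci.blocks_from_simulation(geno, r2_min=0.8)
    assignments = loci.classify_probes(blocks, expr.probes)
    locus_of_rsid = geno.variants["locus"].to_dict()
    label_of_locus = {b.index.locus_label: b for b in blocks}
    for entry in truth.entries:
        label = f"L{locus_of_rsid[entry.rsid]}"
        assert label in label_of_locus
        row = assignments[
            (assignments["probe_id"] == entry.probe_id)
            & (assignments["locus_label"] == label)
        ]
        assert len(row) == 1
        assert row["class"].iloc[0] == entry.label


def test_probe_correlation_is_planted():
    cfg = SimConfig(
        n_samples=4000, n_loci=1, snps_per_locus=1, probes_per_locus=6,
        probe_cor=0.3, noise_sd=1.0, seed=12,
    )
    _, expr, _, _ = simulate_cohort(cfg)
    corr = np.corrcoef(expr.values.to_numpy(), rowvar=False)
    off = corr[np.triu_indices(6, k=1)]
    assert np.mean(off) == pytest.approx(0.3, abs=0.05)


class TestWriteFixture:
    def test_round_trip_through_io_readers(self, tmp_path, planted_cohort):
        _, geno, expr, truth, meta = planted_cohort
        paths = synthio.write_fixture(geno, expr, meta, tmp_path, truth=truth)
        geno2 = io.read_genotypes(paths["genotypes"])
        np.testing.assert_array_equal(
            geno.dosages.to_numpy(), geno2.dosages.to_numpy()
        )
        assert geno2.sample_ids == geno.sample_ids
        expr2 = io.read_expression(paths["expression"], paths["probes"])
        np.testing.assert_array_equal(
            expr.values.to_numpy(), expr2.values.loc[expr.sample_ids, expr.probe_ids].to_numpy()
        )

    def test_empty_cohort_refused(self, tmp_path, planted_cohort):
        _, geno, expr, _, meta = planted_cohort
        with pytest.raises(ConfigurationError):
            synthio.write_fixture(geno.subset(samples=[]), expr, meta, tmp_path)

    def test_fixed_seed_writes_byte_identical_files(self, tmp_path):
        cfg = SimConfig(n_samples=30, n_loci=1, snps_per_locus=3, seed=13)
        digests = []
        for sub in ("a", "b"):
            geno, expr, truth, meta = simulate_cohort(cfg)
            paths = synthio.write_fixture(
                geno, expr, meta, tmp_path / sub, truth=truth
            )
            digests.append(fixture_digest(paths))
        assert digests[0] == digests[1]
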