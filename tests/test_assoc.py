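"""Association scan: OLS statistics, BH adjustment, lead-SNP summaries."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from permqtl import assoc, loci
from permqtl.assoc import bh_adjust, fit_snp_probe, lead_per_gene, scan
from permqtl.errors import EmptyResultError, UndefinedStatisticError
from tests.conftest import toy_expression, toy_genotypes


class TestFitSnpProbe:
    def test_noiseless_line_is_perfect(self):
        d = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        fit = fit_snp_probe(d, 2.0 * d)
        assert fit.slope == pytest.approx(2.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_monomorphic_dosage_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            fit_snp_probe([1, 1, 1, 1], [0.1, 0.2, 0.3, 0.4])

    def test_constant_expression_flagged_with_null_convention(self):
        fit = fit_snp_probe([0, 1, 2, 1], [5.0, 5.0, 5.0, 5.0])
        assert fit.flagged
        assert fit.r_squared == 0.0
        assert fit.p_nominal == 1.0
        assert fit.slope == 0.0

    def test_matches_closed_form_ols_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = int(rng.integers(5, 31))
            d = rng.binomial(2, 0.4, n).astype(float)
            if np.var(d) == 0:
                continue
            y = rng.normal(size=n)
            fit = fit_snp_probe(d, y)
            model = sm.OLS(y, sm.add_constant(d)).fit()
            assert fit.slope == pytest.approx(model.params[1], abs=1e-10)
            assert fit.se == pytest.approx(model.bse[1], abs=1e-10)
            assert fit.r_squared == pytest.approx(model.rsquared, abs=1e-10)
            assert fit.p_nominal == pytest.approx(model.pvalues[1], abs=1e-10)

    def test_p_equals_pearson_correlation_test(self):
        rng = np.random.default_rng(1)
        d = rng.binomial(2, 0.3, 40).astype(float)
        y = rng.normal(size=40) + 0.3 * d
        fit = fit_snp_probe(d, y)
        r, p = stats.pearsonr(d, y)
        assert fit.p_nominal == pytest.approx(p, abs=1e-10)
        assert fit.r_squared == pytest.approx(r * r, abs=1e-10)

    def test_null_p_values_are_uniform(self):
        rng = np.random.default_rng(2)
        d = rng.binomial(2, 0.3, 250).astype(float)
        ps = []
        for _ in range(400):
            fit = fit_snp_probe(d, rng.normal(size=250),
                                compute_spearman=False, diagnostics=False)
            ps.append(fit.p_nominal)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_affine_rescaling_preserves_r2_and_scales_slope(self):
        rng = np.random.default_rng(3)
        d = rng.binomial(2, 0.4, 60).astype(float)
        y = 0.7 * d + rng.normal(size=60)
        base = fit_snp_probe(d, y)
        scaled = fit_snp_probe(d, 3.0 * y + 11.0)
        assert scaled.r_squared == pytest.approx(base.r_squared, abs=1e-12)
        assert scaled.slope == pytest.approx(3.0 * base.slope, abs=1e-10)
        assert scaled.p_nominal == pytest.approx(base.p_nominal, abs=1e-12)

    def test_spearman_sign_agrees_with_slope_on_monotone_data(self):
        d = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        y = np.array([1.0, 1.1, 2.0, 2.1, 3.0, 3.1])
        fit = fit_snp_probe(d, y)
        assert np.sign(fit.rho) == np.sign(fit.slope) == 1.0

    def test_diagnostics_attached(self):
        rng = np.random.default_rng(4)
        d = rng.binomial(2, 0.4, 80).astype(float)
        fit = fit_snp_probe(d, rng.normal(size=80))
        assert {"resid_skewness", "resid_kurtosis", "bp_score", "bp_p"} <= set(
            fit.diagnostics
        )


def _toy_scan_setup():
    rng = np.random.default_rng(5)
    geno = toy_genotypes(
        {f"rs{i}": rng.binomial(2, 0.4, 50).astype(float) for i in range(2)}
    )
    expr = toy_expression({f"p{i}": rng.normal(size=50) for i in range(3)})
    risk = [loci.RiskLocus("rs0", "1", 1_000_000, "L1")]
    blocks, _ = loci.build_ld_blocks(risk, geno, r2_min=0.0)
    assignments = loci.classify_probes(blocks, expr.probes)
    return geno, expr, blocks, assignments


class TestScan:
    def test_cardinality_is_snps_times_probes(self):
        geno, expr, blocks, assignments = _toy_scan_setup()
        results = scan(geno, expr, blocks, assignments, mode="cis")
        assert len(results) == 2 * 3

    def test_results_match_per_pair_fits(self):
        geno, expr, blocks, assignments = _toy_scan_setup()
        results = scan(geno, expr, blocks, assignments, mode="cis")
        for _, row in results.iterrows():
            fit = fit_snp_probe(
                geno.dosages[row["rsid"]], expr.values[row["probe_id"]]
            )
            assert row["slope"] == pytest.approx(fit.slope, abs=1e-10)
            assert row["p_nominal"] == pytest.approx(fit.p_nominal, abs=1e-10)
            assert row["rho"] == pytest.approx(fit.rho, abs=1e-10)

    def test_planted_effect_attains_scan_minimum(self, planted_cohort, planted_blocks):
        _, geno, expr, truth, _ = planted_cohort
        blocks, assignments = planted_blocks
        results = scan(geno, expr, blocks, assignments, mode="cis")
        best = results.loc[results["p_nominal"].idxmin()]
        planted = truth.entries[0]
        assert best["probe_id"] == planted.probe_id
        # the winning SNP is the planted one or a tight proxy of it
        r2 = loci.compute_ld_r2(
            geno.dosages[best["rsid"]], geno.dosages[planted.rsid]
        )
        assert r2 >= 0.8

    def test_jointly_permuted_labels_destroy_association(self, planted_cohort, planted_blocks):
        _, geno, expr, _, _ = planted_cohort
        blocks, assignments = planted_blocks
        rng = np.random.default_rng(6)
        perm = rng.permutation(expr.n_samples)
        shuffled = expr.values.iloc[perm].set_index(expr.values.index)
        expr_perm = type(expr)(shuffled, expr.probes, expr.state)
        observed = scan(geno, expr, blocks, assignments, mode="cis")
        null = scan(geno, expr_perm, blocks, assignments, mode="cis")
        assert null["p_nominal"].min() > observed["p_nominal"].min()
        assert null["p_nominal"].min() > 1e-4

    def test_disjoint_samples_is_hard_error(self):
        geno, expr, blocks, assignments = _toy_scan_setup()
        renamed = expr.values.set_axis([f"X{i}" for i in range(50)], axis=0)
        expr_bad = type(expr)(renamed, expr.probes, expr.state)
        with pytest.raises(EmptyResultError):
            scan(geno, expr_bad, blocks, assignments)


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_ties_stay_equal(self):
        np.testing.assert_allclose(bh_adjust([0.05] * 4), [0.05] * 4)

    def test_empty_input_gives_empty_output(self):
        assert bh_adjust([]).size == 0

    def test_matches_hand_rolled_step_up_oracle(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=37)
        m = len(p)
        order = np.argsort(p)
        stepped = p[order] * m / np.arange(1, m + 1)
        stepped = np.minimum.accumulate(stepped[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(stepped, 1.0)
        np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    def test_never_below_raw_p(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=100)
        assert (bh_adjust(p) >= p - 1e-15).all()


class TestLeadPerGene:
    def test_single_snp_is_lead(self):
        results = pd.DataFrame(
            {
                "locus_label": ["L1"], "rsid": ["rs1"], "pos": [100],
                "probe_id": ["p1"], "gene_symbol": ["G1"],
                "p_nominal": [0.01], "maf": [0.3], "r2_with_index": [1.0],
            }
        )
        lead = lead_per_gene(results, threshold=0.05)
        assert lead["lead_rsid"].iloc[0] == "rs1"
        assert lead["n_significant_snps"].iloc[0] == 1

    def test_ties_break_by_position(self):
        results = pd.DataFrame(
            {
                "locus_label": ["L1", "L1"], "rsid": ["rs_b", "rs_a"],
                "pos": [200, 500], "probe_id": ["p1", "p1"],
                "gene_symbol": ["G1", "G1"], "p_nominal": [0.01, 0.01],
                "maf": [0.3, 0.3], "r2_with_index": [1.0, 0.9],
            }
        )
        lead = lead_per_gene(results, threshold=0.05)
        assert lead["lead_rsid"].iloc[0] == "rs_b"  # smaller position wins

    def test_significant_counts_match_brute_tally(self, planted_cohort, planted_blocks):
        _, geno, expr, _, _ = planted_cohort
        blocks, assignments = planted_blocks
        results = scan(geno, expr, blocks, assignments, mode="cis")
        threshold = 1e-4
        lead = lead_per_gene(results, threshold)
        for _, row in lead.iterrows():
            tally = (
                results.loc[results["probe_id"] == row["probe_id"], "p_nominal"]
                <= threshold
            ).sum()
            assert row["n_significant_snps"] == tally
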