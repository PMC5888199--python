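"""Expression normalization, batch regression and PCA audit."""

import numpy as np
import pandas as pd
import pytest

from permqtl import exprprep, synthio
from permqtl.errors import EmptyResultError, ValidationError
from permqtl.exprprep import _quantile_normalize
from tests.conftest import toy_expression


def _raw(values_dict):
    return toy_expression(values_dict, state="raw")


class TestQuantileNormalize:
    def test_all_samples_share_one_multiset(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(size=(6, 40))
        out = _quantile_normalize(x)
        ref = np.sort(out[0])
        for i in range(1, 6):
            np.testing.assert_allclose(np.sort(out[i]), ref)

    def test_samples_with_equal_multisets_get_equal_multisets(self):
        base = np.array([5.0, 1.0, 3.0, 2.0])
        x = np.vstack([base, base[::-1]])
        out = _quantile_normalize(x)
        np.testing.assert_allclose(np.sort(out[0]), np.sort(out[1]))
        # values stay in each sample's own rank order
        assert (np.argsort(out[0]) == np.argsort(x[0])).all()

    def test_idempotent_fixed_point(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(5, 30))
        once = _quantile_normalize(x)
        np.testing.assert_allclose(_quantile_normalize(once), once, atol=1e-12)

    def test_matches_hand_computation_on_toy_matrix(self):
        # independent oracle: rank, average order statistics, map back
        x = np.array(
            [[2.0, 4.0, 6.0, 8.0], [1.0, 3.0, 5.0, 7.0], [9.0, 2.0, 4.0, 1.0]]
        )
        expected = np.empty_like(x)
        reference = np.sort(x, axis=1).mean(axis=0)
        for i in range(3):
            order = np.argsort(x[i])
            expected[i, order] = reference
        np.testing.assert_allclose(_quantile_normalize(x), expected)


def test_normalize_rejects_nonpositive_values_with_count():
    expr = _raw({"p1": [1.0, -2.0, 3.0], "p2": [0.0, 5.0, 6.0]})
    with pytest.raises(ValidationError, match="2 nonpositive"):
        exprprep.normalize(expr, "log-quantile")


def test_normalize_state_machine_is_forward_only():
    expr = _raw({"p1": [1.0, 2.0, 3.0], "p2": [4.0, 5.0, 6.0]})
    out = exprprep.normalize(expr)
    assert out.state == "normalized"
    with pytest.raises(ValidationError):
        exprprep.normalize(out)


def test_rank_inverse_normal_gives_gaussian_marginals():
    rng = np.random.default_rng(2)
    expr = _raw({f"p{i}": rng.lognormal(size=200) for i in range(3)})
    out = exprprep.normalize(expr, "rank-inverse-normal")
    vals = out.values.to_numpy()
    assert abs(vals.mean()) < 0.01
    assert np.allclose(vals.std(axis=0), 1.0, atol=0.05)


class TestBatchRegression:
    def test_single_batch_is_noop(self):
        expr = _raw({"p1": [1.0, 2.0, 3.0, 4.0]})
        out = exprprep.regress_out_batch(expr, ["A"] * 4)
        np.testing.assert_allclose(out.values.to_numpy(), expr.values.to_numpy())
        assert out.state == "batch_corrected"

    def test_pure_batch_shift_removed_exactly(self):
        mu = 5.0
        vals = np.array([mu + 2.0] * 3 + [mu - 1.0] * 3)
        expr = _raw({"p1": vals})
        out = exprprep.regress_out_batch(expr, ["A"] * 3 + ["B"] * 3)
        corrected = out.values["p1"].to_numpy()
        assert np.allclose(corrected, corrected[0])

    def test_grand_mean_preserved(self):
        rng = np.random.default_rng(3)
        expr = _raw({f"p{i}": rng.normal(size=20) + 10 for i in range(5)})
        batches = ["A"] * 7 + ["B"] * 6 + ["C"] * 7
        out = exprprep.regress_out_batch(expr, batches)
        np.testing.assert_allclose(
            out.values.mean(axis=0), expr.values.mean(axis=0), atol=1e-10
        )

    def test_post_correction_batch_means_agree(self):
        rng = np.random.default_rng(4)
        expr = _raw({f"p{i}": rng.normal(size=30) for i in range(4)})
        batches = pd.Series(["A"] * 10 + ["B"] * 10 + ["C"] * 10, index=expr.values.index)
        out = exprprep.regress_out_batch(expr, batches)
        means = out.values.groupby(batches).mean()
        assert (means.max() - means.min()).max() < 1e-8

    def test_singleton_batch_warned_and_skipped(self):
        expr = _raw({"p1": [1.0, 2.0, 3.0, 9.0]})
        with pytest.warns(UserWarning, match="single sample"):
            out = exprprep.regress_out_batch(expr, ["A", "A", "A", "B"])
        # the singleton sample is left unchanged
        assert out.values["p1"].iloc[3] == 9.0


class TestPCA:
    def test_rank_one_matrix_captured_by_first_component(self):
        u = np.arange(10, dtype=float)
        v = np.array([1.0, -2.0, 0.5, 3.0])
        expr = toy_expression(
            {f"p{i}": u * v[i] for i in range(4)}, state="normalized"
        )
        check = exprprep.pca_check(expr, k=3)
        assert check.variance_fractions[0] >= 0.999

    def test_isotropic_noise_has_flat_spectrum(self):
        rng = np.random.default_rng(5)
        expr = toy_expression(
            {f"p{i}": rng.normal(size=2000) for i in range(5)}, state="normalized"
        )
        check = exprprep.pca_check(expr, k=5)
        assert check.variance_fractions.max() < 2.0 / 5.0

    def test_scores_orthogonal(self):
        rng = np.random.default_rng(6)
        expr = toy_expression(
            {f"p{i}": rng.normal(size=50) for i in range(8)}, state="normalized"
        )
        scores = exprprep.pca_check(expr, k=4).scores.to_numpy()
        gram = scores.T @ scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_k_larger_than_matrix_rejected(self):
        expr = toy_expression({"p1": [1.0, 2.0, 3.0]}, state="normalized")
        with pytest.raises(ValidationError):
            exprprep.pca_check(expr, k=2)

    def test_batch_structure_shrinks_after_correction(self):
        cfg = synthio.SimConfig(
            n_samples=100, n_loci=2, snps_per_locus=2, probes_per_locus=15,
            batch_effect_sd=2.0, n_batches=2, noise_sd=1.0, seed=8,
        )
        _, expr, _, meta = synthio.simulate_cohort(cfg)
        before = exprprep.pca_check(expr, k=3, batch_labels=meta["batch"])
        corrected = exprprep.regress_out_batch(expr, meta["batch"])
        after = exprprep.pca_check(corrected, k=3, batch_labels=meta["batch"])
        assert before.batch_r2[0] > 0.5
        assert after.batch_r2[0] < before.batch_r2[0]
        assert after.batch_r2.max() < 0.01


class TestProbeSets:
    def test_empty_blacklist_is_identity(self):
        expr = _raw({"p1": [1.0, 2.0], "p2": [3.0, 4.0]})
        out = exprprep.exclude_probes(expr, [])
        assert out.probe_ids == expr.probe_ids

    def test_blacklisting_everything_is_loud(self):
        expr = _raw({"p1": [1.0, 2.0]})
        with pytest.raises(EmptyResultError):
            exprprep.exclude_probes(expr, ["p1"])

    def test_partial_blacklist_counts(self):
        expr = _raw({f"p{i}": [1.0, 2.0] for i in range(10)})
        out = exprprep.exclude_probes(expr, ["p0", "p5", "p9", "unknown"])
        assert out.n_probes == 7

    def test_merge_intersects_probes_and_labels_cohorts(self):
        a = toy_expression({"p1": [1.0, 2.0], "p2": [3.0, 4.0]}, sample_prefix="A")
        b = toy_expression({"p2": [5.0, 6.0], "p3": [7.0, 8.0]}, sample_prefix="B")
        merged, labels = exprprep.merge_cohorts([a, b])
        assert merged.probe_ids == ["p2"]
        assert merged.n_samples == 4
        assert set(labels) == {"cohort0", "cohort1"}
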