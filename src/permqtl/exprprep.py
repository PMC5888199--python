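"""Expression preparation: normalization, batch regression, PCA audit.

The eQTL math downstream is agnostic to the exact normalizer; what matters
is a variance-stabilized matrix with comparable per-sample distributions.
The default pipeline is log2(x+1) followed by quantile normalization across
samples; a rank-based inverse-normal transform is available when fully
Gaussian marginals are preferred. Batch effects are removed per probe by
linear modeling on batch indicators, and a PCA check quantifies how much
batch structure remains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .core import ExpressionMatrix
from .errors import EmptyResultError, ValidationError

NORMALIZE_METHODS = ("log-quantile", "rank-inverse-normal", "none")


def _quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Map every sample's values onto the mean order-statistic profile.

    Ties within a sample receive the average of the reference values at the
    tied ranks, which makes the transform idempotent.
    """
    n, p = values.shape
    order = np.argsort(values, axis=1, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(n)[:, None]
    ranks[rows, order] = np.arange(p)
    reference = np.sort(values, axis=1).mean(axis=0)
    out = reference[ranks]
    # average reference values over tied entries, per sample
    for i in range(n):
        row = values[i]
        uniq, inv, counts = np.unique(row, return_inverse=True, return_counts=True)
        if len(uniq) < p:
            sums = np.bincount(inv, weights=out[i])
            out[i] = (sums / counts)[inv]
    return out


def _rank_inverse_normal(values: np.ndarray, c: float = 3.0 / 8.0) -> np.ndarray:
    """Blom-offset rank-based inverse normal transform, per probe."""
    n = values.shape[0]
    ranks = stats.rankdata(values, axis=0)
    return stats.norm.ppf((ranks - c) / (n - 2 * c + 1))


def normalize(expr: ExpressionMatrix, method: str = "log-quantile") -> ExpressionMatrix:
    """Variance-stabilize and normalize a raw expression matrix."""
    if method not in NORMALIZE_METHODS:
        raise ValidationError(f"unknown normalization method '{method}'")
    if expr.state != "raw":
        raise ValidationError(f"normalize expects raw input, got '{expr.state}'")
    values = expr.values.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValidationError("missing expression values are not supported")
    if method == "log-quantile":
        bad = int((values <= 0).sum())
        if bad:
            raise ValidationError(
                f"{bad} nonpositive values; log-family transform undefined"
            )
        values = _quantile_normalize(np.log2(values + 1.0))
    elif method == "rank-inverse-normal":
        values = _rank_inverse_normal(values)
    out = pd.DataFrame(values, index=expr.values.index, columns=expr.values.columns)
    return ExpressionMatrix(out, expr.probes.copy(), state="normalized")


def regress_out_batch(expr: ExpressionMatrix, batch_labels) -> ExpressionMatrix:
    """Remove per-batch additive offsets probe-wise, preserving grand means.

    Batches with a single sample cannot contribute an offset estimate; they
    are left uncorrected with a warning. A single batch overall is a no-op.
    """
    labels = pd.Series(batch_labels, index=expr.values.index)
    counts = labels.value_counts()
    if len(counts) == 1:
        return expr.with_state("batch_corrected")
    singletons = counts[counts < 2].index.tolist()
    if singletons:
        warnings.warn(
            f"batches with a single sample left uncorrected: {singletons}",
            stacklevel=2,
        )
    values = expr.values.to_numpy(dtype=float).copy()
    grand = values.mean(axis=0)
    for batch, cnt in counts.items():
        if cnt < 2:
            continue
        mask = (labels == batch).to_numpy()
        values[mask] += grand - values[mask].mean(axis=0)
    out = pd.DataFrame(values, index=expr.values.index, columns=expr.values.columns)
    return ExpressionMatrix(out, expr.probes.copy(), expr.state).with_state(
        "batch_corrected"
    )


@dataclass
class PCACheck:
    """Top-k PCA of the sample x probe matrix plus batch association."""

    scores: pd.DataFrame  # samples x components
    variance_fractions: np.ndarray
    batch_r2: np.ndarray | None  # per-PC R^2 of PC ~ batch indicators


def pca_check(expr: ExpressionMatrix, k: int, batch_labels=None) -> PCACheck:
    """Principal components of probe-centered expression, to audit batch."""
    if expr.state == "raw":
        raise ValidationError("pca_check expects normalized input")
    n, p = expr.values.shape
    if k > min(n, p):
        raise ValidationError(f"k={k} exceeds min(n_samples, n_probes)={min(n, p)}")
    values = expr.values.to_numpy(dtype=float)
    values = values - values.mean(axis=0)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(values)
    frac = pca.explained_variance_ratio_
    batch_r2 = None
    if batch_labels is not None:
        dummies = pd.get_dummies(pd.Series(batch_labels, index=expr.values.index))
        X = dummies.to_numpy(dtype=float)
        X = np.column_stack([np.ones(n), X[:, 1:]])
        batch_r2 = np.empty(k)
        for j in range(k):
            y = scores[:, j]
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            tss = np.sum((y - y.mean()) ** 2)
            batch_r2[j] = 0.0 if tss == 0 else 1.0 - np.sum(resid**2) / tss
    score_df = pd.DataFrame(
        scores, index=expr.values.index, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return PCACheck(score_df, frac, batch_r2)


def exclude_probes(expr: ExpressionMatrix, blacklist) -> ExpressionMatrix:
    """Drop blacklisted probes (e.g. cross-hybridizing ones); unknown ids
    are ignored. Raises if nothing survives."""
    blacklist = set(blacklist)
    keep = [pid for pid in expr.probe_ids if pid not in blacklist]
    if not keep:
        raise EmptyResultError("probe blacklist removes every probe")
    return expr.subset(probes=keep)


def intersect_probes(*exprs: ExpressionMatrix) -> list[str]:
    """Probe ids common to all matrices (cross-platform intersection)."""
    common = set(exprs[0].probe_ids)
    for e in exprs[1:]:
        common &= set(e.probe_ids)
    return [pid for pid in exprs[0].probe_ids if pid in common]


def merge_cohorts(exprs: list[ExpressionMatrix]) -> tuple[ExpressionMatrix, pd.Series]:
    """Column-aligned concatenation of cohorts on their shared probes.

    Returns the merged matrix and a per-sample batch label series recording
    the cohort of origin (usable by :func:`regress_out_batch`).
    """
    common = intersect_probes(*exprs)
    if not common:
        raise EmptyResultError("no shared probes between cohorts")
    parts, labels = [], []
    for i, e in enumerate(exprs):
        parts.append(e.values[common])
        labels.extend([f"cohort{i}"] * e.n_samples)
    merged = pd.concat(parts, axis=0)
    if merged.index.duplicated().any():
        raise ValidationError("duplicate sample ids across merged cohorts")
    out = ExpressionMatrix(merged, exprs[0].probes.loc[common].copy(), exprs[0].state)
    return out, pd.Series(labels, index=merged.index, name="batch")
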