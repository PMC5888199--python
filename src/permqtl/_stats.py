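"""Vectorized pairwise simple-regression statistics.

The association scan and the permutation null both reduce to ordinary least
squares of each expression probe on each variant dosage. For a simple
regression, slope, R^2 and the two-sided t-test P value are closed-form
functions of pairwise sums, so the whole SNP x probe grid can be computed
with a handful of matrix products — including pairwise complete-case
handling when dosages or intensities are missing.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["pairwise_ols"]


def pairwise_ols(G: np.ndarray, E: np.ndarray) -> dict[str, np.ndarray]:
    """Simple OLS of every column of ``E`` on every column of ``G``.

    Parameters
    ----------
    G : (n, s) array of dosages, NaN = missing.
    E : (n, q) array of expression values, NaN = missing.

    Returns
    -------
    dict of (s, q) arrays: ``n`` complete pairs, ``slope``, ``intercept``,
    ``se`` of the slope, ``r2`` (squared Pearson correlation) and ``p``
    (two-sided t test of slope = 0 on n-2 df).

    Degenerate cells: a monomorphic (zero-variance) dosage column yields NaN
    statistics; constant expression against a polymorphic dosage yields
    slope 0, r2 0 and p 1 by convention.
    """
    G = np.asarray(G, dtype=float)
    E = np.asarray(E, dtype=float)
    if G.ndim != 2 or E.ndim != 2 or G.shape[0] != E.shape[0]:
        raise ValueError("G and E must be 2-D with equal sample counts")

    if not (np.isnan(G).any() or np.isnan(E).any()):
        n = float(G.shape[0])
        N = np.full((G.shape[1], E.shape[1]), n)
        Sx = np.repeat(G.sum(0)[:, None], E.shape[1], axis=1)
        Sy = np.repeat(E.sum(0)[None, :], G.shape[1], axis=0)
        Sxx = np.repeat((G * G).sum(0)[:, None], E.shape[1], axis=1)
        Syy = np.repeat((E * E).sum(0)[None, :], G.shape[1], axis=0)
        Sxy = G.T @ E
    else:
        MG = (~np.isnan(G)).astype(float)
        ME = (~np.isnan(E)).astype(float)
        G0 = np.nan_to_num(G)
        E0 = np.nan_to_num(E)
        N = MG.T @ ME
        Sx = G0.T @ ME
        Sy = MG.T @ E0
        Sxx = (G0 * G0).T @ ME
        Syy = MG.T @ (E0 * E0)
        Sxy = G0.T @ E0

    with np.errstate(invalid="ignore", divide="ignore"):
        # centered sums of squares / cross-products over complete pairs
        ssx = Sxx - Sx * Sx / N
        ssy = Syy - Sy * Sy / N
        sxy = Sxy - Sx * Sy / N
        ok_n = N >= 3
        mono = ssx <= 0  # zero-variance dosage: statistic undefined
        const_y = (ssy <= 0) & ~mono

        slope = np.where(mono, np.nan, sxy / np.where(ssx > 0, ssx, np.nan))
        intercept = (Sy - slope * Sx) / N
        r2 = np.where(
            mono,
            np.nan,
            (sxy * sxy) / np.where((ssx * ssy) > 0, ssx * ssy, np.nan),
        )
        r2 = np.clip(r2, 0.0, 1.0)
        # residual sum of squares and slope standard error
        rss = ssy - np.where(np.isnan(slope), 0.0, slope) * sxy
        rss = np.maximum(rss, 0.0)
        df = N - 2
        se = np.sqrt(rss / np.where(df > 0, df, np.nan) / np.where(ssx > 0, ssx, np.nan))
        tstat = slope / se
        p = 2.0 * stats.t.sf(np.abs(tstat), np.where(df > 0, df, 1))
        # keep P strictly positive even for numerically perfect fits
        p = np.where(np.isnan(p), p, np.maximum(p, 1e-300))

        # conventions for degenerate cells
        slope = np.where(const_y, 0.0, slope)
        r2 = np.where(const_y, 0.0, r2)
        p = np.where(const_y, 1.0, p)
        se = np.where(const_y, 0.0, se)
        for arr in (slope, intercept, se, r2, p):
            arr[~ok_n] = np.nan
        p[mono] = np.nan
        r2[mono] = np.nan

    return {
        "n": N,
        "slope": slope,
        "intercept": intercept,
        "se": se,
        "r2": r2,
        "p": p,
        "flag_constant_expression": const_y,
        "flag_monomorphic": mono,
    }
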