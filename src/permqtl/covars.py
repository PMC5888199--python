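"""Covariate-robustness analysis.

A credible eQTL should keep its slope when clinical or biologic covariates
(age, sex, acute-phase markers, joint counts, activation surrogates,
diagnosis class) enter the linear model one at a time. This module refits
each association with a covariate, records the slope change, evaluates a
SNP x covariate interaction model, and supports scans stratified by
diagnosis class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .assoc import AssociationResult, scan
from .core import ExpressionMatrix, GenotypeMatrix
from .errors import CollinearityError, UndefinedStatisticError, ValidationError

DEFAULT_COVARIATES = ("age", "sex", "crp", "sjc")
DEFAULT_DELTA_TOLERANCE = 0.1
DEFAULT_STRATUM_FLOOR = 20
_CONDITION_BOUND = 1e8


@dataclass
class RobustnessRecord:
    rsid: str
    probe_id: str
    covariate: str
    slope_base: float
    slope_adjusted: float
    delta: float
    interaction_p: float
    flag: str  # "unchanged" or "changed" at the configured tolerance


def _design(dosage: np.ndarray, covariates: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    cols = [dosage]
    names = ["dosage"]
    for name in covariates.columns:
        col = covariates[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=name, drop_first=True)
            for dname in dummies.columns:
                cols.append(dummies[dname].to_numpy(dtype=float))
                names.append(dname)
        else:
            cols.append(col.to_numpy(dtype=float))
            names.append(name)
    X = np.column_stack(cols)
    return X, names


def _check_condition(X: np.ndarray, names: list[str]) -> None:
    # condition number of the standardized design (constant column excluded)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [names[i] for i in np.where(sd == 0)[0]]
        raise CollinearityError(bad, f"constant design columns: {bad}")
    Z = (X - X.mean(axis=0)) / sd
    cond = np.linalg.cond(Z)
    if cond > _CONDITION_BOUND:
        corr = np.corrcoef(Z, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        raise CollinearityError(
            [names[i], names[j]],
            f"design condition number {cond:.3g} exceeds {_CONDITION_BOUND:.0e}; "
            f"most correlated columns: {names[i]}, {names[j]}",
        )


def fit_adjusted(dosage, expression, covariates: pd.DataFrame) -> AssociationResult:
    """OLS of expression ~ dosage + covariates over complete cases.

    Categorical covariates are one-hot encoded against a reference level.
    Reports the dosage slope with its marginal standard error and P value.
    """
    d = pd.Series(np.asarray(dosage, dtype=float))
    y = pd.Series(np.asarray(expression, dtype=float))
    cov = covariates.reset_index(drop=True)
    keep = ~(d.isna() | y.isna() | cov.isna().any(axis=1))
    d, y, cov = d[keep].to_numpy(), y[keep].to_numpy(), cov[keep]
    if d.size < 3:
        raise UndefinedStatisticError("fewer than 3 complete cases")
    if np.var(d) == 0:
        raise UndefinedStatisticError("monomorphic dosage")
    X, names = _design(d, cov)
    _check_condition(X, names)
    model = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    return AssociationResult(
        rsid="",
        probe_id="",
        n=int(d.size),
        slope=float(model.params[1]),
        se=float(model.bse[1]),
        r_squared=float(model.rsquared),
        p_nominal=float(model.pvalues[1]),
    )


def _interaction_p(dosage, expression, covariate: pd.Series) -> float:
    d = np.asarray(dosage, dtype=float)
    y = np.asarray(expression, dtype=float)
    c = covariate
    if c.dtype == object or isinstance(c.dtype, pd.CategoricalDtype):
        c = pd.get_dummies(c, drop_first=True).iloc[:, 0]
    c = c.to_numpy(dtype=float)
    keep = ~(np.isnan(d) | np.isnan(y) | np.isnan(c))
    d, y, c = d[keep], y[keep], c[keep]
    X = np.column_stack([d, c, d * c])
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(d)), X])) < 4:
        return np.nan
    model = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    return float(model.pvalues[3])


def robustness_sweep(
    results: pd.DataFrame,
    geno: GenotypeMatrix,
    expr: ExpressionMatrix,
    meta: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
    tolerance: float = DEFAULT_DELTA_TOLERANCE,
) -> pd.DataFrame:
    """Refit each result with each covariate, one at a time.

    The flag is "unchanged" when |slope_adjusted - slope_base| <
    tolerance * |slope_base| (base slope taken from ``results``). A SNP x
    covariate interaction P accompanies each record as an explicitly
    labelled extension of the slope-comparison convention. Covariates
    absent from the metadata are skipped.
    """
    shared = [s for s in geno.sample_ids if s in set(expr.sample_ids) and s in meta.index]
    records = []
    for _, row in results.iterrows():
        d = geno.dosages.loc[shared, row["rsid"]]
        y = expr.values.loc[shared, row["probe_id"]]
        for name in covariates:
            if name not in meta.columns:
                continue
            cov = meta.loc[shared, [name]]
            adj = fit_adjusted(d, y, cov)
            delta = adj.slope - row["slope"]
            base = abs(row["slope"])
            unchanged = abs(delta) < tolerance * base if base > 0 else abs(delta) < tolerance
            records.append(
                RobustnessRecord(
                    rsid=row["rsid"],
                    probe_id=row["probe_id"],
                    covariate=name,
                    slope_base=float(row["slope"]),
                    slope_adjusted=adj.slope,
                    delta=float(delta),
                    interaction_p=_interaction_p(d, y, meta.loc[shared, name]),
                    flag="unchanged" if unchanged else "changed",
                )
            )
    return pd.DataFrame([r.__dict__ for r in records])


def stratified_scan(
    geno: GenotypeMatrix,
    expr: ExpressionMatrix,
    meta: pd.DataFrame,
    stratum: str,
    blocks,
    assignments,
    mode: str = "cis",
    min_samples: int = DEFAULT_STRATUM_FLOOR,
    **scan_kwargs,
) -> pd.DataFrame:
    """Association scan restricted to one diagnosis class."""
    members = meta.index[meta["diagnosis"] == stratum].tolist()
    if len(members) < min_samples:
        raise ValidationError(
            f"stratum '{stratum}' has {len(members)} samples, below the floor of {min_samples}"
        )
    keep_g = [s for s in geno.sample_ids if s in set(members)]
    keep_e = [s for s in expr.sample_ids if s in set(members)]
    return scan(
        geno.subset(samples=keep_g),
        expr.subset(samples=keep_e),
        blocks,
        assignments,
        mode=mode,
        **scan_kwargs,
    )
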