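"""Vectorized mass univariate linear regression.

Every arm of the triangle (gene ~ phenotype, expression ~ dosage,
dosage ~ phenotype) is a large batch of simple linear regressions. Running
them one feature at a time is the bottleneck the method's permutation loop
cannot afford, so the batch is computed in closed form from centered
cross-products; a per-feature OLS fit is the test oracle, not the
implementation.

Covariates are handled by residualizing the response and every predictor on
the covariates plus an intercept, then applying the simple regression with
degrees of freedom ``n - 2 - c``. For the slope t-test this is equivalent to
the full multiple regression (Frisch–Waugh–Lovell).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .datatypes import DosageMatrix, EqtlMap, ExpressionMatrix

__all__ = ["AssocResult", "mass_simple_regression", "compute_eqtl_map"]

# smallest positive float: perfect fits get this rather than an exact 0,
# keeping p-values in (0, 1]
_P_FLOOR = np.finfo(float).tiny


@dataclass
class AssocResult:
    """Per-feature slope estimates and two-sided p-values."""

    feature_ids: list[str]
    beta: np.ndarray
    pvalue: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.pvalue = np.asarray(self.pvalue, dtype=float)
        if not (len(self.feature_ids) == len(self.beta) == len(self.pvalue)):
            raise ValueError("feature_ids, beta and pvalue must have equal length")


def _residualize(v: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Project out the column space of the orthonormal basis ``q``."""
    return v - q @ (q.T @ v)


def mass_simple_regression(
    X: np.ndarray,
    y: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    feature_ids: Optional[Sequence[str]] = None,
) -> AssocResult:
    """Simple linear regression of ``y`` on each column of ``X``.

    Parameters
    ----------
    X : (n_samples, n_features) array
        Predictor matrix; each column is tested separately.
    y : (n_samples,) array
        Response.
    covariates : (n_samples, c) array, optional
        Nuisance covariates; both ``y`` and each predictor are residualized
        on them (plus an intercept) before the slope test, df = n - 2 - c.
    feature_ids : sequence of str, optional
        Labels for the columns of ``X``; defaults to stringified indices.

    Returns
    -------
    AssocResult
        Slopes and two-sided t-test p-values, one per feature. A constant
        predictor column yields beta 0 and p = 1 with a warning (the
        regression is undefined), so that permutation loops survive
        degenerate columns.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if len(y) != n:
        raise ValueError(f"y has {len(y)} samples but X has {n}")
    if feature_ids is None:
        feature_ids = [str(j) for j in range(p)]
    feature_ids = [str(f) for f in feature_ids]
    if len(feature_ids) != p:
        raise ValueError("feature_ids length does not match number of predictors")

    c = 0
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != n:
            raise ValueError("covariate rows do not match sample count")
        c = covariates.shape[1]
    df = n - 2 - c
    if df < 1:
        raise ValueError(
            f"too few samples: n={n} with {c} covariates leaves df={df} (< 1)"
        )

    if covariates is not None:
        basis = np.column_stack([np.ones(n), covariates])
        q, _ = np.linalg.qr(basis)
        Xc = _residualize(X, q)
        yc = _residualize(y, q)
    else:
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()

    sxx = np.einsum("ij,ij->j", Xc, Xc)
    syy = float(yc @ yc)
    sxy = Xc.T @ yc

    constant = sxx <= 0
    if constant.any():
        bad = [feature_ids[j] for j in np.flatnonzero(constant)[:5]]
        warnings.warn(
            f"{int(constant.sum())} constant predictor column(s) "
            f"(e.g. {bad}); assigned p = 1",
            RuntimeWarning,
            stacklevel=2,
        )
    sxx_safe = np.where(constant, 1.0, sxx)

    beta = sxy / sxx_safe
    # residual sum of squares of the simple fit; clip guards rounding when
    # the fit is numerically perfect
    rss = np.clip(syy - beta * sxy, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        se2 = rss / (df * sxx_safe)
        tstat = beta / np.sqrt(se2)
    tstat = np.where(np.isfinite(tstat), tstat, np.where(beta >= 0, np.inf, -np.inf))
    pval = 2.0 * stats.t.sf(np.abs(tstat), df)
    pval = np.clip(pval, _P_FLOOR, 1.0)

    beta = np.where(constant, 0.0, beta)
    pval = np.where(constant, 1.0, pval)
    # degenerate response (zero variance after residualization): no test
    if syy <= 0:
        beta = np.zeros(p)
        pval = np.ones(p)
    return AssocResult(list(feature_ids), beta, pval)


def compute_eqtl_map(
    dosages: DosageMatrix, expr: ExpressionMatrix, p_snp_gene: float
) -> EqtlMap:
    """Exhaustive SNP-by-gene association scan (expression ~ dosage).

    Stands in for a precomputed eQTL-database export when none is supplied.
    All (snp, gene) pairs whose simple-regression p-value falls strictly
    below ``p_snp_gene`` are recorded. Computed once per dataset; the
    permutation null never touches it (the phenotype plays no role here).
    """
    if not (0.0 <= p_snp_gene <= 1.0):
        raise ValueError(f"p_snp_gene must lie in [0, 1], got {p_snp_gene}")
    if dosages.sample_ids != expr.sample_ids:
        raise ValueError("dosage and expression matrices are not sample-aligned")
    n = dosages.n_samples
    df = n - 2
    if df < 1:
        raise ValueError("need at least 3 samples for the SNP-gene scan")

    D = dosages.values - dosages.values.mean(axis=0)
    E = expr.values - expr.values.mean(axis=0)
    sd_d = np.sqrt(np.einsum("ij,ij->j", D, D))
    sd_e = np.sqrt(np.einsum("ij,ij->j", E, E))
    denom = np.outer(sd_d, sd_e)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (D.T @ E) / denom
    r = np.where(denom > 0, r, 0.0)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt(df / (1.0 - r * r))
    tstat = np.where(np.abs(r) >= 1.0, np.inf, tstat)
    pval = np.clip(2.0 * stats.t.sf(np.abs(tstat), df), _P_FLOOR, 1.0)

    snp_idx, gene_idx = np.nonzero(pval < p_snp_gene)
    import pandas as pd

    records = pd.DataFrame(
        {
            "snp_id": np.asarray(dosages.snp_ids, dtype=object)[snp_idx],
            "gene_id": np.asarray(expr.gene_ids, dtype=object)[gene_idx],
            "pvalue": pval[snp_idx, gene_idx],
        }
    )
    return EqtlMap(records)
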