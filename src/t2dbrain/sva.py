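"""Surrogate variable estimation for count data (hidden-confounder adjustment).

Hidden structure (e.g. batch) is estimated from the residuals of log
size-factor-normalised counts on the full model (intercept + known covariates
+ protected status), then refined by an iteratively reweighted SVD: genes are
weighted by the evidence (1 - p of a per-gene F-test) that they carry signal
associated with the current surrogate variables beyond the full model, and the
SVD is recomputed on the row-weighted residual matrix. Because the protected
effect is part of the model whose residuals are decomposed, the surrogate
variables cannot absorb it.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["fit_surrogate_variables", "build_design"]


def build_design(covariates, status=None) -> np.ndarray:
    """Intercept + numeric covariates (+ protected status column last)."""
    import pandas as pd

    n = len(covariates)
    cols = [np.ones(n)]
    if isinstance(covariates, pd.DataFrame):
        for c in covariates.columns:
            v = covariates[c]
            if v.dtype == object or str(v.dtype) == "category":
                levels = sorted(v.astype(str).unique())
                for lev in levels[1:]:
                    cols.append((v.astype(str) == lev).to_numpy(float))
            else:
                cols.append(v.to_numpy(float))
    elif covariates is not None:
        arr = np.asarray(covariates, float)
        if arr.ndim == 1:
            arr = arr[:, None]
        cols.extend(arr.T)
    if status is not None:
        cols.append(np.asarray(status, float))
    return np.column_stack(cols)


def _residuals(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene OLS residuals of Y (genes x samples) on X (samples x p)."""
    Q, _ = np.linalg.qr(X)
    fitted = (Y @ Q) @ Q.T
    return Y - fitted, Q


def fit_surrogate_variables(
    counts,
    size_factors,
    covariates,
    status,
    n_sv: int = 3,
    n_iter: int = 5,
    protect_full_model: bool = True,
) -> np.ndarray:
    """Estimate ``n_sv`` surrogate variables from a count matrix.

    Parameters
    ----------
    counts : (genes x samples) array or DataFrame of non-negative counts
    size_factors : per-sample normalisation factors
    covariates : known covariates (DataFrame or array), may be None
    status : protected binary effect (kept in the model whose residuals
        are decomposed when ``protect_full_model``; otherwise only the
        covariates are protected)
    n_sv : number of surrogate variables (0 allowed)
    n_iter : reweighting rounds; 0 reduces to a plain residual SVD

    Returns
    -------
    (samples x n_sv) array; columns are zero-mean, unit-norm, mutually
    orthogonal and orthogonal to the intercept.
    """
    K = np.asarray(counts, float)
    s = np.asarray(size_factors, float)
    if np.any(K < 0):
        raise ValueError("counts must be non-negative")
    n = K.shape[1]
    X = build_design(covariates, status if protect_full_model else None)
    rank = np.linalg.matrix_rank(X)
    if n_sv >= n - rank:
        raise ValueError(f"n_sv={n_sv} too large for {n} samples and design rank {rank}")
    if n_sv == 0:
        return np.empty((n, 0))

    Y = np.log(K / s[None, :] + 1.0)
    keep = Y.std(axis=1) > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("dropping %d constant genes before surrogate estimation", dropped)
    Y = Y[keep]

    R, Q = _residuals(Y, X)
    _, _, Vt = np.linalg.svd(R, full_matrices=False)
    sv = Vt[:n_sv].T

    df_full = n - rank
    for _ in range(n_iter):
        # F-test per gene: does adding the current SVs to the full model help?
        XS = np.column_stack([X, sv])
        R1, _ = _residuals(Y, XS)
        rss0 = np.sum(R * R, axis=1)
        rss1 = np.sum(R1 * R1, axis=1)
        q = sv.shape[1]
        df2 = n - rank - q
        if df2 <= 0:
            break
        with np.errstate(divide="ignore", invalid="ignore"):
            F = ((rss0 - rss1) / q) / (rss1 / df2)
        F = np.where(np.isfinite(F), F, 0.0)
        pvals = stats.f.sf(F, q, df2)
        w = 1.0 - pvals
        _, _, Vt = np.linalg.svd(R * w[:, None], full_matrices=False)
        sv = Vt[:n_sv].T

    # rows of the residual matrix are orthogonal to the design (incl. the
    # intercept), so the right singular vectors are already zero-mean;
    # normalise for safety
    sv = sv - sv.mean(axis=0, keepdims=True)
    sv = sv / np.linalg.norm(sv, axis=0, keepdims=True)
    return sv
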