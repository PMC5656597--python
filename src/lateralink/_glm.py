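"""Internal mass-univariate OLS machinery shared by task and group models."""

from __future__ import annotations

import numpy as np
from scipy import linalg

from .core_io import ParameterError


def ols_contrast_t(
    X: np.ndarray, Y: np.ndarray, contrast: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """Per-column OLS of Y (n x V) on X (n x p); t statistic for c'beta.

    Returns ``(t, beta, df, residuals)``.  Uses the pseudo-inverse, but a
    rank-deficient design is rejected up front with the offending condition
    number, since silently dropping columns would change the contrast meaning.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    c = np.asarray(contrast, dtype=float)
    n, p = X.shape
    if Y.shape[0] != n:
        raise ParameterError(f"design has {n} rows but data has {Y.shape[0]}")
    if c.shape != (p,):
        raise ParameterError(f"contrast must have length {p}")
    if n <= p:
        raise ParameterError("model is saturated: need more rows than columns")
    if np.linalg.matrix_rank(X) < p:
        raise ParameterError(
            "design matrix is rank deficient "
            f"(condition number {np.linalg.cond(X):.3g}); remove collinear columns"
        )
    pinv = linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    df = float(n - p)
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    c_var = float(c @ pinv @ pinv.T @ c)  # c'(X'X)^-1 c
    se = np.sqrt(np.maximum(sigma2 * c_var, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (c @ beta) / np.where(se > 0, se, 1.0), 0.0)
    return t, beta, df, resid
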