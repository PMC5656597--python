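"""Correlation between regional connectivity and laterality.

Per group, the mean Fisher-z connectivity in each significantly different
region is correlated with the subject laterality indices, with plain Pearson
correlation and with Shepherd's pi: Spearman rank correlation after removing
influential outliers flagged by their average squared Mahalanobis distance to
bootstrap-resampled bivariate means, with the p-value doubled (and capped at
1) to pay for the outlier removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core_io import Mask, ParameterError, StatMap

__all__ = [
    "CorrelationResult",
    "roi_mean_z",
    "pearson_correlation",
    "bootstrap_mahalanobis_outliers",
    "shepherd_pi",
]


@dataclass
class CorrelationResult:
    method: str  # "pearson" | "shepherd_pi"
    estimate: float
    p_value: float
    n_used: int
    outlier_indices: np.ndarray = field(default_factory=lambda: np.array([], int))


def roi_mean_z(zmap: StatMap, region: Mask) -> float:
    """Mean Fisher-z connectivity over a region mask."""
    zmap.grid.require_match(region.grid)
    if region.n_voxels == 0:
        raise ParameterError("region mask is empty")
    return float(zmap.values[region.indicator].mean())


def _validate_xy(x, y, n_min: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be 1-D arrays of equal length")
    if x.size < n_min:
        raise ParameterError(f"need at least {n_min} points")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ParameterError("x and y must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ParameterError("x and y must be nonconstant")
    return x, y


def pearson_correlation(x, y) -> CorrelationResult:
    """Product-moment correlation with the two-sided t test (df = n - 2)."""
    x, y = _validate_xy(x, y, 3)
    r, p = stats.pearsonr(x, y)
    return CorrelationResult("pearson", float(r), float(p), x.size)


def bootstrap_mahalanobis_outliers(
    x,
    y,
    n_boot: int = 200,
    cutoff: float = 6.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Flag influential bivariate outliers by bootstrapped Mahalanobis distance.

    For each bootstrap resample of the points, the squared Mahalanobis
    distance of every *original* point to the resample's mean and covariance
    is computed and averaged over resamples; points lying at an average
    distance of at least ``cutoff`` (default 6, the robust-correlation
    convention -- i.e. mean squared distance >= cutoff**2) are outliers.
    Under a clean bivariate normal cloud the squared distance is ~chi^2(2),
    so distance 6 is essentially never reached without genuine contamination.
    """
    x, y = _validate_xy(x, y, 5)
    rng = np.random.default_rng(rng)
    pts = np.column_stack([x, y])
    n = pts.shape[0]
    acc = np.zeros(n)
    used = 0
    for _ in range(n_boot):
        take = rng.integers(0, n, n)
        sample = pts[take]
        cov = np.cov(sample, rowvar=False)
        if np.linalg.det(cov) <= 1e-12:
            continue  # degenerate resample (e.g. duplicated point set)
        inv = np.linalg.inv(cov)
        d = pts - sample.mean(axis=0)
        acc += np.einsum("ij,jk,ik->i", d, inv, d)
        used += 1
    if used == 0:
        raise ParameterError("bivariate covariance is singular in every resample")
    return np.flatnonzero(acc / used >= cutoff**2)


def shepherd_pi(
    x,
    y,
    n_boot: int = 200,
    cutoff: float = 6.0,
    rng: np.random.Generator | int | None = None,
) -> CorrelationResult:
    """Shepherd's pi: Spearman correlation after bootstrapped-Mahalanobis
    outlier removal, with the Spearman p doubled (capped at 1)."""
    x, y = _validate_xy(x, y, 5)
    outliers = bootstrap_mahalanobis_outliers(x, y, n_boot, cutoff, rng)
    keep = np.setdiff1d(np.arange(x.size), outliers)
    if keep.size < 3:
        raise ParameterError("too few points remain after outlier removal")
    xk, yk = x[keep], y[keep]
    if xk.std() == 0 or yk.std() == 0:
        raise ParameterError("retained points are constant")
    rho, p = stats.spearmanr(xk, yk)
    return CorrelationResult(
        "shepherd_pi", float(rho), float(min(1.0, 2.0 * p)), keep.size, outliers
    )
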