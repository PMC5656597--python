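"""Threshold-free laterality index (LI) on task t-maps.

Counting "activated" voxels per hemisphere depends strongly on the chosen
statistical threshold.  The threshold-free LI removes that dependence by
sweeping a grid of thresholds, regressing the suprathreshold voxel count on
the threshold, and summarising each hemisphere by the regression's constant
term A (an extrapolated activation extent).  Then

    LI = (A_left - A_right) / (A_left + A_right),

positive for left-hemisphere dominance, with the conventional categorical
calls: left-lateralized (LI >= 0.2), right-lateralized (LI <= -0.2),
non-lateralized otherwise.  The index is computed separately for the cerebral
and cerebellar compartments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import Mask, ParameterError, StatMap

__all__ = [
    "CountFit",
    "LateralityResult",
    "default_threshold_grid",
    "threshold_sweep_counts",
    "fit_count_regression",
    "laterality_index",
    "categorize_li",
    "REGRESSION_FAMILIES",
]

#: regression families for count-vs-threshold curves, all fitted by ordinary
#: least squares on y = ln(count + 1):
#:   log_linear : y = a - b * theta        (exponential count decay; default)
#:   linear     : count = a - b * theta    (fitted on the raw count scale)
#:   gaussian   : y = a - b * theta**2     (Gaussian-tail count decay)
REGRESSION_FAMILIES = ("log_linear", "linear", "gaussian")


@dataclass
class CountFit:
    """Result of regressing suprathreshold counts on the threshold grid."""

    A: float  # extrapolated count constant (voxels)
    family: str
    r_squared: float
    coef: tuple[float, float]  # (intercept a, slope b) on the fit scale
    all_zero: bool = False


@dataclass
class LateralityResult:
    compartment: str
    A_left: float
    A_right: float
    li: float
    category: str
    defined: bool
    fit_left: CountFit
    fit_right: CountFit
    thresholds: np.ndarray = field(repr=False, default=None)


def default_threshold_grid(
    tmap: StatMap, mask: Mask, n_points: int = 20, p_min: float = 0.001
) -> np.ndarray:
    """Evenly spaced thresholds over the conventionally significant range.

    The grid runs from the one-sided ``p_min`` critical value (of the map's t
    or z distribution) up to the in-mask maximum.  Starting at a significant
    threshold keeps the counts activation-dominated: below it most
    suprathreshold voxels are noise, which is hemispherically symmetric and
    would only dilute the laterality contrast.
    """
    from scipy import stats as _stats

    vals = tmap.masked_values(mask)
    if vals.size == 0:
        raise ParameterError("mask is empty")
    if tmap.stat_kind == "t" and tmap.df > 0:
        lo = float(_stats.t.isf(p_min, tmap.df))
    else:
        lo = float(_stats.norm.isf(p_min))
    top = float(vals.max())
    if top <= lo:
        top = lo + 1.0  # nothing activated; the sweep returns zero counts
    return np.linspace(lo, top * (1.0 - 1e-9), n_points)


def threshold_sweep_counts(
    tmap: StatMap, hemi_mask: Mask, thresholds: np.ndarray
) -> np.ndarray:
    """(threshold, count) pairs: count of in-mask voxels with t > threshold."""
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size < 5 or np.any(np.diff(thresholds) <= 0):
        raise ParameterError("need a strictly increasing grid of >= 5 thresholds")
    vals = tmap.masked_values(hemi_mask)
    counts = np.array([(vals > th).sum() for th in thresholds], dtype=float)
    return np.column_stack([thresholds, counts])


def _fit_family(theta: np.ndarray, counts: np.ndarray, family: str) -> CountFit:
    y = np.log(counts + 1.0)
    if family == "log_linear":
        X = np.column_stack([np.ones_like(theta), theta])
        target = y
    elif family == "gaussian":
        X = np.column_stack([np.ones_like(theta), theta**2])
        target = y
    elif family == "linear":
        X = np.column_stack([np.ones_like(theta), theta])
        target = counts
    else:
        raise ParameterError(f"unknown regression family {family!r}")
    coef, *_ = np.linalg.lstsq(X, target, rcond=None)
    fitted = X @ coef
    ss_res = float(np.sum((target - fitted) ** 2))
    ss_tot = float(np.sum((target - target.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    a, b = float(coef[0]), float(-coef[1])
    A = max(a, 0.0) if family == "linear" else float(np.expm1(a))
    return CountFit(max(A, 0.0), family, r2, (a, b))


def fit_count_regression(
    pairs: np.ndarray, families: tuple[str, ...] = ("log_linear",)
) -> CountFit:
    """Fit count-vs-threshold pairs; the best-R^2 family wins.

    The constant A extrapolates the activated-voxel count to zero threshold
    (A = e^a - 1 for the log families, the intercept for the linear family).
    All-zero counts give A = 0 with a flag instead of an error.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 5:
        raise ParameterError("need >= 5 (threshold, count) pairs")
    theta, counts = pairs[:, 0], pairs[:, 1]
    if np.all(counts == 0):
        return CountFit(0.0, families[0], 1.0, (0.0, 0.0), all_zero=True)
    fits = [_fit_family(theta, counts, fam) for fam in families]
    return max(fits, key=lambda f: f.r_squared)


def laterality_index(
    tmap: StatMap,
    left_mask: Mask,
    right_mask: Mask,
    thresholds: np.ndarray | None = None,
    compartment: str = "cerebral",
    families: tuple[str, ...] = ("log_linear",),
) -> LateralityResult:
    """Threshold-free LI for one subject's t-map over one compartment.

    The same threshold grid (default: 20 points from 0 to the 99.9th
    percentile over both hemispheres) is applied to both sides; each side's
    count curve is regressed and LI formed from the two constants.  When both
    constants vanish the LI is undefined and flagged.
    """
    if thresholds is None:
        both = Mask(
            left_mask.grid, left_mask.indicator | right_mask.indicator, "both"
        )
        thresholds = default_threshold_grid(tmap, both)
    pairs_l = threshold_sweep_counts(tmap, left_mask, thresholds)
    pairs_r = threshold_sweep_counts(tmap, right_mask, thresholds)
    fit_l = fit_count_regression(pairs_l, families)
    fit_r = fit_count_regression(pairs_r, families)
    total = fit_l.A + fit_r.A
    if total > 0:
        li = (fit_l.A - fit_r.A) / total
        defined = True
        category = categorize_li(li)
    else:
        li, defined, category = float("nan"), False, "undefined"
    return LateralityResult(
        compartment, fit_l.A, fit_r.A, li, category, defined, fit_l, fit_r,
        np.asarray(thresholds, dtype=float),
    )


def categorize_li(li: float) -> str:
    """Categorical call: LI >= 0.2 left-, LI <= -0.2 right-, else non-lateralized."""
    if not np.isfinite(li):
        raise ParameterError("LI is not finite")
    if li >= 0.2:
        return "left-lateralized"
    if li <= -0.2:
        return "right-lateralized"
    return "non-lateralized"
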