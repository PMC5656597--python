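"""Block-design task GLM, group-difference maps and seed selection.

The semantic task alternates 30-s semantic-judgement and perceptual-control
blocks (four of each).  A per-subject contrast t-map (semantic minus control)
feeds three downstream consumers: threshold-free laterality indices, a
covaried two-sample group comparison with voxel-wise FDR, and the choice of
seed voxels (regional t maxima) for resting-state connectivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._glm import ols_contrast_t
from .core_io import BoldRun, Mask, ParameterError, StatMap

__all__ = [
    "DesignMatrix",
    "canonical_hrf",
    "build_block_design",
    "fit_glm_contrast",
    "percent_signal_change",
    "group_difference_map",
    "one_sample_tmap",
    "conjunction_map",
    "pick_peak_seeds",
]


@dataclass
class DesignMatrix:
    """GLM design: columns (semantic, control, intercept, drift[, extras])."""

    matrix: np.ndarray  # (T, p)
    labels: list[str]
    tr: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.labels):
            raise ParameterError("design shape does not match labels")

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    def column(self, label: str) -> np.ndarray:
        return self.matrix[:, self.labels.index(label)]

    def contrast_vector(self, plus: str, minus: str | None = None) -> np.ndarray:
        c = np.zeros(len(self.labels))
        c[self.labels.index(plus)] = 1.0
        if minus is not None:
            c[self.labels.index(minus)] = -1.0
        return c


def canonical_hrf(tr: float, duration_s: float = 32.0, dt: float = 0.1) -> np.ndarray:
    """Canonical double-gamma haemodynamic response sampled at ``dt``.

    Peak at 6 s, undershoot at 16 s, peak:undershoot ratio 6; the kernel is
    normalised to unit sum so a sustained block converges to the block
    amplitude, which keeps percent-signal-change estimates in data units.
    """
    t = np.arange(0, duration_s, dt)
    h = stats.gamma.pdf(t, 6.0) - stats.gamma.pdf(t, 16.0) / 6.0
    s = h.sum() * 1.0
    if s <= 0:
        raise ParameterError("degenerate HRF kernel")
    return h / s


def _convolved_boxcar(
    onsets_s: np.ndarray, block_len_s: float, total_s: float, tr: float, dt: float = 0.1
) -> np.ndarray:
    n_fine = int(round(total_s / dt))
    box = np.zeros(n_fine)
    for onset in onsets_s:
        i0 = int(round(onset / dt))
        i1 = int(round((onset + block_len_s) / dt))
        box[i0:i1] = 1.0
    h = canonical_hrf(tr, dt=dt)
    conv = np.convolve(box, h)[:n_fine]
    sample_idx = (np.arange(int(round(total_s / tr))) * (tr / dt)).round().astype(int)
    return conv[sample_idx]


def build_block_design(
    tr: float,
    n_block_pairs: int = 4,
    block_len_s: float = 30.0,
    semantic_first: bool = True,
) -> DesignMatrix:
    """Alternating semantic/control boxcars convolved with the canonical HRF,
    plus intercept and centred linear drift columns."""
    if tr <= 0 or n_block_pairs < 1 or block_len_s <= 0:
        raise ParameterError("invalid design parameters")
    vols_per_block = block_len_s / tr
    if abs(vols_per_block - round(vols_per_block)) > 1e-9:
        raise ParameterError(
            f"block length {block_len_s}s is not an integer number of TRs ({tr}s)"
        )
    total_s = 2 * n_block_pairs * block_len_s
    first = np.arange(n_block_pairs) * 2 * block_len_s
    second = first + block_len_s
    sem_on, ctl_on = (first, second) if semantic_first else (second, first)
    semantic = _convolved_boxcar(sem_on, block_len_s, total_s, tr)
    control = _convolved_boxcar(ctl_on, block_len_s, total_s, tr)
    T = semantic.size
    t = np.arange(T, dtype=float)
    drift = (t - t.mean()) / T
    X = np.column_stack([semantic, control, np.ones(T), drift])
    return DesignMatrix(X, ["semantic", "control", "intercept", "drift"], tr)


def fit_glm_contrast(
    run: BoldRun, design: DesignMatrix, contrast: np.ndarray | None = None
) -> StatMap:
    """Per-voxel OLS contrast t-map; default contrast semantic minus control."""
    if design.n_rows != run.n_volumes:
        raise ParameterError("design rows must match run volumes")
    if contrast is None:
        contrast = design.contrast_vector("semantic", "control")
    t, _, df, _ = ols_contrast_t(design.matrix, run.data, contrast)
    return StatMap(run.grid, t, "t", df)


def percent_signal_change(run: BoldRun, design: DesignMatrix, roi: Mask) -> float:
    """Semantic-vs-control fitted amplitude as % of the fitted baseline,
    averaged over the ROI."""
    run.grid.require_match(roi.grid)
    if roi.n_voxels == 0:
        raise ParameterError("ROI is empty")
    c = design.contrast_vector("semantic", "control")
    _, beta, _, _ = ols_contrast_t(design.matrix, run.data[:, roi.indicator], c)
    amplitude = c @ beta
    baseline = beta[design.labels.index("intercept")]
    if np.any(baseline <= 0):
        raise ParameterError("non-positive fitted baseline in ROI")
    return float(np.mean(100.0 * amplitude / baseline))


def _group_design(
    groups: np.ndarray, covariates: pd.DataFrame | None
) -> tuple[np.ndarray, np.ndarray]:
    """Intercept + group indicator + centred covariates; contrast on group."""
    n = groups.size
    cols = [np.ones(n), groups.astype(float)]
    if covariates is not None and covariates.shape[1] > 0:
        Z = covariates.to_numpy(dtype=float)
        Z = Z - Z.mean(axis=0)
        sd = Z.std(axis=0)
        if np.any(sd == 0):
            warnings.warn("dropping constant covariate column(s)", stacklevel=3)
            Z = Z[:, sd > 0]
        cols.extend(Z.T)
    X = np.column_stack(cols)
    g = groups.astype(float) - groups.mean()
    for j in range(2, X.shape[1]):
        z = X[:, j]
        r = np.corrcoef(g, z)[0, 1] if z.std() > 0 else 0.0
        if abs(r) > 0.95:
            warnings.warn(
                f"covariate column {j - 2} is nearly collinear with group "
                f"(|r| = {abs(r):.3f}; design condition number "
                f"{np.linalg.cond(X):.3g}); proceeding",
                stacklevel=3,
            )
    c = np.zeros(X.shape[1])
    c[1] = 1.0
    return X, c


def encode_covariates(table: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Numeric covariate frame; ``sex`` is coded F=0 / M=1."""
    out = {}
    for col in columns:
        v = table[col]
        if col == "sex":
            out[col] = v.map({"F": 0.0, "M": 1.0}).astype(float)
        else:
            out[col] = v.astype(float)
    return pd.DataFrame(out)


def group_difference_map(
    tmaps: list[StatMap],
    groups: np.ndarray,
    covariates: pd.DataFrame | None = None,
    mask: Mask | None = None,
    q: float = 0.01,
) -> tuple[StatMap, Mask]:
    """Covaried two-sample comparison of subject maps with BH-FDR at ``q``.

    ``groups`` is a 0/1 indicator (1 = second group); the returned t is for
    the group coefficient, positive where group 1 exceeds group 0.
    """
    if not tmaps:
        raise ParameterError("no subject maps")
    grid = tmaps[0].grid
    for m in tmaps[1:]:
        grid.require_match(m.grid)
    groups = np.asarray(groups)
    if groups.size != len(tmaps):
        raise ParameterError("groups length must match number of maps")
    if min((groups == 0).sum(), (groups == 1).sum()) < 3:
        raise ParameterError("need at least 3 subjects per group")
    Y = np.stack([m.values for m in tmaps])
    X, c = _group_design(groups, covariates)
    t, _, df, _ = ols_contrast_t(X, Y, c)
    tmap = StatMap(grid, t, "t", df)
    in_mask = mask.indicator if mask is not None else np.ones(grid.n_voxels, bool)
    p = 2.0 * stats.t.sf(np.abs(t[in_mask]), df)
    sig = np.zeros(grid.n_voxels, bool)
    if p.size:
        rej, *_ = multipletests(p, alpha=q, method="fdr_bh")
        sig[np.flatnonzero(in_mask)] = rej
    return tmap, Mask(grid, sig, f"fdr_q{q}")


def one_sample_tmap(maps: list[StatMap], mask: Mask | None = None) -> StatMap:
    """One-sample t across subjects (group-level activation map)."""
    if len(maps) < 2:
        raise ParameterError("need at least 2 subject maps")
    grid = maps[0].grid
    for m in maps[1:]:
        grid.require_match(m.grid)
    Y = np.stack([m.values for m in maps])
    n = Y.shape[0]
    mean = Y.mean(axis=0)
    sd = Y.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    return StatMap(grid, t, "t", n - 1)


def conjunction_map(
    tmap_a: StatMap, tmap_b: StatMap, threshold: float
) -> Mask:
    """Minimum-statistic conjunction: voxels where both maps exceed threshold."""
    tmap_a.grid.require_match(tmap_b.grid)
    conj = np.minimum(tmap_a.values, tmap_b.values) > threshold
    return Mask(tmap_a.grid, conj, "conjunction")


def pick_peak_seeds(sig_map: StatMap, regions: dict[str, Mask]) -> pd.DataFrame:
    """One seed per region at the regional t maximum (Table-1 style rows).

    Ties break to the smallest flat voxel index, so the choice is
    deterministic.  Columns: label, hem, x, y, z, peak_t.
    """
    rows = []
    coords = sig_map.grid.voxel_coords_world()
    for label, region in regions.items():
        sig_map.grid.require_match(region.grid)
        idx = np.flatnonzero(region.indicator)
        if idx.size == 0:
            raise ParameterError(f"region {label!r} is empty")
        vals = sig_map.values[idx]
        best = idx[int(np.argmax(vals))]  # argmax returns first max: tie rule
        x, y, z = coords[best]
        hem = "L" if x < 0 else ("R" if x > 0 else "L/R")
        rows.append(
            {
                "label": label,
                "hem": hem,
                "x": float(x),
                "y": float(y),
                "z": float(z),
                "peak_t": float(sig_map.values[best]),
            }
        )
    return pd.DataFrame(rows)
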