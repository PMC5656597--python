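"""Group comparison of connectivity maps with Monte-Carlo cluster correction.

The voxel-wise two-sample model (with age, sex and mean-FD covariates) yields
a group-difference t-map.  Familywise error over voxels is controlled at the
cluster level, AlphaSim style: Gaussian null fields matching the residual
smoothness are simulated on the analysis mask, thresholded at the voxel p,
and the observed maximum cluster sizes give the minimum extent ``threshold_k``
whose familywise rate is at most ``alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage import measure

from ._glm import ols_contrast_t
from .core_io import Mask, ParameterError, StatMap
from .preprocess import FWHM_TO_SIGMA
from .task_activation import _group_design

__all__ = [
    "ClusterRecord",
    "ClusterNull",
    "voxelwise_group_glm",
    "estimate_smoothness",
    "montecarlo_cluster_threshold",
    "extract_clusters",
    "cluster_table",
    "degree_summary",
]

_SKIMAGE_CONNECTIVITY = {6: 1, 18: 2, 26: 3}


@dataclass
class ClusterRecord:
    """A suprathreshold connected component (one row of a cluster table)."""

    label: str
    hemisphere: str
    peak_mm: tuple[float, float, float]
    peak_t: float
    extent: int
    voxel_indices: np.ndarray = field(repr=False, default=None)


@dataclass
class ClusterNull:
    """Monte-Carlo null of the maximum cluster size on a mask."""

    voxel_p: float
    alpha: float
    n_iterations: int
    fwhm_mm: tuple[float, float, float]
    max_sizes: np.ndarray
    threshold_k: int
    two_sided: bool = True


def voxelwise_group_glm(
    zmaps: list[StatMap],
    groups: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> tuple[StatMap, list[StatMap]]:
    """Per-voxel group-coefficient t for subject z-maps; returns the t-map and
    per-subject residual maps (used for smoothness estimation)."""
    if not zmaps:
        raise ParameterError("no subject maps")
    grid = zmaps[0].grid
    for m in zmaps[1:]:
        grid.require_match(m.grid)
    groups = np.asarray(groups)
    if min((groups == 0).sum(), (groups == 1).sum()) < 3:
        raise ParameterError("need at least 3 subjects per group")
    Y = np.stack([m.values for m in zmaps])
    X, c = _group_design(groups, covariates)
    t, _, df, resid = ols_contrast_t(X, Y, c)
    residual_maps = [StatMap(grid, resid[i], "z", 0.0) for i in range(resid.shape[0])]
    return StatMap(grid, t, "t", df), residual_maps


def estimate_smoothness(
    residual_maps: list[StatMap], mask: Mask
) -> tuple[float, float, float]:
    """Per-axis FWHM (mm) of the residual random field.

    Uses the Gaussian-autocorrelation estimator: with neighbour correlation
    rho along an axis, sigma^2 = -dx^2 / (4 ln rho) and FWHM =
    sqrt(8 ln 2) sigma.  Independent noise gives rho <= 0 and FWHM 0 (below
    voxel size); a constant image has no defined smoothness and is an error.
    """
    if not residual_maps:
        raise ParameterError("no residual maps")
    grid = residual_maps[0].grid
    grid.require_match(mask.grid)
    ind3 = mask.indicator.reshape(grid.dims)
    vols = np.stack([m.values.reshape(grid.dims) for m in residual_maps])
    var = float(np.mean(vols[:, ind3] ** 2))
    if var <= 0:
        raise ParameterError("residuals are identically zero; smoothness undefined")
    fwhm = []
    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(1, None)
        sl_b[axis] = slice(None, -1)
        pair = ind3[tuple(sl_a)] & ind3[tuple(sl_b)]
        if not pair.any():
            fwhm.append(0.0)
            continue
        diffs = (vols[(slice(None),) + tuple(sl_a)] -
                 vols[(slice(None),) + tuple(sl_b)])[:, pair]
        s2 = float(np.mean(diffs**2))
        rho = 1.0 - s2 / (2.0 * var)
        dx = float(grid.voxel_size[axis])
        if rho <= 0:
            fwhm.append(0.0)
        else:
            sigma = np.sqrt(-(dx**2) / (4.0 * np.log(rho)))
            fwhm.append(float(np.sqrt(8.0 * np.log(2.0)) * sigma))
    return tuple(fwhm)


def _field_sd_map(sigma_vox: np.ndarray, dims: tuple[int, int, int]) -> np.ndarray:
    """Exact per-voxel sd of zero-padded Gaussian-smoothed unit white noise.

    The kernel is separable and the volume a box, so the variance at voxel
    (i, j, k) factorises into per-axis sums of squared truncated kernel
    weights; near the edges part of the kernel mass falls outside the volume
    and the variance drops, which must be normalised away before applying a
    global voxel threshold.
    """
    axis_vars = []
    for s, d in zip(sigma_vox, dims):
        if s <= 0:
            axis_vars.append(np.ones(d))
            continue
        radius = int(4.0 * float(s) + 0.5)
        x = np.arange(-radius, radius + 1)
        k = np.exp(-0.5 * (x / s) ** 2)
        k /= k.sum()
        k2 = k**2
        # positions j in [0, d): weight k[i - j] contributes when |i-j|<=radius
        v = np.empty(d)
        for i in range(d):
            j0 = max(0, i - radius)
            j1 = min(d, i + radius + 1)
            v[i] = k2[(j0 - i) + radius : (j1 - i) + radius].sum()
        axis_vars.append(v)
    var3 = (
        axis_vars[0][:, None, None]
        * axis_vars[1][None, :, None]
        * axis_vars[2][None, None, :]
    )
    return np.sqrt(var3)


def montecarlo_cluster_threshold(
    mask: Mask,
    fwhm_mm: tuple[float, float, float] | float = 0.0,
    voxel_p: float = 0.01,
    alpha: float = 0.01,
    iters: int = 10_000,
    rng: np.random.Generator | int | None = None,
    two_sided: bool = True,
    connectivity: int = 26,
) -> ClusterNull:
    """AlphaSim-style Monte-Carlo cluster-extent threshold.

    Simulates unit-variance Gaussian fields smoothed to ``fwhm_mm``,
    thresholds voxels at ``voxel_p`` within ``mask`` and records the maximum
    cluster size; ``threshold_k`` is the smallest extent whose familywise
    exceedance probability is at most ``alpha``.
    """
    if mask.n_voxels == 0:
        raise ParameterError("mask is empty")
    if not 0 < voxel_p < 1 or not 0 < alpha <= 1:
        raise ParameterError("voxel_p in (0,1) and alpha in (0,1] required")
    rng = np.random.default_rng(rng)
    if np.isscalar(fwhm_mm):
        fwhm_mm = (float(fwhm_mm),) * 3
    grid = mask.grid
    dims = grid.dims
    ind3 = mask.indicator.reshape(dims)
    sigma_vox = np.asarray(fwhm_mm, float) * FWHM_TO_SIGMA / grid.voxel_size
    do_smooth = np.any(sigma_vox > 0)
    sd_map = _field_sd_map(sigma_vox, dims) if do_smooth else None
    zc = stats.norm.isf(voxel_p / 2.0) if two_sided else stats.norm.isf(voxel_p)
    conn = _SKIMAGE_CONNECTIVITY[connectivity]
    max_sizes = np.zeros(iters, dtype=int)
    for i in range(iters):
        field3 = rng.standard_normal(dims)
        if do_smooth:
            field3 = (
                ndimage.gaussian_filter(field3, sigma_vox, mode="constant") / sd_map
            )
        biggest = 0
        excursions = (field3 > zc, field3 < -zc) if two_sided else (field3 > zc,)
        for exc in excursions:
            exc = exc & ind3
            if exc.any():
                lab = measure.label(exc, connectivity=conn)
                sizes = np.bincount(lab.ravel())[1:]
                if sizes.size:
                    biggest = max(biggest, int(sizes.max()))
        max_sizes[i] = biggest
    k = 1
    while np.mean(max_sizes >= k) > alpha:
        k += 1
    return ClusterNull(voxel_p, alpha, iters, tuple(fwhm_mm), max_sizes, k, two_sided)


def extract_clusters(
    tmap: StatMap,
    voxel_threshold: float,
    threshold_k: int = 1,
    connectivity: int = 26,
    mask: Mask | None = None,
    two_sided: bool = True,
    label_volume: np.ndarray | None = None,
    label_names: dict[int, str] | None = None,
) -> list[ClusterRecord]:
    """Connected suprathreshold components with extent >= ``threshold_k``.

    Positive and negative excursions (|t| > threshold when ``two_sided``) are
    labelled separately so a cluster never mixes signs.  The peak is the
    max-|t| voxel; an optional integer label volume names the peak's region.
    """
    if connectivity not in _SKIMAGE_CONNECTIVITY:
        raise ParameterError("connectivity must be 6, 18 or 26")
    grid = tmap.grid
    vals3 = tmap.values.reshape(grid.dims)
    in_mask = (
        mask.indicator.reshape(grid.dims)
        if mask is not None
        else np.ones(grid.dims, bool)
    )
    coords = grid.voxel_coords_world()
    conn = _SKIMAGE_CONNECTIVITY[connectivity]
    excursions = [vals3 > voxel_threshold]
    if two_sided:
        excursions.append(vals3 < -voxel_threshold)
    records: list[ClusterRecord] = []
    for exc in excursions:
        exc = exc & in_mask
        if not exc.any():
            continue
        lab = measure.label(exc, connectivity=conn)
        for comp in range(1, lab.max() + 1):
            flat_idx = np.flatnonzero((lab == comp).ravel())
            if flat_idx.size < threshold_k:
                continue
            comp_vals = tmap.values[flat_idx]
            peak = flat_idx[int(np.argmax(np.abs(comp_vals)))]
            x, y, z = coords[peak]
            hem = "L" if x < 0 else ("R" if x > 0 else "L/R")
            name = ""
            if label_volume is not None:
                code = int(np.asarray(label_volume).ravel()[peak])
                name = (label_names or {}).get(code, str(code) if code else "")
            records.append(
                ClusterRecord(
                    label=name,
                    hemisphere=hem,
                    peak_mm=(float(x), float(y), float(z)),
                    peak_t=float(tmap.values[peak]),
                    extent=int(flat_idx.size),
                    voxel_indices=flat_idx,
                )
            )
    records.sort(key=lambda r: -abs(r.peak_t))
    return records


def cluster_table(records: list[ClusterRecord]) -> pd.DataFrame:
    """Tabulate cluster records (label, hem, peak x/y/z, peak t, extent)."""
    return pd.DataFrame(
        [
            {
                "label": r.label,
                "hem": r.hemisphere,
                "x": r.peak_mm[0],
                "y": r.peak_mm[1],
                "z": r.peak_mm[2],
                "peak_t": r.peak_t,
                "extent": r.extent,
            }
            for r in records
        ],
        columns=["label", "hem", "x", "y", "z", "peak_t", "extent"],
    )


def degree_summary(tables: dict[str, pd.DataFrame]) -> dict[str, int]:
    """Seed degree: number of distinct (label, hemisphere) regions per seed."""
    out = {}
    for seed, table in tables.items():
        if table.empty:
            out[seed] = 0
        else:
            out[seed] = int(table[["label", "hem"]].drop_duplicates().shape[0])
    return out
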