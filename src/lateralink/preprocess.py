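"""Motion QC, framewise displacement, nuisance regression, filtering, smoothing.

The resting-state pipeline applies, in order: nuisance regression (six motion
parameters plus white-matter and ventricular mean signals), temporal band-pass
filtering (0.01-0.08 Hz), and linear detrending.  Spatial smoothing is applied
to connectivity z-maps before group comparison, not to raw runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .core_io import BoldRun, Mask, ParameterError, StatMap

__all__ = [
    "FdSeries",
    "QcDecision",
    "framewise_displacement",
    "motion_qc",
    "nuisance_regress",
    "build_nuisance_regressors",
    "detrend_linear",
    "bandpass_filter",
    "gaussian_smooth",
    "preprocess_rest",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class FdSeries:
    """Framewise displacement: per-transition scalar head motion in mm."""

    values: np.ndarray  # (T-1,)
    mean_fd: float
    max_fd: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ParameterError("FD values must be nonnegative")


@dataclass
class QcDecision:
    included: bool
    reason: str = ""  # "", "translation", "rotation", "fd"
    max_translation_mm: float = 0.0
    max_rotation_deg: float = 0.0
    max_fd_mm: float = 0.0
    mean_fd_mm: float = 0.0


def framewise_displacement(
    motion: np.ndarray, head_radius_mm: float = 50.0
) -> FdSeries:
    """Power-style FD: sum of absolute backward differences of the six
    rigid-body parameters, rotations converted to arc length on a
    ``head_radius_mm`` sphere (default 50 mm).
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ParameterError("motion must be (T, 6): 3 translations mm, 3 rotations rad")
    if motion.shape[0] < 2:
        raise ParameterError("need at least two time points for FD")
    d = np.diff(motion, axis=0)
    fd = np.abs(d[:, :3]).sum(axis=1) + head_radius_mm * np.abs(d[:, 3:]).sum(axis=1)
    return FdSeries(fd, float(fd.mean()), float(fd.max()))


def motion_qc(
    motion: np.ndarray,
    trans_limit_mm: float = 1.0,
    rot_limit_deg: float = 1.0,
    fd_limit_mm: float = 0.5,
    head_radius_mm: float = 50.0,
) -> QcDecision:
    """Exclusion rule: any |translation| > 1 mm, any |rotation| > 1 degree,
    or maximum FD at/over 0.5 mm excludes the run."""
    motion = np.asarray(motion, dtype=float)
    fd = framewise_displacement(motion, head_radius_mm)
    max_t = float(np.abs(motion[:, :3]).max())
    max_r = float(np.rad2deg(np.abs(motion[:, 3:]).max()))
    if max_t > trans_limit_mm:
        reason = "translation"
    elif max_r > rot_limit_deg:
        reason = "rotation"
    elif fd.max_fd >= fd_limit_mm:
        reason = "fd"
    else:
        reason = ""
    return QcDecision(reason == "", reason, max_t, max_r, fd.max_fd, fd.mean_fd)


def nuisance_regress(run: BoldRun, regressors: np.ndarray) -> BoldRun:
    """Residualise every voxel on the nuisance design (intercept added)."""
    R = np.asarray(regressors, dtype=float)
    if R.ndim == 1:
        R = R[:, None]
    T = run.n_volumes
    if R.shape[0] != T:
        raise ParameterError("regressors must have one row per volume")
    if not np.all(np.isfinite(R)):
        raise ParameterError("regressors contain non-finite values")
    X = np.column_stack([np.ones(T), R])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # keep a maximal independent subset so the projection is still exact
        keep, basis = [], np.zeros((T, 0))
        for j in range(X.shape[1]):
            cand = np.column_stack([basis, X[:, j]])
            if np.linalg.matrix_rank(cand) > basis.shape[1]:
                keep.append(j)
                basis = cand
        X = X[:, keep]
    if X.shape[1] >= T:
        raise ParameterError("more nuisance regressors than time points")
    beta, *_ = np.linalg.lstsq(X, run.data, rcond=None)
    return run.with_data(run.data - X @ beta)


def build_nuisance_regressors(
    run: BoldRun, motion: np.ndarray, wm_mask: Mask, vent_mask: Mask
) -> np.ndarray:
    """Six motion parameters plus WM and ventricle mean signals (T x 8)."""
    motion = np.asarray(motion, dtype=float)
    if motion.shape != (run.n_volumes, 6):
        raise ParameterError("motion must be (T, 6) matching the run")
    cols = [motion]
    for m in (wm_mask, vent_mask):
        run.grid.require_match(m.grid)
        if m.n_voxels == 0:
            raise ParameterError(f"nuisance mask {m.name!r} is empty")
        cols.append(run.data[:, m.indicator].mean(axis=1, keepdims=True))
    return np.column_stack(cols)


def detrend_linear(run: BoldRun) -> BoldRun:
    """Remove the per-voxel least-squares line (mean and linear trend)."""
    T = run.n_volumes
    t = np.arange(T, dtype=float)
    X = np.column_stack([np.ones(T), t - t.mean()])
    beta, *_ = np.linalg.lstsq(X, run.data, rcond=None)
    return run.with_data(run.data - X @ beta)


def bandpass_filter(
    run: BoldRun, low_hz: float = 0.01, high_hz: float = 0.08, order: int = 2
) -> BoldRun:
    """Zero-phase Butterworth band-pass (forward-backward, edge-padded)."""
    if not 0 < low_hz < high_hz:
        raise ParameterError("need 0 < low_hz < high_hz")
    nyquist = 0.5 / run.tr
    if high_hz >= nyquist:
        raise ParameterError(
            f"high cutoff {high_hz} Hz is at or above Nyquist {nyquist:.4g} Hz"
        )
    sos = signal.butter(
        order, [low_hz, high_hz], btype="bandpass", fs=1.0 / run.tr, output="sos"
    )
    padlen = min(run.n_volumes - 1, 3 * int(np.ceil(1.0 / (low_hz * run.tr))))
    filtered = signal.sosfiltfilt(sos, run.data, axis=0, padtype="even", padlen=padlen)
    return run.with_data(filtered)


def _smooth_volume(vol: np.ndarray, fwhm_mm: float, voxel_size: np.ndarray) -> np.ndarray:
    # reflective boundaries keep constants constant and conserve total mass
    sigma_vox = (fwhm_mm * FWHM_TO_SIGMA) / np.asarray(voxel_size, dtype=float)
    return ndimage.gaussian_filter(vol, sigma=sigma_vox, mode="reflect")


def gaussian_smooth(volume, fwhm_mm: float = 8.0):
    """Isotropic Gaussian smoothing of a StatMap or BoldRun (per volume).

    ``fwhm_mm`` is the kernel full width at half maximum in world mm;
    ``fwhm_mm = 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ParameterError("fwhm must be nonnegative")
    if fwhm_mm == 0:
        return volume
    if isinstance(volume, StatMap):
        vol = volume.values.reshape(volume.grid.dims)
        sm = _smooth_volume(vol, fwhm_mm, volume.grid.voxel_size)
        return StatMap(volume.grid, sm.ravel(), volume.stat_kind, volume.df)
    if isinstance(volume, BoldRun):
        out = np.empty_like(volume.data, dtype=float)
        for t in range(volume.n_volumes):
            out[t] = _smooth_volume(
                volume.data[t].reshape(volume.grid.dims),
                fwhm_mm,
                volume.grid.voxel_size,
            ).ravel()
        return volume.with_data(out)
    raise ParameterError(f"cannot smooth {type(volume).__name__}")


def preprocess_rest(
    run: BoldRun,
    motion: np.ndarray,
    wm_mask: Mask,
    vent_mask: Mask,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
) -> BoldRun:
    """Full resting-state chain: nuisance regression, band-pass, detrend."""
    regressors = build_nuisance_regressors(run, motion, wm_mask, vent_mask)
    out = nuisance_regress(run, regressors)
    out = bandpass_filter(out, low_hz=low_hz, high_hz=high_hz)
    return detrend_linear(out)
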