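"""Seed time-series extraction and voxel-wise RSFC z-maps.

Resting-state functional connectivity (RSFC) is the Pearson correlation
between a seed ROI's mean time series and every other voxel, Fisher
r-to-z transformed for group statistics.  Smoothing of z-maps (before group
comparison) lives in :mod:`lateralink.preprocess`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import BoldRun, Mask, ParameterError, StatMap

__all__ = ["ConnectivityMap", "extract_seed_timeseries", "rsfc_zmap", "R_CLIP"]

#: correlations are clipped to +/-(1 - R_CLIP) before atanh so seed voxels
#: (r = 1 with themselves) map to a finite z.
R_CLIP = 1e-7


@dataclass
class ConnectivityMap:
    """A Fisher-z RSFC map for one subject and one seed."""

    zmap: StatMap
    seed_label: str
    subject_id: str
    constant_voxels: np.ndarray | None = None  # flat indices set to z = 0


def extract_seed_timeseries(run: BoldRun, roi: Mask) -> np.ndarray:
    """Mean BOLD series over the ROI voxels (the seed regressor)."""
    run.grid.require_match(roi.grid)
    if roi.n_voxels == 0:
        raise ParameterError("seed ROI is empty")
    return run.data[:, roi.indicator].mean(axis=1)


def rsfc_zmap(
    run: BoldRun, seed_series: np.ndarray, seed_label: str = ""
) -> ConnectivityMap:
    """Voxel-wise Pearson correlation with the seed series, Fisher transformed.

    Constant voxels (zero variance) get z = 0 and are reported in
    ``constant_voxels`` rather than propagating NaNs.
    """
    s = np.asarray(seed_series, dtype=float)
    if s.shape != (run.n_volumes,):
        raise ParameterError("seed series length must match run volumes")
    s_c = s - s.mean()
    s_norm = np.sqrt(s_c @ s_c)
    if s_norm == 0:
        raise ParameterError("seed series is constant")
    Y = run.data - run.data.mean(axis=0)
    y_norm = np.sqrt(np.einsum("ij,ij->j", Y, Y))
    constant = y_norm == 0
    denom = np.where(constant, 1.0, y_norm) * s_norm
    r = (s_c @ Y) / denom
    r[constant] = 0.0
    r = np.clip(r, -(1.0 - R_CLIP), 1.0 - R_CLIP)
    z = np.arctanh(r)
    z[constant] = 0.0
    return ConnectivityMap(
        StatMap(run.grid, z, "z", 0.0),
        seed_label,
        run.subject_id,
        np.flatnonzero(constant) if constant.any() else None,
    )
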