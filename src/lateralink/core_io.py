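"""Volume data model and NIfTI/TSV input-output.

All volumes in a ``lateralink`` analysis live on a shared :class:`VolumeGrid`
(the study's normalised 3 mm stereotaxic grid, or a smaller phantom grid for
simulation work).  Voxel data are stored flat, in C order over ``(i, j, k)``
voxel indices, so a time series is a ``(T, V)`` array and a statistic map a
``(V,)`` vector.  World coordinates follow the MNI sign convention: +x right,
+y anterior, +z superior, in millimetres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VolumeGrid",
    "BoldRun",
    "Mask",
    "StatMap",
    "SubjectRecord",
    "FormatError",
    "GridMismatchError",
    "GeometryError",
    "ParameterError",
    "make_hemisphere_masks",
    "sphere_roi_mask",
    "read_bold",
    "write_bold",
    "read_statmap",
    "write_statmap",
    "read_mask",
    "write_mask",
    "roundtrip_volume",
    "read_motion_tsv",
    "write_motion_tsv",
    "MOTION_COLUMNS",
]

#: Required column order for motion-parameter tables (rotations in radians).
MOTION_COLUMNS = (
    "trans_x_mm",
    "trans_y_mm",
    "trans_z_mm",
    "rot_x_rad",
    "rot_y_rad",
    "rot_z_rad",
)


class FormatError(ValueError):
    """Raised when a file cannot be parsed as the expected format."""


class GridMismatchError(ValueError):
    """Raised when two objects that must share a grid do not."""


class GeometryError(ValueError):
    """Raised for degenerate grid geometry (e.g. singular affine)."""


class ParameterError(ValueError):
    """Raised for invalid user-supplied parameter values."""


@dataclass(frozen=True)
class VolumeGrid:
    """A regular 3-D voxel grid with a voxel-to-world affine.

    Parameters
    ----------
    dims
        Number of voxels along (i, j, k).
    affine
        4x4 matrix mapping 0-based voxel indices to world mm (MNI
        convention: +x right, +y anterior, +z superior).
    """

    dims: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        if len(dims) != 3 or any(d < 1 for d in dims):
            raise GeometryError(f"dims must be 3 positive integers, got {self.dims}")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise GeometryError("affine must be 4x4")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise GeometryError("affine is singular")
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "affine", aff)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the 3x3 affine block)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_coords_world(self) -> np.ndarray:
        """World-mm centres of all voxels, shape (V, 3), C order over (i,j,k)."""
        ijk = np.stack(
            np.unravel_index(np.arange(self.n_voxels), self.dims), axis=1
        ).astype(float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def matches(self, other: "VolumeGrid", atol: float = 1e-4) -> bool:
        return self.dims == other.dims and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def require_match(self, other: "VolumeGrid") -> None:
        if not self.matches(other):
            raise GridMismatchError("volumes are not on the same grid")

    @classmethod
    def isotropic(
        cls, dims: tuple[int, int, int], voxel_mm: float = 3.0, centered: bool = True
    ) -> "VolumeGrid":
        """Axis-aligned isotropic grid; ``centered`` puts world 0 mid-grid.

        With even dims the midline plane x = 0 falls *between* voxel columns,
        so no voxel centre sits exactly on it.
        """
        aff = np.eye(4)
        aff[:3, :3] *= voxel_mm
        if centered:
            aff[:3, 3] = -voxel_mm * (np.asarray(dims, float) - 1) / 2.0
        return cls(tuple(dims), aff)


def _check_finite(arr: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(arr)):
        raise ParameterError(f"{what} contains non-finite values")


@dataclass
class BoldRun:
    """A 4-D BOLD time series: ``data[t, v]`` on ``grid``, repetition time ``tr``."""

    grid: VolumeGrid
    data: np.ndarray  # (T, V)
    tr: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2 or self.data.shape[1] != self.grid.n_voxels:
            raise ParameterError(
                f"data must be (T, V={self.grid.n_voxels}), got {self.data.shape}"
            )
        if self.data.shape[0] < 2:
            raise ParameterError("a BOLD run needs at least 2 time points")
        if self.tr <= 0:
            raise ParameterError("tr must be positive")
        _check_finite(self.data, "BOLD data")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    def with_data(self, data: np.ndarray) -> "BoldRun":
        return BoldRun(self.grid, data, self.tr, self.subject_id)


@dataclass
class Mask:
    """A boolean voxel set on a grid."""

    grid: VolumeGrid
    indicator: np.ndarray  # (V,) bool
    name: str = ""

    def __post_init__(self) -> None:
        ind = np.asarray(self.indicator)
        if ind.shape != (self.grid.n_voxels,):
            raise ParameterError("indicator length must equal grid voxel count")
        self.indicator = ind.astype(bool)

    @property
    def n_voxels(self) -> int:
        return int(self.indicator.sum())

    def __and__(self, other: "Mask") -> "Mask":
        self.grid.require_match(other.grid)
        return Mask(self.grid, self.indicator & other.indicator,
                    f"{self.name}&{other.name}")

    def __or__(self, other: "Mask") -> "Mask":
        self.grid.require_match(other.grid)
        return Mask(self.grid, self.indicator | other.indicator,
                    f"{self.name}|{other.name}")


@dataclass
class StatMap:
    """A per-voxel statistic image (t, z or r) with degrees of freedom."""

    grid: VolumeGrid
    values: np.ndarray  # (V,)
    stat_kind: str = "t"
    df: float = 0.0

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (self.grid.n_voxels,):
            raise ParameterError("values length must equal grid voxel count")
        if self.stat_kind not in ("t", "z", "r"):
            raise ParameterError(f"stat_kind must be t/z/r, got {self.stat_kind!r}")
        if self.stat_kind == "t" and self.df <= 0:
            raise ParameterError("t maps need df > 0")
        self.values = vals

    def masked_values(self, mask: Mask) -> np.ndarray:
        self.grid.require_match(mask.grid)
        return self.values[mask.indicator]


@dataclass
class SubjectRecord:
    """Per-subject covariates; ``mean_fd`` is filled in by preprocessing."""

    subject_id: str
    group: str  # "LH" or "RH"
    age: float
    sex: str  # "F" / "M"
    education: float
    ehi: float
    mean_fd: float = float("nan")

    def __post_init__(self) -> None:
        if not self.group:
            raise ParameterError("group must be nonempty")
        if not -100.0 <= self.ehi <= 100.0:
            raise ParameterError("EHI score must lie in [-100, 100]")


# ---------------------------------------------------------------------------
# hemisphere and spherical ROI masks
# ---------------------------------------------------------------------------

def make_hemisphere_masks(grid: VolumeGrid, brain_mask: Mask) -> tuple[Mask, Mask]:
    """Split a brain mask at the world midsagittal plane x = 0.

    Voxels whose centre lies exactly on x = 0 belong to neither hemisphere,
    so the laterality voxel counts never double-count midline tissue.
    """
    grid.require_match(brain_mask.grid)
    x = grid.voxel_coords_world()[:, 0]
    left = brain_mask.indicator & (x < 0)
    right = brain_mask.indicator & (x > 0)
    return Mask(grid, left, "left"), Mask(grid, right, "right")


def sphere_roi_mask(
    grid: VolumeGrid, center_mm, radius_mm: float, name: str = "sphere"
) -> Mask:
    """Spherical ROI: voxels whose centre is within ``radius_mm`` of ``center_mm``.

    A centre outside the grid yields an empty mask with a warning, not an
    error, so scripted seed tables with a stray coordinate fail soft.
    """
    if radius_mm <= 0:
        raise ParameterError("radius must be positive")
    center = np.asarray(center_mm, dtype=float)
    if center.shape != (3,):
        raise ParameterError("center_mm must be a 3-vector")
    coords = grid.voxel_coords_world()
    dist2 = np.sum((coords - center) ** 2, axis=1)
    ind = dist2 <= radius_mm**2
    if not ind.any():
        warnings.warn(
            f"sphere ROI at {tuple(center)} r={radius_mm} mm contains no voxels",
            stacklevel=2,
        )
    return Mask(grid, ind, name)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _grid_from_img(img: nib.Nifti1Image) -> VolumeGrid:
    return VolumeGrid(tuple(img.shape[:3]), np.asarray(img.affine))


def _load_nifti(path) -> nib.Nifti1Image:
    try:
        img = nib.load(str(path))
        img.get_fdata()  # force a full read so truncation surfaces here
        return img
    except FileNotFoundError:
        raise
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read {path} as NIfTI: {exc}") from exc


def write_bold(path, run: BoldRun) -> None:
    arr = np.moveaxis(
        run.data.reshape((run.n_volumes,) + run.grid.dims), 0, -1
    ).astype(np.float32)
    img = nib.Nifti1Image(arr, run.grid.affine)
    img.header.set_zooms(tuple(run.grid.voxel_size) + (run.tr,))
    nib.save(img, str(path))


def read_bold(path, subject_id: str = "") -> BoldRun:
    img = _load_nifti(path)
    if img.ndim != 4:
        raise FormatError(f"{path} is not a 4-D BOLD image")
    data = np.moveaxis(img.get_fdata(dtype=np.float32), -1, 0)
    tr = float(img.header.get_zooms()[3])
    return BoldRun(
        _grid_from_img(img), data.reshape(data.shape[0], -1), tr, subject_id
    )


def write_statmap(path, smap: StatMap) -> None:
    img = nib.Nifti1Image(
        smap.values.reshape(smap.grid.dims).astype(np.float32), smap.grid.affine
    )
    img.header["intent_code"] = {"t": 3, "z": 5, "r": 4}[smap.stat_kind]
    img.header["intent_p1"] = smap.df
    nib.save(img, str(path))


def read_statmap(path) -> StatMap:
    img = _load_nifti(path)
    if img.ndim != 3:
        raise FormatError(f"{path} is not a 3-D statistic image")
    kind = {3: "t", 5: "z", 4: "r"}.get(int(img.header["intent_code"]), "z")
    df = float(img.header["intent_p1"]) if kind == "t" else 0.0
    return StatMap(_grid_from_img(img), img.get_fdata().ravel(), kind, df)


def write_mask(path, mask: Mask) -> None:
    img = nib.Nifti1Image(
        mask.indicator.reshape(mask.grid.dims).astype(np.uint8), mask.grid.affine
    )
    nib.save(img, str(path))


def read_mask(path, name: str = "") -> Mask:
    img = _load_nifti(path)
    if img.ndim != 3:
        raise FormatError(f"{path} is not a 3-D mask image")
    return Mask(_grid_from_img(img), img.get_fdata().ravel() > 0.5,
                name or Path(str(path)).stem)


def roundtrip_volume(path, volume):
    """Write ``volume`` to ``path`` and read it back (storage-precision check)."""
    if isinstance(volume, BoldRun):
        write_bold(path, volume)
        return read_bold(path, volume.subject_id)
    if isinstance(volume, StatMap):
        write_statmap(path, volume)
        return read_statmap(path)
    if isinstance(volume, Mask):
        write_mask(path, volume)
        return read_mask(path, volume.name)
    raise ParameterError(f"unsupported volume type {type(volume).__name__}")


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def write_motion_tsv(path, params: np.ndarray) -> None:
    params = np.asarray(params, dtype=float)
    if params.ndim != 2 or params.shape[1] != 6:
        raise ParameterError("motion parameters must be (T, 6)")
    pd.DataFrame(params, columns=list(MOTION_COLUMNS)).to_csv(
        str(path), sep="\t", index=False
    )


def read_motion_tsv(path, degrees: bool = False) -> np.ndarray:
    """Read a 6-column motion table; ``degrees=True`` converts rotations."""
    df = pd.read_csv(str(path), sep="\t")
    missing = [c for c in MOTION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"motion table {path} lacks columns {missing}")
    params = df[list(MOTION_COLUMNS)].to_numpy(dtype=float)
    if degrees:
        params[:, 3:] = np.deg2rad(params[:, 3:])
    return params


def subjects_to_frame(subjects: list[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "age": s.age,
                "sex": s.sex,
                "education": s.education,
                "ehi": s.ehi,
                "mean_fd": s.mean_fd,
            }
            for s in subjects
        ]
    )
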