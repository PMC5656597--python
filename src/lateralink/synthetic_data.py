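"""Synthetic fMRI cohorts with known activation asymmetry and connectivity.

The generator emulates the study design this package analyses: two handedness
groups (left-handers LH, right-handers RH, 28 each), a 6-min resting run and
a 4-min semantic-language task run per subject (TR 3 s, eight alternating
30-s blocks), six-parameter motion traces, and subject covariates.

Everything is planted with a closed-form ground truth:

* task activation: each mirrored left/right region pair responds at a common
  per-voxel block amplitude (% of baseline), while the *recruited extents*
  ``m_L, m_R`` split the pair's voxels in ratio ``(1 + LI) : (1 - LI)``, so
  the true laterality index is ``LI = (m_L - m_R) / (m_L + m_R)``.
  Hemispheric dominance is expressed as extent of recruited tissue at matched
  response strength -- the quantity voxel-count laterality indices measure;
  per-subject LI jitter is drawn around the group value;
* resting connectivity: a latent signal shared between a seed region and a
  target region produces a chosen seed-target correlation ``r`` (the target
  mixing weight ``w`` solves ``r = w / sqrt(w^2 + 1)`` for unit-variance
  components);
* the subject-level deviations of (cerebral LI, seed-target Fisher z) are
  drawn from a bivariate normal with correlation ``li_conn_rho``, planting
  the laterality-connectivity association the downstream pipeline must
  recover;
* noise is temporally AR(1), spatially independent; motion is a per-parameter
  random walk.

Geometry is a desk-scale head phantom: a superellipsoidal "brain" split at
the midsagittal plane, an inferior "cerebellar" slab, and geometric
white-matter / ventricle stand-in masks for nuisance regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_io import (
    BoldRun,
    Mask,
    ParameterError,
    SubjectRecord,
    VolumeGrid,
    make_hemisphere_masks,
    sphere_roi_mask,
)
from .task_activation import build_block_design

__all__ = [
    "RegionSpec",
    "PhantomGeometry",
    "CohortSpec",
    "GroundTruth",
    "CohortData",
    "make_phantom",
    "simulate_motion_trace",
    "simulate_resting_run",
    "simulate_task_run",
    "simulate_cohort",
]

GROUPS = ("LH", "RH")


@dataclass(frozen=True)
class RegionSpec:
    label: str
    center_mm: tuple[float, float, float]
    radius_mm: float = 6.0


@dataclass
class PhantomGeometry:
    """Masks shared by every simulated subject."""

    grid: VolumeGrid
    brain: Mask
    left: Mask
    right: Mask
    cerebral: Mask
    cerebellar: Mask
    wm: Mask
    vent: Mask
    regions: dict[str, Mask]

    def compartment_hemis(self, compartment: str) -> tuple[Mask, Mask]:
        comp = {"cerebral": self.cerebral, "cerebellar": self.cerebellar}[compartment]
        return (
            Mask(self.grid, comp.indicator & self.left.indicator, f"{compartment}_L"),
            Mask(self.grid, comp.indicator & self.right.indicator, f"{compartment}_R"),
        )


def _default_regions(grid: VolumeGrid, radius_mm: float = 6.0) -> list[RegionSpec]:
    """Mirrored frontal and cerebellar region pairs, placed as fractions of
    the brain semi-axes so the same recipe works at any grid size."""
    half = (np.asarray(grid.dims, float) - 1) / 2.0 * grid.voxel_size * 0.95
    rx, ry, rz = half
    return [
        RegionSpec("frontal_l", (-0.55 * rx, 0.45 * ry, 0.45 * rz), radius_mm),
        RegionSpec("frontal_r", (0.55 * rx, 0.45 * ry, 0.45 * rz), radius_mm),
        RegionSpec("cerebellar_l", (-0.45 * rx, -0.45 * ry, -0.75 * rz), radius_mm),
        RegionSpec("cerebellar_r", (0.45 * rx, -0.45 * ry, -0.75 * rz), radius_mm),
    ]


def make_phantom(
    dims: tuple[int, int, int] = (20, 24, 20),
    voxel_mm: float = 3.0,
    regions: list[RegionSpec] | None = None,
) -> PhantomGeometry:
    """Desk-scale head phantom with brain/hemisphere/compartment/nuisance masks.

    The "brain" is a superellipsoid (4th-power ball) filling most of the grid;
    the cerebellar compartment is the slab below z = -0.4 of the inferior
    semi-axis.  With even grid dims no voxel centre sits on x = 0, so the
    hemisphere masks partition the brain exactly.
    """
    grid = VolumeGrid.isotropic(dims, voxel_mm, centered=True)
    coords = grid.voxel_coords_world()
    half = (np.asarray(dims, float) - 1) / 2.0 * voxel_mm * 0.95
    frac = coords / half
    brain_ind = np.sum(frac**4, axis=1) <= 1.0
    brain = Mask(grid, brain_ind, "brain")
    left, right = make_hemisphere_masks(grid, brain)
    z_cut = -0.4 * half[2]
    cerebellar = Mask(grid, brain_ind & (coords[:, 2] < z_cut), "cerebellar")
    cerebral = Mask(grid, brain_ind & (coords[:, 2] >= z_cut), "cerebral")
    wm_c = np.array([0.0, 0.25 * half[1], 0.25 * half[2]])
    wm_frac = (coords - wm_c) / (0.28 * half)
    wm = Mask(grid, brain_ind & (np.sum(wm_frac**2, axis=1) <= 1.0), "wm")
    vent_c = np.array([0.0, -0.2 * half[1], 0.1 * half[2]])
    vent_frac = (coords - vent_c) / (0.15 * half)
    vent = Mask(grid, brain_ind & (np.sum(vent_frac**2, axis=1) <= 1.0), "vent")
    if regions is None:
        regions = _default_regions(grid)
    region_masks = {}
    for r in regions:
        m = sphere_roi_mask(grid, r.center_mm, r.radius_mm, r.label)
        m = Mask(grid, m.indicator & brain_ind, r.label)
        if m.n_voxels == 0:
            raise ParameterError(f"region {r.label!r} has no in-brain voxels")
        region_masks[r.label] = m
    return PhantomGeometry(
        grid, brain, left, right, cerebral, cerebellar, wm, vent, region_masks
    )


@dataclass
class CohortSpec:
    """Study conditions for a simulated cohort.

    Defaults reproduce the emulated design at desk scale: 28 subjects per
    group, TR 3 s, 120 resting volumes (6 min), 80 task volumes (4 min, four
    30-s semantic / control block pairs), 1 percent-range block amplitudes,
    AR(1) noise, and random-walk head motion small enough that every subject
    passes the +/-1 mm / 0.5 mm FD screening, as in the emulated cohort.
    """

    n_per_group: int = 28
    dims: tuple[int, int, int] = (20, 24, 20)
    voxel_mm: float = 3.0
    tr: float = 3.0
    rest_volumes: int = 120
    task_volumes: int = 80
    n_block_pairs: int = 4
    block_len_s: float = 30.0
    baseline: float = 100.0
    noise_sd: float = 1.0  # BOLD units (= % of the 100-unit baseline)
    noise_ar1: float = 0.3
    seed_purity: float = 0.9  # latent weight within the seed region
    motion_step_sd: tuple[float, ...] = (0.01,) * 3 + (3e-4,) * 3
    regions: list[RegionSpec] | None = None
    # group-level planted connectivity: group -> {(seed, target): r}
    planted_connectivity: dict = field(
        default_factory=lambda: {
            "LH": {("frontal_r", "cerebellar_l"): 0.55},
            "RH": {("frontal_r", "cerebellar_l"): 0.30},
        }
    )
    # group-level planted block amplitudes (% of baseline) per region; the
    # two regions of a mirrored pair respond with the mean of their values
    planted_activation: dict = field(
        default_factory=lambda: {
            "LH": {
                "frontal_l": 2.0, "frontal_r": 2.0,
                "cerebellar_l": 2.0, "cerebellar_r": 2.0,
            },
            "RH": {
                "frontal_l": 2.0, "frontal_r": 2.0,
                "cerebellar_l": 2.0, "cerebellar_r": 2.0,
            },
        }
    )
    # group-level true laterality per compartment: fixes the left/right split
    # of the *activated extent* within the mirrored region pair
    planted_li: dict = field(
        default_factory=lambda: {
            "LH": {"cerebral": 0.0, "cerebellar": 0.0},
            "RH": {"cerebral": 0.5, "cerebellar": -0.4},
        }
    )
    amp_jitter_sd: float = 0.1  # lognormal SD of per-subject amplitude scale
    li_sd: float = 0.10  # between-subject SD of the true LI
    conn_z_sd: float = 0.20  # between-subject SD of the true Fisher z
    li_conn_rho: float = -0.6  # planted corr(true cerebral LI, true z)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ParameterError("need at least 2 subjects per group")
        if self.rest_volumes < 2 or self.task_volumes < 2:
            raise ParameterError("runs need at least 2 volumes")
        if not 0 <= self.noise_ar1 < 1:
            raise ParameterError("AR(1) coefficient must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ParameterError("noise SD must be positive")
        for group, pairs in self.planted_connectivity.items():
            for pair, r in pairs.items():
                if not abs(r) < 1:
                    raise ParameterError(f"|r| must be < 1 for {group}:{pair}")
        for group, amps in self.planted_activation.items():
            if any(a < 0 for a in amps.values()):
                raise ParameterError("activation amplitudes must be nonnegative")
        expected = 2 * self.n_block_pairs * self.block_len_s / self.tr
        if abs(self.task_volumes - expected) > 1e-9:
            raise ParameterError(
                f"task_volumes must equal 2*n_block_pairs*block_len_s/tr = {expected}"
            )

    def make_geometry(self) -> PhantomGeometry:
        return make_phantom(self.dims, self.voxel_mm, self.regions)

    def scaled(self, **overrides) -> "CohortSpec":
        """A copy with overrides (e.g. a smaller grid for quick studies)."""
        return replace(self, **overrides)


@dataclass
class SubjectTruth:
    subject_id: str
    group: str
    cerebral_li: float  # realized from the rounded activated extents
    cerebellar_li: float
    amplitudes: dict[str, float]  # region -> % amplitude (per activated voxel)
    extents: dict[str, int]  # region -> number of activated voxels
    pair_r: dict[tuple[str, str], float]  # (seed, target) -> correlation


@dataclass
class GroundTruth:
    """Planted per-subject quantities, reproducible from (spec, rng_seed)."""

    subjects: list[SubjectTruth]

    def frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            row = {
                "subject_id": s.subject_id,
                "group": s.group,
                "cerebral_li": s.cerebral_li,
                "cerebellar_li": s.cerebellar_li,
            }
            for region, a in s.amplitudes.items():
                row[f"amp_{region}"] = a
            for region, m in s.extents.items():
                row[f"extent_{region}"] = m
            for (seed, target), r in s.pair_r.items():
                row[f"r_{seed}__{target}"] = r
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class CohortData:
    spec: CohortSpec
    geometry: PhantomGeometry
    subjects: list[SubjectRecord]
    rest_runs: dict[str, BoldRun]
    task_runs: dict[str, BoldRun]
    motion: dict[str, np.ndarray]
    truth: GroundTruth


# ---------------------------------------------------------------------------
# primitive simulators
# ---------------------------------------------------------------------------

def simulate_motion_trace(
    T: int, step_sd, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Cumulative random-walk rigid-body parameters (T x 6), starting at 0."""
    if T < 2:
        raise ParameterError("need T >= 2")
    step_sd = np.broadcast_to(np.asarray(step_sd, dtype=float), (6,))
    if np.any(step_sd < 0):
        raise ParameterError("step SDs must be nonnegative")
    rng = np.random.default_rng(rng)
    steps = rng.standard_normal((T - 1, 6)) * step_sd
    return np.vstack([np.zeros(6), np.cumsum(steps, axis=0)])


def _ar1(rng: np.random.Generator, phi: float, shape: tuple[int, ...]) -> np.ndarray:
    """AR(1) series along axis 0 with unit marginal variance."""
    out = np.empty(shape)
    out[0] = rng.standard_normal(shape[1:])
    if shape[0] > 1:
        innov = rng.standard_normal((shape[0] - 1,) + shape[1:]) * np.sqrt(
            1.0 - phi**2
        )
        for t in range(1, shape[0]):
            out[t] = phi * out[t - 1] + innov[t - 1]
    return out


def _connectivity_signal(
    spec: CohortSpec,
    truth: SubjectTruth,
    geometry: PhantomGeometry,
    T: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-variance (T, V) resting signal with the planted correlations.

    Each seed region carries one latent series (shared across its targets);
    seed voxels are mostly-latent (weight ``seed_purity``), target voxels mix
    the latent with weight w such that corr(latent, voxel) equals the planted
    r.  A region may serve as target of at most one seed.
    """
    V = geometry.grid.n_voxels
    signal = _ar1(rng, spec.noise_ar1, (T, V))
    seeds = {pair[0] for pair in truth.pair_r}
    targets = [pair[1] for pair in truth.pair_r]
    if len(targets) != len(set(targets)):
        raise ParameterError("a region may be the target of only one seed")
    latents = {s: _ar1(rng, spec.noise_ar1, (T,)) for s in sorted(seeds)}
    for label in seeds:
        ind = geometry.regions[label].indicator
        p = spec.seed_purity
        signal[:, ind] = (
            p * latents[label][:, None] + np.sqrt(1 - p**2) * signal[:, ind]
        )
    for (seed, target), r in truth.pair_r.items():
        w = r / np.sqrt(1.0 - r**2)
        ind = geometry.regions[target].indicator
        mixed = w * latents[seed][:, None] + signal[:, ind]
        signal[:, ind] = mixed / np.sqrt(1.0 + w**2)
    return signal


def simulate_resting_run(
    spec: CohortSpec,
    truth: SubjectTruth,
    geometry: PhantomGeometry,
    rng: np.random.Generator | int | None = None,
) -> BoldRun:
    """Resting-state run: baseline + planted-connectivity signal + AR(1) noise."""
    rng = np.random.default_rng(rng)
    signal = _connectivity_signal(spec, truth, geometry, spec.rest_volumes, rng)
    data = spec.baseline + spec.noise_sd * signal
    return BoldRun(geometry.grid, data.astype(np.float32), spec.tr, truth.subject_id)


def simulate_task_run(
    spec: CohortSpec,
    truth: SubjectTruth,
    geometry: PhantomGeometry,
    rng: np.random.Generator | int | None = None,
) -> BoldRun:
    """Task run: baseline + HRF-convolved semantic blocks in the planted
    regions (amplitude in % of baseline) + AR(1) noise."""
    rng = np.random.default_rng(rng)
    design = build_block_design(spec.tr, spec.n_block_pairs, spec.block_len_s)
    if design.n_rows != spec.task_volumes:
        raise ParameterError("task_volumes inconsistent with block design")
    sem = design.column("semantic")
    data = spec.baseline + spec.noise_sd * _ar1(
        rng, spec.noise_ar1, (spec.task_volumes, geometry.grid.n_voxels)
    )
    coords = geometry.grid.voxel_coords_world()
    for label, amp_pct in truth.amplitudes.items():
        idx = _activated_voxels(
            geometry.regions[label], coords, truth.extents.get(label)
        )
        if idx.size:
            data[:, idx] += (amp_pct / 100.0 * spec.baseline) * sem[:, None]
    return BoldRun(geometry.grid, data.astype(np.float32), spec.tr, truth.subject_id)


def _activated_voxels(
    region: Mask, coords: np.ndarray, extent: int | None
) -> np.ndarray:
    """Flat indices of the ``extent`` region voxels nearest its centroid.

    The recruited patch grows deterministically from the region centre, so a
    larger planted extent always contains a smaller one.
    """
    idx = np.flatnonzero(region.indicator)
    if extent is None or extent >= idx.size:
        return idx
    if extent <= 0:
        return idx[:0]
    center = coords[idx].mean(axis=0)
    d2 = np.sum((coords[idx] - center) ** 2, axis=1)
    order = np.lexsort((idx, d2))  # index tie-break keeps this deterministic
    return idx[order[:extent]]


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

COMPARTMENT_PAIRS = {
    "cerebral": ("frontal_l", "frontal_r"),
    "cerebellar": ("cerebellar_l", "cerebellar_r"),
}


def _split_extent(n_left: int, n_right: int, li: float) -> tuple[int, int, float]:
    """Activated voxel counts for a mirrored pair at laterality ``li``.

    The left region activates a fraction (1 + li)/2 of its voxels and the
    right (1 - li)/2, so the activated-extent ratio is (1+li):(1-li); the
    realized LI (returned last) accounts for integer rounding.
    """
    m_left = int(round(n_left * (1.0 + li) / 2.0))
    m_right = int(round(n_right * (1.0 - li) / 2.0))
    total = m_left + m_right
    realized = 0.0 if total == 0 else (m_left - m_right) / total
    return m_left, m_right, realized


def _draw_subject_truth(
    spec: CohortSpec,
    geometry: PhantomGeometry,
    group: str,
    subject_id: str,
    rng: np.random.Generator,
) -> SubjectTruth:
    base_amps = spec.planted_activation[group]
    # bivariate jitter linking cerebral LI and the primary pair's Fisher z
    rho = spec.li_conn_rho
    cov = np.array([[1.0, rho], [rho, 1.0]])
    xi = rng.multivariate_normal([0.0, 0.0], cov)
    amp_scale = float(np.exp(rng.normal(0.0, spec.amp_jitter_sd)))
    amps: dict[str, float] = {}
    extents: dict[str, int] = {}
    realized_li = {"cerebral": float("nan"), "cerebellar": float("nan")}
    for compartment, (left, right) in COMPARTMENT_PAIRS.items():
        if left not in base_amps or right not in base_amps:
            continue
        li_group = spec.planted_li[group][compartment]
        dz = xi[0] if compartment == "cerebral" else rng.standard_normal()
        li_subj = float(np.clip(li_group + spec.li_sd * dz, -0.95, 0.95))
        m_l, m_r, realized = _split_extent(
            geometry.regions[left].n_voxels,
            geometry.regions[right].n_voxels,
            li_subj,
        )
        extents[left], extents[right] = m_l, m_r
        # both sides respond at the pair-mean amplitude: laterality lives in
        # the recruited extent, which is what voxel-count indices measure
        pair_amp = amp_scale * (base_amps[left] + base_amps[right]) / 2.0
        amps[left] = amps[right] = pair_amp
        realized_li[compartment] = realized
    pair_r = {}
    for i, (pair, r_group) in enumerate(spec.planted_connectivity[group].items()):
        dz = xi[1] if i == 0 else rng.standard_normal()
        z = np.arctanh(r_group) + spec.conn_z_sd * dz
        pair_r[pair] = float(np.tanh(z))
    return SubjectTruth(
        subject_id,
        group,
        realized_li["cerebral"],
        realized_li["cerebellar"],
        amps,
        extents,
        pair_r,
    )


def _draw_covariates(
    group: str, subject_id: str, rng: np.random.Generator
) -> SubjectRecord:
    if group == "LH":
        age = rng.normal(24.2, 2.5)
        sex = "F" if rng.random() < 17 / 28 else "M"
        ehi = float(np.clip(rng.normal(-66.4, 13.4), -100.0, -50.0))
    else:
        age = rng.normal(24.7, 1.9)
        sex = "F" if rng.random() < 15 / 28 else "M"
        ehi = float(np.clip(rng.normal(96.8, 7.2), 50.0, 100.0))
    education = float(np.clip(rng.normal(16.0, 2.0), 9.0, 22.0))
    return SubjectRecord(subject_id, group, float(age), sex, education, ehi)


def simulate_cohort(
    spec: CohortSpec, include_rest: bool = True, include_task: bool = True
) -> CohortData:
    """Simulate the full two-group cohort; reproducible from ``spec.rng_seed``.

    Each subject and each data component (truth, covariates, rest run, task
    run, motion) gets its own spawned random stream, so skipping a component
    (e.g. ``include_task=False`` for resting-only null studies) leaves the
    others bit-identical.
    """
    geometry = spec.make_geometry()
    ss = np.random.SeedSequence(spec.rng_seed)
    subjects: list[SubjectRecord] = []
    truths: list[SubjectTruth] = []
    rest_runs: dict[str, BoldRun] = {}
    task_runs: dict[str, BoldRun] = {}
    motion: dict[str, np.ndarray] = {}
    subject_streams = ss.spawn(2 * spec.n_per_group)
    sid = 0
    for gi, group in enumerate(GROUPS):
        for _ in range(spec.n_per_group):
            sid += 1
            subject_id = f"sub-{sid:02d}"
            streams = subject_streams[sid - 1].spawn(5)
            rngs = [np.random.default_rng(s) for s in streams]
            truth = _draw_subject_truth(spec, geometry, group, subject_id, rngs[0])
            subjects.append(_draw_covariates(group, subject_id, rngs[1]))
            if include_rest:
                rest_runs[subject_id] = simulate_resting_run(
                    spec, truth, geometry, rngs[2]
                )
            if include_task:
                task_runs[subject_id] = simulate_task_run(
                    spec, truth, geometry, rngs[3]
                )
            motion[subject_id] = simulate_motion_trace(
                spec.rest_volumes, spec.motion_step_sd, rngs[4]
            )
            truths.append(truth)
    return CohortData(
        spec, geometry, subjects, rest_runs, task_runs, motion, GroundTruth(truths)
    )
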