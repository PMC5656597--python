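"""End-to-end cohort analysis: QC, task GLM, LI, RSFC, group inference,
laterality-connectivity association.

This is a thin orchestration layer over the analysis modules, mirroring the
study flow: motion screening -> per-subject task contrast maps -> threshold-
free laterality indices -> peak-seed resting-state z-maps -> covaried group
comparison with Monte-Carlo cluster correction -> per-group correlation of
cluster connectivity with cerebral LI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import pearson_correlation, roi_mean_z, shepherd_pi
from .connectivity import extract_seed_timeseries, rsfc_zmap
from .core_io import Mask, ParameterError, StatMap, subjects_to_frame
from .group_inference import (
    ClusterNull,
    ClusterRecord,
    cluster_table,
    estimate_smoothness,
    extract_clusters,
    montecarlo_cluster_threshold,
    voxelwise_group_glm,
)
from .laterality import LateralityResult, laterality_index
from .preprocess import gaussian_smooth, motion_qc, preprocess_rest
from .synthetic_data import CohortData
from .task_activation import (
    build_block_design,
    encode_covariates,
    fit_glm_contrast,
    group_difference_map,
    pick_peak_seeds,
)
from scipy import stats

__all__ = ["CohortAnalysis", "analyze_cohort", "qc_table"]

TASK_COVARIATES = ["age", "sex", "education", "mean_fd", "ehi"]
RSFC_COVARIATES = ["age", "sex", "mean_fd"]


@dataclass
class CohortAnalysis:
    qc: pd.DataFrame
    subjects: pd.DataFrame
    task_tmaps: dict[str, StatMap]
    laterality: pd.DataFrame
    seed_table: pd.DataFrame
    zmaps: dict[str, StatMap]
    group_tmap: StatMap
    smoothness_mm: tuple[float, float, float]
    cluster_null: ClusterNull
    clusters: list[ClusterRecord]
    cluster_records: pd.DataFrame
    associations: pd.DataFrame
    li_results: dict[str, dict[str, LateralityResult]] = field(default_factory=dict)


def qc_table(cohort: CohortData) -> pd.DataFrame:
    """Motion QC per subject; fills ``mean_fd`` on the subject records."""
    rows = []
    for rec in cohort.subjects:
        dec = motion_qc(cohort.motion[rec.subject_id])
        rec.mean_fd = dec.mean_fd_mm
        rows.append(
            {
                "subject_id": rec.subject_id,
                "included": dec.included,
                "reason": dec.reason,
                "max_translation_mm": dec.max_translation_mm,
                "max_rotation_deg": dec.max_rotation_deg,
                "max_fd_mm": dec.max_fd_mm,
                "mean_fd_mm": dec.mean_fd_mm,
            }
        )
    return pd.DataFrame(rows)


def _group_indicator(subjects: pd.DataFrame) -> np.ndarray:
    # 1 = LH so positive group t means stronger in left-handers, as reported
    return (subjects["group"] == "LH").to_numpy().astype(int)


def analyze_cohort(
    cohort: CohortData,
    seed_region: str = "frontal_r",
    zmap_fwhm_mm: float = 8.0,
    seed_radius_mm: float = 6.0,
    voxel_p: float = 0.01,
    alpha: float = 0.01,
    cluster_iters: int = 10_000,
    task_fdr_q: float = 0.01,
    rng: np.random.Generator | int | None = None,
) -> CohortAnalysis:
    """Run the full analysis chain on a (synthetic or loaded) cohort."""
    geom = cohort.geometry
    spec = cohort.spec
    qc = qc_table(cohort)
    keep = set(qc.loc[qc["included"], "subject_id"])
    if len(keep) < 6:
        raise ParameterError("too few subjects pass motion QC")
    subjects = subjects_to_frame(
        [s for s in cohort.subjects if s.subject_id in keep]
    )
    sids = subjects["subject_id"].tolist()

    # --- task GLM and laterality -------------------------------------------
    design = build_block_design(spec.tr, spec.n_block_pairs, spec.block_len_s)
    tmaps = {sid: fit_glm_contrast(cohort.task_runs[sid], design) for sid in sids}
    li_rows, li_results = [], {}
    for sid in sids:
        li_results[sid] = {}
        row = {"subject_id": sid}
        for compartment in ("cerebral", "cerebellar"):
            lmask, rmask = geom.compartment_hemis(compartment)
            res = laterality_index(tmaps[sid], lmask, rmask, compartment=compartment)
            li_results[sid][compartment] = res
            row[f"{compartment}_li"] = res.li
            row[f"{compartment}_category"] = res.category
        li_rows.append(row)
    laterality = pd.DataFrame(li_rows)

    # --- seed selection on the group task-difference map -------------------
    groups = _group_indicator(subjects)
    covars = encode_covariates(subjects, TASK_COVARIATES)
    task_diff_tmap, _ = group_difference_map(
        [tmaps[s] for s in sids], groups, covars, mask=geom.brain, q=task_fdr_q
    )
    seed_table = pick_peak_seeds(task_diff_tmap, {seed_region: geom.regions[seed_region]})
    from .core_io import sphere_roi_mask

    peak = seed_table.iloc[0]
    seed_mask = sphere_roi_mask(
        geom.grid, (peak["x"], peak["y"], peak["z"]), seed_radius_mm, seed_region
    )

    # --- resting-state connectivity ----------------------------------------
    zmaps = {}
    for sid in sids:
        clean = preprocess_rest(
            cohort.rest_runs[sid], cohort.motion[sid], geom.wm, geom.vent
        )
        series = extract_seed_timeseries(clean, seed_mask)
        cmap = rsfc_zmap(clean, series, seed_region)
        zmaps[sid] = gaussian_smooth(cmap.zmap, zmap_fwhm_mm)

    # --- group inference with Monte-Carlo cluster correction ---------------
    rsfc_covars = encode_covariates(subjects, RSFC_COVARIATES)
    group_tmap, residuals = voxelwise_group_glm(
        [zmaps[s] for s in sids], groups, rsfc_covars
    )
    fwhm_est = estimate_smoothness(residuals, geom.brain)
    null = montecarlo_cluster_threshold(
        geom.brain, fwhm_est, voxel_p=voxel_p, alpha=alpha, iters=cluster_iters,
        rng=rng,
    )
    t_crit = float(stats.t.isf(voxel_p / 2.0, group_tmap.df))
    # the seed's own neighbourhood trivially correlates with itself in both
    # groups; exclude it from the difference search
    search = Mask(
        geom.grid, geom.brain.indicator & ~seed_mask.indicator, "search"
    )
    clusters = extract_clusters(
        group_tmap, t_crit, null.threshold_k, mask=search, two_sided=True
    )

    # --- association with cerebral LI --------------------------------------
    li_map = laterality.set_index("subject_id")["cerebral_li"]
    assoc_rows = []
    for ci, rec in enumerate(clusters):
        region = Mask(geom.grid, np.isin(
            np.arange(geom.grid.n_voxels), rec.voxel_indices), f"cluster{ci}")
        zvals = {sid: roi_mean_z(zmaps[sid], region) for sid in sids}
        for group_name in ("LH", "RH"):
            gsids = subjects.loc[subjects["group"] == group_name, "subject_id"]
            x = np.array([zvals[s] for s in gsids])
            y = li_map.loc[gsids].to_numpy()
            for result in (
                pearson_correlation(x, y),
                shepherd_pi(x, y, rng=rng),
            ):
                assoc_rows.append(
                    {
                        "cluster": ci,
                        "peak_x": rec.peak_mm[0],
                        "peak_y": rec.peak_mm[1],
                        "peak_z": rec.peak_mm[2],
                        "group": group_name,
                        "method": result.method,
                        "estimate": result.estimate,
                        "p_value": result.p_value,
                        "n_used": result.n_used,
                        "n_outliers": len(result.outlier_indices),
                    }
                )
    associations = pd.DataFrame(
        assoc_rows,
        columns=[
            "cluster", "peak_x", "peak_y", "peak_z", "group", "method",
            "estimate", "p_value", "n_used", "n_outliers",
        ],
    )
    return CohortAnalysis(
        qc=qc,
        subjects=subjects,
        task_tmaps=tmaps,
        laterality=laterality,
        seed_table=seed_table,
        zmaps=zmaps,
        group_tmap=group_tmap,
        smoothness_mm=fwhm_est,
        cluster_null=null,
        clusters=clusters,
        cluster_records=cluster_table(clusters),
        associations=associations,
        li_results=li_results,
    )
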