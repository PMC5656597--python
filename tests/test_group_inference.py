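from collections import deque

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lateralink.core_io import Mask, ParameterError, StatMap, VolumeGrid
from lateralink.group_inference import (
    cluster_table,
    degree_summary,
    estimate_smoothness,
    extract_clusters,
    montecarlo_cluster_threshold,
    voxelwise_group_glm,
)
from lateralink.preprocess import gaussian_smooth


def flood_fill_clusters(suprathreshold3, connectivity):
    """Brute-force BFS connected components (oracle for extract_clusters)."""
    offsets = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if (di, dj, dk) == (0, 0, 0):
                    continue
                order = abs(di) + abs(dj) + abs(dk)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((di, dj, dk))
    seen = np.zeros_like(suprathreshold3, dtype=bool)
    comps = []
    dims = suprathreshold3.shape
    for idx in np.argwhere(suprathreshold3):
        if seen[tuple(idx)]:
            continue
        comp = []
        queue = deque([tuple(idx)])
        seen[tuple(idx)] = True
        while queue:
            cur = queue.popleft()
            comp.append(cur)
            for off in offsets:
                nb = tuple(np.add(cur, off))
                if all(0 <= nb[a] < dims[a] for a in range(3)):
                    if suprathreshold3[nb] and not seen[nb]:
                        seen[nb] = True
                        queue.append(nb)
        comps.append(frozenset(comp))
    return set(comps)


class TestGroupGlm:
    def test_matches_pooled_two_sample_t(self, grid, rng):
        maps = [
            StatMap(grid, rng.standard_normal(grid.n_voxels), "z") for _ in range(16)
        ]
        groups = np.array([0] * 8 + [1] * 8)
        tmap, resid = voxelwise_group_glm(maps, groups, covariates=None)
        Y = np.stack([m.values for m in maps])
        oracle, _ = stats.ttest_ind(Y[8:], Y[:8], axis=0, equal_var=True)
        assert np.max(np.abs(tmap.values - oracle)) < 1e-8
        assert len(resid) == 16

    def test_null_tail_matches_t_distribution(self, rng):
        g = VolumeGrid.isotropic((10, 10, 10), 3.0)
        maps = [StatMap(g, rng.standard_normal(g.n_voxels), "z") for _ in range(20)]
        groups = np.array([0] * 10 + [1] * 10)
        tmap, _ = voxelwise_group_glm(maps, groups)
        q99 = np.quantile(np.abs(tmap.values), 0.99)
        assert q99 == pytest.approx(stats.t.isf(0.005, tmap.df), rel=0.12)

    def test_planted_difference_peaks_in_region(self, rng):
        g = VolumeGrid.isotropic((8, 8, 8), 3.0)
        region = np.zeros(g.n_voxels, bool)
        region[200:240] = True
        hits = 0
        n_sims = 10
        for _ in range(n_sims):
            maps = []
            for i in range(56):
                vals = rng.standard_normal(g.n_voxels) * 0.2
                if i >= 28:
                    vals[region] += 0.3
                maps.append(StatMap(g, vals, "z"))
            groups = np.array([0] * 28 + [1] * 28)
            tmap, _ = voxelwise_group_glm(maps, groups)
            hits += region[np.argmax(tmap.values)]
        assert hits >= 9

    def test_too_few_subjects_rejected(self, grid, rng):
        maps = [StatMap(grid, rng.standard_normal(grid.n_voxels), "z")] * 4
        with pytest.raises(ParameterError):
            voxelwise_group_glm(maps, np.array([0, 0, 1, 1]))


class TestSmoothness:
    def test_iid_noise_below_voxel_size(self, rng):
        g = VolumeGrid.isotropic((12, 12, 12), 3.0)
        maps = [StatMap(g, rng.standard_normal(g.n_voxels), "z") for _ in range(10)]
        mask = Mask(g, np.ones(g.n_voxels, bool))
        fwhm = estimate_smoothness(maps, mask)
        assert all(f <= 3.0 for f in fwhm)

    def test_smoothed_noise_recovered(self, rng):
        g = VolumeGrid.isotropic((24, 24, 24), 2.0)
        mask = Mask(g, np.ones(g.n_voxels, bool))
        maps = []
        for _ in range(20):
            raw = StatMap(g, rng.standard_normal(g.n_voxels), "z")
            maps.append(gaussian_smooth(raw, 8.0))
        fwhm = estimate_smoothness(maps, mask)
        assert np.allclose(fwhm, 8.0, rtol=0.15)

    def test_constant_image_rejected(self, grid):
        maps = [StatMap(grid, np.zeros(grid.n_voxels), "z")]
        with pytest.raises(ParameterError):
            estimate_smoothness(maps, Mask(grid, np.ones(grid.n_voxels, bool)))


class TestMonteCarloThreshold:
    def test_isolated_voxels_match_binomial(self):
        # 10 pairwise non-adjacent voxels: P(max>=1) = 1-0.99^10 ~ 0.096 > 0.05
        # and two-voxel clusters are impossible, so threshold_k must be 2
        g = VolumeGrid.isotropic((10, 10, 10), 3.0)
        ind3 = np.zeros(g.dims, bool)
        pts = [(1, 1, 1), (1, 4, 7), (4, 1, 4), (7, 7, 1), (7, 1, 7),
               (1, 7, 4), (4, 7, 7), (7, 4, 4), (4, 4, 1), (8, 8, 8)]
        for p in pts:
            ind3[p] = True
        null = montecarlo_cluster_threshold(
            Mask(g, ind3.ravel()), fwhm_mm=0.0, voxel_p=0.01, alpha=0.05,
            iters=4000, rng=11,
        )
        assert null.threshold_k == 2
        p_any = np.mean(null.max_sizes >= 1)
        assert p_any == pytest.approx(1 - 0.99**10, abs=0.02)
        assert np.all(null.max_sizes <= 1)

    def test_alpha_one_gives_k_one(self, grid):
        null = montecarlo_cluster_threshold(
            Mask(grid, np.ones(grid.n_voxels, bool)), 0.0, 0.01, 1.0, 200, rng=0
        )
        assert null.threshold_k == 1

    def test_threshold_monotone_in_fwhm(self):
        g = VolumeGrid.isotropic((12, 12, 12), 3.0)
        mask = Mask(g, np.ones(g.n_voxels, bool))
        ks = [
            montecarlo_cluster_threshold(
                mask, fwhm, 0.01, 0.05, 1500, rng=5
            ).threshold_k
            for fwhm in (0.0, 4.0, 8.0)
        ]
        assert ks == sorted(ks)

    def test_reproducible_given_seed(self, grid):
        mask = Mask(grid, np.ones(grid.n_voxels, bool))
        a = montecarlo_cluster_threshold(mask, 3.0, 0.01, 0.05, 300, rng=42)
        b = montecarlo_cluster_threshold(mask, 3.0, 0.01, 0.05, 300, rng=42)
        assert np.array_equal(a.max_sizes, b.max_sizes)
        assert a.threshold_k == b.threshold_k


class TestExtractClusters:
    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, rng, connectivity):
        g = VolumeGrid.isotropic((7, 7, 7), 3.0)
        for _ in range(5):
            vals = rng.standard_normal(g.n_voxels)
            recs = extract_clusters(
                StatMap(g, vals, "t", 30.0), 1.0, threshold_k=1,
                connectivity=connectivity, two_sided=False,
            )
            got = {
                frozenset(
                    tuple(np.unravel_index(i, g.dims)) for i in r.voxel_indices
                )
                for r in recs
            }
            expected = flood_fill_clusters(
                (vals > 1.0).reshape(g.dims), connectivity
            )
            assert got == expected

    def test_extent_rule_67(self, rng):
        g = VolumeGrid.isotropic((12, 12, 12), 3.0)
        vals = np.zeros(g.dims)
        vals[1:6, 1:6, 1:5] = 5.0  # 100-voxel blob
        vals[8:10, 8:13, 7:12] = 5.0  # 50-voxel blob (2x5x5)
        recs = extract_clusters(StatMap(g, vals.ravel(), "t", 30.0), 2.0, 67)
        assert len(recs) == 1
        assert recs[0].extent == 100

    def test_diagonal_touching_connectivity(self):
        g = VolumeGrid.isotropic((5, 5, 5), 3.0)
        vals = np.zeros(g.dims)
        vals[1, 1, 1] = 3.0
        vals[2, 2, 2] = 3.0
        smap = StatMap(g, vals.ravel(), "t", 30.0)
        assert len(extract_clusters(smap, 1.0, 1, connectivity=26)) == 1
        assert len(extract_clusters(smap, 1.0, 1, connectivity=6)) == 2

    def test_two_sided_keeps_signs_separate(self):
        g = VolumeGrid.isotropic((6, 6, 6), 3.0)
        vals = np.zeros(g.dims)
        vals[1:3, 1, 1] = 4.0
        vals[3:5, 1, 1] = -4.0  # adjacent but opposite sign
        recs = extract_clusters(StatMap(g, vals.ravel(), "t", 30.0), 2.0, 1)
        assert len(recs) == 2
        assert sorted(r.peak_t for r in recs) == [-4.0, 4.0]


class TestDegreeSummary:
    def test_counts_distinct_regions(self):
        table = pd.DataFrame(
            {
                "label": ["ANG", "CRBcrus1", "CRBcrus2", "CRBcrus2"],
                "hem": ["R", "L", "L", "R"],
            }
        )
        assert degree_summary({"right MFG": table}) == {"right MFG": 4}

    def test_empty_table_zero(self):
        assert degree_summary({"s": pd.DataFrame(columns=["label", "hem"])}) == {
            "s": 0
        }

    def test_duplicates_collapse(self):
        table = pd.DataFrame(
            {"label": ["CAU", "CAU", "CRBcrus2"], "hem": ["L", "L", "R"]}
        )
        assert degree_summary({"s": table}) == {"s": 2}

    def test_cluster_table_columns(self, grid, rng):
        recs = extract_clusters(
            StatMap(grid, rng.standard_normal(grid.n_voxels), "t", 30.0), 2.0, 1
        )
        table = cluster_table(recs)
        assert list(table.columns) == [
            "label", "hem", "x", "y", "z", "peak_t", "extent",
        ]
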