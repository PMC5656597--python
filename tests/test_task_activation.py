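import numpy as np
import pytest
from scipy import stats

from lateralink.core_io import BoldRun, Mask, ParameterError, StatMap, VolumeGrid
from lateralink.task_activation import (
    build_block_design,
    conjunction_map,
    fit_glm_contrast,
    group_difference_map,
    one_sample_tmap,
    percent_signal_change,
    pick_peak_seeds,
)


@pytest.fixture(scope="module")
def design():
    return build_block_design(tr=3.0)


class TestBlockDesign:
    def test_row_count_matches_paradigm(self, design):
        # 8 blocks x 30 s at TR 3 s -> 80 volumes, 10 per block
        assert design.n_rows == 80

    def test_deterministic_across_calls(self, design):
        again = build_block_design(tr=3.0)
        assert np.array_equal(again.matrix, design.matrix)

    def test_full_column_rank(self, design):
        assert np.linalg.matrix_rank(design.matrix) == design.matrix.shape[1]

    def test_semantic_and_control_cover_all_time(self, design):
        # the two condition regressors sum to the response of an always-on
        # boxcar, which converges to 1 once the HRF transient has passed
        total = design.column("semantic") + design.column("control")
        assert np.allclose(total[15:], 1.0, atol=0.02)

    def test_non_integer_block_rejected(self):
        with pytest.raises(ParameterError):
            build_block_design(tr=3.5)


class TestGlmContrast:
    def test_matches_per_voxel_regression_oracle(self, design, rng):
        g = VolumeGrid.isotropic((4, 4, 4), 3.0)
        data = rng.standard_normal((80, g.n_voxels))
        tmap = fit_glm_contrast(BoldRun(g, data, 3.0), design)
        X = design.matrix
        c = design.contrast_vector("semantic", "control")
        df = 80 - X.shape[1]
        for v in range(g.n_voxels):  # brute-force voxel loop
            beta = np.linalg.solve(X.T @ X, X.T @ data[:, v])
            resid = data[:, v] - X @ beta
            sigma2 = resid @ resid / df
            se = np.sqrt(sigma2 * c @ np.linalg.inv(X.T @ X) @ c)
            assert tmap.values[v] == pytest.approx(c @ beta / se, abs=1e-8)
        assert tmap.df == df

    def test_null_false_positive_rate(self, design, rng):
        g = VolumeGrid.isotropic((10, 10, 10), 3.0)
        data = rng.standard_normal((80, g.n_voxels))
        tmap = fit_glm_contrast(BoldRun(g, data, 3.0), design)
        crit = stats.t.isf(0.005, tmap.df)
        frac = np.mean(np.abs(tmap.values) > crit)
        assert frac == pytest.approx(0.01, abs=0.01)

    def test_planted_amplitude_recovered_at_peak(self, design, rng):
        g = VolumeGrid.isotropic((6, 6, 6), 3.0)
        data = rng.standard_normal((80, g.n_voxels))
        region = np.zeros(g.n_voxels, bool)
        region[50:60] = True
        data[:, region] += 5.0 * design.column("semantic")[:, None]
        tmap = fit_glm_contrast(BoldRun(g, data, 3.0), design)
        assert region[np.argmax(tmap.values)]


class TestPercentSignalChange:
    def _run_with(self, grid, design, baseline, amplitude, rng):
        data = baseline + rng.standard_normal((80, grid.n_voxels)) * 0.5
        data += amplitude * design.column("semantic")[:, None]
        return BoldRun(grid, data, 3.0)

    def test_construction_recovers_one_percent(self, design, rng):
        g = VolumeGrid.isotropic((4, 4, 4), 3.0)
        run = self._run_with(g, design, 200.0, 2.0, rng)
        roi = Mask(g, np.ones(g.n_voxels, bool))
        assert percent_signal_change(run, design, roi) == pytest.approx(1.0, abs=0.1)

    def test_zero_amplitude_near_zero(self, design, rng):
        g = VolumeGrid.isotropic((4, 4, 4), 3.0)
        run = self._run_with(g, design, 200.0, 0.0, rng)
        roi = Mask(g, np.ones(g.n_voxels, bool))
        assert abs(percent_signal_change(run, design, roi)) < 0.1

    def test_homogeneity(self, design, rng):
        g = VolumeGrid.isotropic((4, 4, 4), 3.0)
        roi = Mask(g, np.ones(g.n_voxels, bool))
        base = 200.0
        sem = design.column("semantic")[:, None]
        run1 = BoldRun(g, base + 1.0 * sem * np.ones(g.n_voxels), 3.0)
        run2 = BoldRun(g, base + 2.0 * sem * np.ones(g.n_voxels), 3.0)
        psc1 = percent_signal_change(run1, design, roi)
        psc2 = percent_signal_change(run2, design, roi)
        assert psc2 == pytest.approx(2.0 * psc1, abs=1e-6)


def _stack_maps(grid, rng, n, shift=None):
    maps = []
    for i in range(n):
        vals = rng.standard_normal(grid.n_voxels)
        if shift is not None:
            vals = vals + shift[i]
        maps.append(StatMap(grid, vals, "t", 40.0))
    return maps


class TestGroupDifference:
    def test_no_covariates_equals_two_sample_t_oracle(self, rng):
        g = VolumeGrid.isotropic((5, 5, 5), 3.0)
        n0, n1 = 10, 12
        maps = _stack_maps(g, rng, n0 + n1)
        groups = np.array([0] * n0 + [1] * n1)
        tmap, _ = group_difference_map(maps, groups, covariates=None, q=0.05)
        Y = np.stack([m.values for m in maps])
        t_oracle, _ = stats.ttest_ind(Y[n0:], Y[:n0], axis=0, equal_var=True)
        assert np.max(np.abs(tmap.values - t_oracle)) < 1e-8
        assert tmap.df == n0 + n1 - 2

    def test_identical_groups_rarely_significant(self):
        g = VolumeGrid.isotropic((8, 8, 8), 3.0)
        rng = np.random.default_rng(99)
        any_sig = 0
        n_sims = 20
        for _ in range(n_sims):
            maps = _stack_maps(g, rng, 20)
            groups = np.array([0] * 10 + [1] * 10)
            _, sig = group_difference_map(maps, groups, q=0.01)
            any_sig += sig.n_voxels > 0
        assert any_sig <= 2  # FWER under the null is at most q = 0.01-ish

    def test_planted_difference_localized(self, rng):
        g = VolumeGrid.isotropic((8, 8, 8), 3.0)
        region = np.zeros(g.n_voxels, bool)
        region[100:140] = True
        shift = np.concatenate([np.zeros(14), np.ones(14)])
        maps = []
        for i in range(28):
            vals = rng.standard_normal(g.n_voxels) * 0.5
            if shift[i]:
                vals[region] += 1.0
            maps.append(StatMap(g, vals, "t", 40.0))
        groups = np.array([0] * 14 + [1] * 14)
        _, sig = group_difference_map(maps, groups, q=0.01)
        assert sig.n_voxels > 0
        hits_in_region = (sig.indicator & region).sum() / sig.n_voxels
        assert hits_in_region >= 0.8

    def test_collinear_covariate_warns_but_proceeds(self, rng):
        import pandas as pd

        g = VolumeGrid.isotropic((4, 4, 4), 3.0)
        maps = _stack_maps(g, rng, 12)
        groups = np.array([0] * 6 + [1] * 6)
        ehi = groups * 150.0 - 70.0 + rng.standard_normal(12)
        cov = pd.DataFrame({"ehi": ehi})
        with pytest.warns(UserWarning, match="collinear"):
            tmap, _ = group_difference_map(maps, groups, cov, q=0.05)
        assert np.all(np.isfinite(tmap.values))


class TestConjunction:
    def test_identical_maps_equal_suprathreshold(self, grid, rng):
        vals = rng.standard_normal(grid.n_voxels)
        smap = StatMap(grid, vals, "t", 30.0)
        conj = conjunction_map(smap, smap, 1.0)
        assert np.array_equal(conj.indicator, vals > 1.0)

    def test_disjoint_activations_empty(self, grid):
        a = np.zeros(grid.n_voxels)
        b = np.zeros(grid.n_voxels)
        a[:5] = 5.0
        b[-5:] = 5.0
        conj = conjunction_map(
            StatMap(grid, a, "t", 30.0), StatMap(grid, b, "t", 30.0), 2.0
        )
        assert conj.n_voxels == 0

    def test_matches_voxel_loop_oracle(self, grid, rng):
        a = StatMap(grid, rng.standard_normal(grid.n_voxels), "t", 30.0)
        b = StatMap(grid, rng.standard_normal(grid.n_voxels), "t", 30.0)
        conj = conjunction_map(a, b, 0.5)
        for v in range(grid.n_voxels):
            assert conj.indicator[v] == (min(a.values[v], b.values[v]) > 0.5)

    def test_monotone_in_threshold(self, grid, rng):
        a = StatMap(grid, rng.standard_normal(grid.n_voxels), "t", 30.0)
        b = StatMap(grid, rng.standard_normal(grid.n_voxels), "t", 30.0)
        prev = conjunction_map(a, b, 0.0)
        for thr in (0.5, 1.0, 2.0):
            cur = conjunction_map(a, b, thr)
            assert not np.any(cur.indicator & ~prev.indicator)
            prev = cur


class TestPeakSeeds:
    def test_single_voxel_region(self, grid, rng):
        vals = rng.standard_normal(grid.n_voxels)
        ind = np.zeros(grid.n_voxels, bool)
        ind[37] = True
        table = pick_peak_seeds(
            StatMap(grid, vals, "t", 30.0), {"only": Mask(grid, ind)}
        )
        coords = grid.voxel_coords_world()[37]
        assert table.iloc[0][["x", "y", "z"]].to_numpy() == pytest.approx(coords)

    def test_planted_peak_reported_in_world_mm(self):
        # a grid whose voxel centres include the MNI-style point (-51, 18, 36)
        aff = np.eye(4) * 3.0
        aff[3, 3] = 1.0
        aff[:3, 3] = [-60.0, 9.0, 27.0]
        g = VolumeGrid((8, 8, 8), aff)
        coords = g.voxel_coords_world()
        target = np.flatnonzero(
            (coords == np.array([-51.0, 18.0, 36.0])).all(axis=1)
        )[0]
        vals = np.zeros(g.n_voxels)
        vals[target] = 8.10
        table = pick_peak_seeds(
            StatMap(g, vals, "t", 30.0),
            {"MFG": Mask(g, np.ones(g.n_voxels, bool))},
        )
        row = table.iloc[0]
        assert (row["x"], row["y"], row["z"]) == (-51.0, 18.0, 36.0)
        assert row["peak_t"] == pytest.approx(8.10)
        assert row["hem"] == "L"

    def test_tie_breaks_to_smallest_index(self, grid):
        vals = np.zeros(grid.n_voxels)
        vals[[10, 20]] = 3.0
        ind = np.zeros(grid.n_voxels, bool)
        ind[[10, 20]] = True
        table = pick_peak_seeds(
            StatMap(grid, vals, "t", 30.0), {"r": Mask(grid, ind)}
        )
        assert table.iloc[0][["x", "y", "z"]].to_numpy() == pytest.approx(
            grid.voxel_coords_world()[10]
        )


class TestOneSample:
    def test_matches_scipy(self, grid, rng):
        maps = _stack_maps(grid, rng, 9)
        tmap = one_sample_tmap(maps)
        Y = np.stack([m.values for m in maps])
        t_oracle, _ = stats.ttest_1samp(Y, 0.0, axis=0)
        assert np.max(np.abs(tmap.values - t_oracle)) < 1e-8
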