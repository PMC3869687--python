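import numpy as np
import pytest
from scipy import stats

from _oracles import flood_fill_labels

from ctvbm.ct_preprocess import BrainMask
from ctvbm.errors import DegenerateInputError
from ctvbm.head_phantom import PhantomSpec, generate_density_cohort
from ctvbm.vbm_stats import (Cluster, GroupDesign, StatMaps, cluster_p_perm,
                             cluster_p_rft, compute_global, fdr_select,
                             fit_two_group_glm, make_cluster_table,
                             proportional_scale, t_to_z, t_upper_p,
                             threshold_and_cluster)
from ctvbm.volume_io import GridSpec, Volume3D


def _vol(data, voxel=2.0, modality="mr"):
    data = np.asarray(data, dtype=float)
    grid = GridSpec.isotropic(data.shape, voxel)
    return Volume3D(data, grid.affine, modality)


class TestGlobals:
    def test_two_pass_rule_hand_case(self):
        """Block of ones over 10% of voxels: mean 0.1, threshold 0.0125,
        so the global is exactly 1.0."""
        data = np.zeros((10, 10, 10))
        data[:1] = 1.0  # 100 of 1000 voxels
        assert compute_global(_vol(data)) == pytest.approx(1.0)

    def test_constant_positive(self):
        assert compute_global(_vol(np.full((4, 4, 4), 2.5))) == pytest.approx(2.5)

    def test_all_zero_rejected(self):
        with pytest.raises(DegenerateInputError):
            compute_global(_vol(np.zeros((4, 4, 4))))


class TestProportionalScaling:
    def test_identical_images_unchanged(self):
        vols = [_vol(np.full((4, 4, 4), 2.0)) for _ in range(3)]
        out = proportional_scale(vols, [2.0, 2.0, 2.0])
        for o in out:
            np.testing.assert_allclose(o.data, 2.0)

    def test_two_image_arithmetic(self):
        v1, v2 = _vol(np.full((4, 4, 4), 2.0)), _vol(np.full((4, 4, 4), 4.0))
        out = proportional_scale([v1, v2], [2.0, 4.0])
        np.testing.assert_allclose(out[0].data, 3.0)   # x1.5
        np.testing.assert_allclose(out[1].data, 3.0)   # x0.75

    def test_globals_equalized_on_random_images(self, rng):
        vols = [_vol(rng.uniform(0.2, 1.0, (8, 8, 8))) for _ in range(4)]
        gs = [compute_global(v) for v in vols]
        out = proportional_scale(vols, gs)
        new = [compute_global(v) for v in out]
        np.testing.assert_allclose(new, new[0], rtol=1e-9)

    def test_nonpositive_global_rejected(self):
        with pytest.raises(ValueError):
            proportional_scale([_vol(np.ones((4, 4, 4)))], [0.0])


class TestTwoGroupGlm:
    def test_scalar_oracle(self, rng):
        """Voxelwise t equals the textbook pooled two-sample formula."""
        a = np.array([1, 1, 1, 1, 1], dtype=float) + rng.normal(0, 1e-3, 5)
        b = np.zeros(7) + rng.normal(0, 1e-3, 7)
        vols = [_vol(np.full((3, 3, 3), v)) for v in np.concatenate([a, b])]
        groups = ["control"] * 5 + ["patient"] * 7
        maps = fit_two_group_glm(GroupDesign(vols, groups),
                                 mask_threshold=0.0, scale=False)
        sp2 = (np.var(a, ddof=1) * 4 + np.var(b, ddof=1) * 6) / 10
        t_expect = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 5 + 1 / 7))
        assert maps.t_map.data[1, 1, 1] == pytest.approx(t_expect, rel=1e-9)
        assert maps.df == 10

    def test_null_mean_t_near_zero(self, rng):
        vols = [_vol(rng.normal(1.0, 0.1, (12, 12, 12))) for _ in range(12)]
        groups = ["control"] * 6 + ["patient"] * 6
        maps = fit_two_group_glm(GroupDesign(vols, groups), scale=False)
        mask = maps.analysis_mask.mask
        assert abs(maps.t_map.data[mask].mean()) < 0.05

    def test_null_voxelwise_calibration(self):
        """Fraction of suprathreshold voxels under the null ~ voxel_p."""
        rng = np.random.default_rng(99)
        from ctvbm.smoothing import smooth_gaussian
        vols = []
        grid = GridSpec.isotropic((24, 24, 24), 4.0)
        for _ in range(12):
            d = rng.normal(1.0, 0.3, grid.shape)
            vols.append(Volume3D(d, grid.affine, "mr"))
        groups = ["control"] * 6 + ["patient"] * 6
        maps = fit_two_group_glm(GroupDesign(vols, groups),
                                 mask_threshold=0.5, scale=False)
        t_crit = stats.t.isf(0.005, maps.df)
        frac = (np.abs(maps.t_map.data[maps.analysis_mask.mask]) > t_crit).mean()
        # two-sided: expect ~2*0.005
        assert frac == pytest.approx(0.01, abs=0.006)

    def test_small_group_rejected(self):
        vols = [_vol(np.ones((3, 3, 3))) for _ in range(3)]
        with pytest.raises(ValueError):
            GroupDesign(vols, ["control", "patient", "patient"])


class TestTtoZ:
    def test_zero_maps_to_zero(self):
        for df in (1, 5, 10, 100):
            assert t_to_z(0.0, df) == 0.0

    @pytest.mark.parametrize("t_val,df,z_expect,p_expect", [
        (8.955, 10, 4.595, 2.16e-6),
        (9.359, 10, 4.677, 1.45e-6),
    ])
    def test_table_triples(self, t_val, df, z_expect, p_expect):
        """The printed peak t / Z / P triples are internally consistent at
        df = 10 (5 patients vs 7 controls)."""
        assert t_to_z(t_val, df) == pytest.approx(z_expect, abs=0.005)
        assert t_upper_p(t_val, df) == pytest.approx(p_expect, rel=0.02)
        # and the inverse-normal of the printed P reproduces the printed Z
        assert stats.norm.isf(p_expect) == pytest.approx(z_expect, abs=0.005)

    def test_monotone_and_odd(self):
        ts = np.linspace(-30, 30, 121)
        z = t_to_z(ts, 10)
        assert np.all(np.diff(z) > 0)
        np.testing.assert_allclose(z, -t_to_z(-ts, 10), atol=1e-12)

    def test_large_df_agrees_with_identity(self):
        ts = np.linspace(-3, 3, 25)
        z = t_to_z(ts, 250)
        assert np.abs(z - ts).max() < 0.05

    def test_no_saturation_at_extreme_t(self):
        z = t_to_z(40.0, 10)
        assert np.isfinite(z) and z > 7


def _maps_from_t(t_data, df=10, fwhm=(8.0, 8.0, 8.0), voxel=2.0):
    vol = _vol(t_data, voxel)
    z = t_to_z(np.asarray(t_data, dtype=float), df)
    return StatMaps(
        t_map=vol,
        z_map=Volume3D(z, vol.affine, "mr"),
        df=df,
        analysis_mask=BrainMask(np.ones(vol.data.shape, dtype=bool)),
        resid_fwhm_mm=np.asarray(fwhm),
    )


class TestClustering:
    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(connectivity)
        for _ in range(20):
            mask = rng.uniform(size=(20, 20, 20)) < 0.25
            t_data = np.where(mask, 10.0, 0.0)
            maps = _maps_from_t(t_data)
            clusters = threshold_and_cluster(maps, 0.005, connectivity, 0)
            oracle, n = flood_fill_labels(mask, connectivity)
            assert len(clusters) == n
            # identical partition: each cluster maps to exactly one oracle label
            for cl in clusters:
                labs = oracle[tuple(cl.indices.T)]
                assert labs.min() == labs.max()
                assert (oracle == labs[0]).sum() == cl.size

    def test_two_separated_blobs(self):
        t_data = np.zeros((16, 16, 16))
        t_data[2:5, 2:5, 2:5] = 10.0
        t_data[10:13, 10:13, 10:13] = 10.0
        clusters = threshold_and_cluster(_maps_from_t(t_data), 0.005, 18, 0)
        assert sorted(c.size for c in clusters) == [27, 27]

    def test_extent_threshold_semantics(self):
        t_data = np.zeros((12, 12, 12))
        t_data[1:6, 1:6, 1:4] = 10.0      # a 75-voxel blob
        maps = _maps_from_t(t_data)
        assert threshold_and_cluster(maps, 0.005, 18, 123) == []
        assert len(threshold_and_cluster(maps, 0.005, 18, 75)) == 1

    def test_study_cluster_sizes_pass_extent(self):
        for size in (2776, 630, 366):
            assert size >= 123  # all reported CT clusters clear the threshold


class TestClusterPRft:
    def test_zero_size_is_one(self):
        maps = _maps_from_t(np.zeros((8, 8, 8)))
        assert cluster_p_rft(0, maps) == 1.0

    def test_monotone_in_size(self):
        maps = _maps_from_t(np.zeros((12, 12, 12)))
        sizes = [5, 10, 20, 40, 80, 160]
        ps = [cluster_p_rft(s, maps) for s in sizes]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_agrees_with_permutation_within_factor_two(self):
        """Family-wise RFT cluster p vs the permutation estimate on a
        matched null cohort."""
        spec = PhantomSpec()
        imgs, groups = generate_density_cohort(7, 5, spec=spec, atrophy=None,
                                               seed=77)
        design = GroupDesign(imgs, groups)
        maps = fit_two_group_glm(design, scale=False)
        # probe sizes spanning the bulk of the null max-cluster distribution
        probes = [20, 30, 40]
        perm_ps = cluster_p_perm(design, probes, voxel_p=0.005,
                                 connectivity=18, n_perm=2000, seed=3,
                                 scale=False)
        for size, pp in zip(probes, perm_ps):
            pr = cluster_p_rft(size, maps, voxel_p=0.005, corrected=True)
            assert pr / pp < 2.0 and pp / pr < 2.0


class TestClusterPPerm:
    def test_extreme_and_zero_cases(self):
        rng = np.random.default_rng(5)
        grid = GridSpec.isotropic((10, 10, 10), 4.0)
        vols = [Volume3D(rng.normal(1, 0.1, grid.shape), grid.affine, "mr")
                for _ in range(12)]
        design = GroupDesign(vols, ["control"] * 7 + ["patient"] * 5)
        ps = cluster_p_perm(design, [10**6, 0], n_perm=100, seed=0, scale=False)
        assert ps[0] == pytest.approx(1.0 / 101)
        assert ps[1] == 1.0

    def test_too_few_permutations_rejected(self):
        rng = np.random.default_rng(6)
        grid = GridSpec.isotropic((6, 6, 6), 4.0)
        vols = [Volume3D(rng.normal(1, 0.1, grid.shape), grid.affine, "mr")
                for _ in range(4)]
        design = GroupDesign(vols, ["control"] * 2 + ["patient"] * 2)
        with pytest.raises(ValueError):
            cluster_p_perm(design, [5], n_perm=100, seed=0)  # C(4,2)=6 < 20

    def test_super_uniform_under_null(self):
        """Max-statistic permutation p-values are stochastically >= uniform
        under the null (Kolmogorov-Smirnov, one-sided)."""
        rng = np.random.default_rng(8)
        spec = PhantomSpec(shape=(24, 24, 24), voxel_mm=8.0)
        pvals = []
        for i in range(40):
            imgs, groups = generate_density_cohort(5, 4, spec=spec,
                                                   atrophy=None, seed=500 + i)
            design = GroupDesign(imgs, groups)
            maps = fit_two_group_glm(design, scale=False)
            clusters = threshold_and_cluster(maps, 0.01, 18, 0)
            obs = max((c.size for c in clusters), default=0)
            p = cluster_p_perm(design, [obs], voxel_p=0.01, n_perm=199,
                               seed=i, scale=False)[0]
            pvals.append(p)
        # one-sided KS: empirical CDF must not exceed uniform significantly
        pvals = np.sort(pvals)
        ecdf = np.arange(1, len(pvals) + 1) / len(pvals)
        d_plus = float(np.max(ecdf - pvals))
        # critical one-sided KS value at alpha=0.01 for n=40
        assert d_plus < 1.52 / np.sqrt(len(pvals))


class TestFdrSelect:
    def test_single_p(self):
        assert fdr_select([0.001], 0.05) == [True]

    def test_step_up_hand_case(self):
        # sorted thresholds 0.0167, 0.0333, 0.05
        assert fdr_select([0.01, 0.02, 0.20], 0.05) == [True, True, False]

    def test_all_ones(self):
        assert fdr_select([1.0, 1.0, 1.0], 0.05) == [False, False, False]

    def test_empty(self):
        assert fdr_select([], 0.05) == []


class TestClusterTable:
    def test_single_cluster_single_peak(self):
        t_data = np.zeros((10, 10, 10))
        t_data[3:5, 3:5, 3:5] = 5.0
        t_data[4, 4, 4] = 9.0
        t_data[3, 3, 3] = 5.0
        maps = _maps_from_t(t_data)
        clusters = threshold_and_cluster(maps, 0.005, 18, 0)
        table = make_cluster_table(clusters, maps, max_peaks=1)
        assert len(table.frame) == 1
        row = table.frame.iloc[0]
        assert row.cluster_size_voxels == 8
        peak_world = maps.grid.voxel_to_world(np.array([4.0, 4.0, 4.0]))
        assert (row.x_mm, row.y_mm, row.z_mm) == tuple(peak_world)
        assert row.peak_t == pytest.approx(9.0)
        assert row.peak_p_uncorrected == pytest.approx(
            float(stats.t.sf(9.0, 10)), rel=1e-9)

    def test_voxel_to_volume_conversion(self):
        t_data = np.zeros((16, 16, 16))
        idx = np.unravel_index(np.arange(123), (16, 16, 16))
        t_data[idx] = 10.0
        maps = _maps_from_t(t_data, voxel=2.0)
        clusters = threshold_and_cluster(maps, 0.005, 26, 0)
        table = make_cluster_table(clusters, maps)
        assert table.frame.volume_mm3.iloc[0] == pytest.approx(
            table.frame.cluster_size_voxels.iloc[0] * 8.0)

    def test_publication_schema(self):
        t_data = np.zeros((10, 10, 10))
        t_data[2:6, 2:6, 2:6] = 8.0
        maps = _maps_from_t(t_data)
        clusters = threshold_and_cluster(maps, 0.005, 18, 0)
        pub = make_cluster_table(clusters, maps).to_publication_table()
        assert list(pub.columns[:4]) == [
            "Cluster size, voxels", "Peak P (uncorrected)",
            "Peak t value", "Peak Z value"]

    def test_peaks_min_distance(self):
        t_data = np.zeros((20, 20, 20))
        t_data[2:18, 8:11, 8:11] = 4.0
        t_data[3, 9, 9] = 9.0
        t_data[16, 9, 9] = 8.0
        t_data[4, 9, 9] = 8.5     # within 8 mm of the first peak: suppressed
        maps = _maps_from_t(t_data)
        clusters = threshold_and_cluster(maps, 0.005, 18, 0)
        table = make_cluster_table(clusters, maps)
        assert len(table.frame) >= 2
        xs = table.frame[["x_mm", "y_mm", "z_mm"]].to_numpy()
        for i in range(len(xs)):
            for j in range(i + 1, len(xs)):
                assert np.linalg.norm(xs[i] - xs[j]) >= 8.0
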