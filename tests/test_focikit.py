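"""Imaging measurements: rescaling, segmentation filters, features,
cluster statistics, periphery coverage and masked-signal quantification."""

from __future__ import annotations

import numpy as np
import pytest

from replidyn import focikit
from replidyn.focikit import (
    FocusRecord,
    NucleusMask,
    VoxelGrid,
    chromocenter_props,
    cluster_stats,
    cluster_stats_from_counts,
    focus_features,
    histone_cc_ratio,
    isotropic_rescale,
    masked_signal,
    periphery_coverage,
    segment_foci,
    segment_nuclei,
)
from replidyn.synthgen import ImageSimConfig, simulate_stacks

ISO = (40.0, 40.0, 40.0)


def ball_mask(shape, center, radius):
    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    return (
        (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    ) <= radius**2


def record_from_mask(mask, focus_id=0, nucleus_id=1, regime="sim"):
    sub = np.asarray(mask, dtype=bool)
    centroid = tuple(float(c) for c in np.argwhere(sub).mean(axis=0))
    return FocusRecord(
        focus_id=focus_id,
        nucleus_id=nucleus_id,
        voxel_count=int(sub.sum()),
        volume_um3=float(sub.sum()) * np.prod(ISO) / 1e9,
        centroid=centroid,
        resolution_regime=regime,
        _bbox=((0, 0, 0), sub.shape),
        _submask=sub,
        _shape=sub.shape,
    )


class TestIsotropicRescale:
    def test_isotropic_grid_unchanged(self):
        g = VoxelGrid(np.ones((4, 4, 4)), ISO)
        assert isotropic_rescale(g) is g

    def test_z_upsampling_factor(self):
        g = VoxelGrid(np.random.default_rng(0).random((16, 32, 32)), (125.0, 40.0, 40.0))
        out = isotropic_rescale(g)
        assert out.voxel_nm == (40.0, 40.0, 40.0)
        assert out.data.shape == (50, 32, 32)  # 16 × 3.125

    def test_sum_preserved_within_one_percent(self):
        g = VoxelGrid(
            np.random.default_rng(1).random((16, 32, 32)) + 1.0, (125.0, 40.0, 40.0)
        )
        out = isotropic_rescale(g)
        assert out.data.sum() == pytest.approx(g.data.sum(), rel=0.01)

    def test_constant_grid_stays_constant(self):
        g = VoxelGrid(np.full((10, 8, 8), 7.0), (125.0, 40.0, 40.0))
        out = isotropic_rescale(g)
        assert np.allclose(out.data, out.data.flat[0])


class TestSegmentNuclei:
    def test_single_bright_sphere(self):
        data = np.where(ball_mask((24, 48, 48), (12, 24, 24), 10), 200.0, 5.0)
        mask = segment_nuclei(VoxelGrid(data, ISO), min_volume_um3=0.1)
        assert mask.ids() == [1]

    def test_two_spheres_with_markers(self):
        shape = (24, 64, 64)
        data = np.full(shape, 5.0)
        data[ball_mask(shape, (12, 30, 20), 10)] = 200.0
        data[ball_mask(shape, (12, 34, 42), 10)] = 200.0
        mask = segment_nuclei(
            VoxelGrid(data, ISO), markers=[(12, 30, 20), (12, 34, 42)],
            min_volume_um3=0.1,
        )
        assert len(mask.ids()) == 2

    def test_empty_stack_warns(self):
        with pytest.warns(UserWarning, match="foreground"):
            mask = segment_nuclei(VoxelGrid(np.zeros((4, 8, 8)), ISO))
        assert mask.ids() == []

    def test_synthetic_nuclei_recovered_with_high_jaccard(self):
        cfg = ImageSimConfig(
            shape_zyx=(20, 220, 220), n_nuclei=3, nucleus_radius_um=1.6,
            n_foci=0, seed=9,
        )
        channels, gt = simulate_stacks(cfg)
        markers = [
            (r.z, r.y, r.x) for r in gt.nucleus_centers.itertuples()
        ]
        mask = segment_nuclei(channels["dapi"], markers=markers)
        assert len(mask.ids()) == 3
        for nid in (1, 2, 3):
            truth = gt.nuclei == nid
            got = mask.labels == nid
            jac = (truth & got).sum() / (truth | got).sum()
            assert jac > 0.9


class TestSegmentFoci:
    def _nucleus_everywhere(self, shape):
        return NucleusMask(np.ones(shape, dtype=np.int32), ISO)

    def test_well_separated_gaussians_counted(self):
        shape = (24, 96, 96)
        grid = np.full(shape, 2.0)
        centers = [(12, 20, 20), (12, 20, 70), (12, 70, 20), (12, 70, 70), (12, 45, 45)]
        zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
        for c in centers:
            d2 = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
            grid += 500.0 * np.exp(-0.5 * d2 / 2.0**2)
        recs = segment_foci(
            VoxelGrid(grid, ISO), self._nucleus_everywhere(shape), regime="sim"
        )
        assert len(recs) == 5

    def test_confocal_discards_sub_psf_object(self):
        # 150 voxels is below the one-PSF floor of 200; 7×7×7 = 343 passes
        shape = (30, 60, 60)
        small = np.full(shape, 1.0)
        small[10:16, 10:15, 10:15] = 1000.0  # 6×5×5 = 150 voxels
        recs = segment_foci(
            VoxelGrid(small, ISO), self._nucleus_everywhere(shape), regime="confocal"
        )
        assert len(recs) == 0
        big = np.full(shape, 1.0)
        big[10:17, 10:17, 10:17] = 1000.0
        recs = segment_foci(
            VoxelGrid(big, ISO), self._nucleus_everywhere(shape), regime="confocal"
        )
        assert len(recs) == 1

    def test_confocal_nuclear_overlap_rule(self):
        shape = (20, 40, 80)
        labels = np.zeros(shape, dtype=np.int32)
        labels[:, :, :40] = 1  # nucleus covers the left half
        mask = NucleusMask(labels, ISO)
        data = np.full(shape, 1.0)
        data[6:14, 16:24, 30:44] = 1000.0  # ~71% of x-extent inside the nucleus
        recs = segment_foci(VoxelGrid(data, ISO), mask, regime="confocal")
        assert len(recs) == 1 and recs[0].nucleus_id == 1
        data2 = np.full(shape, 1.0)
        data2[6:14, 16:24, 36:50]= 1000.0  # only ~29% inside
        recs2 = segment_foci(VoxelGrid(data2, ISO), mask, regime="confocal")
        assert recs2 == []

    def test_sim_minimum_volume_filter(self):
        # at 40 nm isotropic voxels, 0.0002 μm³ is 3.125 voxels: 3 fails, 8 passes
        shape = (16, 32, 32)
        data = np.zeros(shape)
        data[8, 10, 10:13] = 1000.0  # 3 voxels
        data[8:10, 20:22, 20:22] = 1000.0  # 8 voxels
        recs = segment_foci(
            VoxelGrid(data, ISO), self._nucleus_everywhere(shape), regime="sim",
            watershed_split=False,
        )
        assert len(recs) == 1 and recs[0].voxel_count == 8

    def test_unknown_regime_rejected(self):
        with pytest.raises(ValueError):
            segment_foci(
                VoxelGrid(np.zeros((4, 8, 8)), ISO),
                self._nucleus_everywhere((4, 8, 8)),
                regime="widefield",
            )

    def test_size_filter_monotonicity(self, sim_stack_run):
        _, _, _, rep, _, mask = sim_stack_run
        recs = segment_foci(rep, mask, regime="sim")
        sizes = np.array([r.voxel_count for r in recs])
        # raising the minimum volume can only reduce the count
        for k in (5, 10, 20, 50):
            assert (sizes >= k).sum() <= len(recs)
        assert (sizes >= 1).all()


class TestFocusFeatures:
    def test_ball_solidity_near_one(self):
        rec = record_from_mask(ball_mask((21, 21, 21), (10, 10, 10), 7))
        table, _ = focus_features([rec], {})
        assert table.solidity.iloc[0] > 0.9

    def test_cross_less_solid_than_ball(self):
        cross = np.zeros((21, 21, 21), dtype=bool)
        cross[8:13, 8:13, 2:19] = True
        cross[8:13, 2:19, 8:13] = True
        cross[2:19, 8:13, 8:13] = True
        rec = record_from_mask(cross)
        table, _ = focus_features([rec], {})
        ball = record_from_mask(ball_mask((21, 21, 21), (10, 10, 10), 7))
        ball_table, _ = focus_features([ball], {})
        assert table.solidity.iloc[0] < ball_table.solidity.iloc[0]

    def test_center_distance_equals_radius(self):
        shape = (31, 31, 31)
        nucleus = ball_mask(shape, (15, 15, 15), 12)
        mask = NucleusMask(nucleus.astype(np.int32), ISO)
        rec = record_from_mask(ball_mask(shape, (15, 15, 15), 2))
        _, _ = focus_features([rec], {}, mask=mask)
        r_um = 12 * 40.0 / 1000.0
        assert rec.distance_to_border_um == pytest.approx(r_um, rel=0.1)

    def test_tiny_object_solidity_one_by_convention(self):
        sub = np.zeros((5, 5, 5), dtype=bool)
        sub[2, 2, 2:4] = True
        rec = record_from_mask(sub)
        table, _ = focus_features([rec], {})
        assert table.solidity.iloc[0] == 1.0


class TestClusterStats:
    def test_count_example(self):
        s = cluster_stats_from_counts([1, 3, 5])
        assert s.pct_single == pytest.approx(100 / 3)
        assert s.pct_clustered == pytest.approx(200 / 3)
        assert s.mean_clustered_size == pytest.approx(4.0)
        assert s.pct_single + s.pct_clustered == pytest.approx(100.0)

    def test_all_singletons(self):
        s = cluster_stats_from_counts([1, 1, 1])
        assert s.pct_clustered == 0.0 and s.mean_clustered_size is None

    def test_record_assignment_and_conservation(self):
        shape = (10, 40, 40)
        pwf_a = np.zeros(shape, dtype=bool); pwf_a[2:8, 5:15, 5:15] = True
        pwf_b = np.zeros(shape, dtype=bool); pwf_b[2:8, 25:35, 25:35] = True
        pwf = [record_from_mask(pwf_a, 0), record_from_mask(pwf_b, 1)]
        nano_masks = []
        for c in [(5, 8, 8), (5, 12, 12), (5, 30, 30), (5, 2, 38)]:
            m = np.zeros(shape, dtype=bool)
            m[c[0] - 1 : c[0] + 2, c[1] - 1 : c[1] + 2, c[2] - 1 : c[2] + 2] = True
            nano_masks.append(m)
        nano = [record_from_mask(m, i) for i, m in enumerate(nano_masks)]
        s = cluster_stats(pwf, nano)
        assert s.n_nano_assigned + s.n_nano_unassigned == 4
        assert s.n_nano_unassigned == 1
        assert s.ratio_nano_per_pwf == pytest.approx(3 / 2)
        assert s.mean_clustered_size == pytest.approx(2.0)

    def test_generator_law_recovered(self):
        from replidyn.synthgen import ClusterSizeLaw, sample_cluster_sizes

        sizes = sample_cluster_sizes(
            ClusterSizeLaw("one_plus_poisson", {"lam": 2.845}), 100_000, rng=3
        )
        s = cluster_stats_from_counts(sizes.tolist())
        expected = 1.0 + 2.845 / (1.0 - np.exp(-2.845))
        assert s.mean_clustered_size == pytest.approx(expected, abs=0.03)


class TestPeriphery:
    def _setup(self):
        shape = (31, 31, 31)
        nucleus = ball_mask(shape, (15, 15, 15), 12)
        return shape, NucleusMask(nucleus.astype(np.int32), ISO)

    def test_no_foci_zero(self):
        _, mask = self._setup()
        assert periphery_coverage([], mask, band_um=0.44) == 0.0

    def test_full_tiling_hundred(self):
        shape, mask = self._setup()
        rec = record_from_mask(mask.labels > 0)
        assert periphery_coverage([rec], mask, band_um=0.44) == pytest.approx(100.0)

    def test_known_fraction_recovered(self):
        shape, mask = self._setup()
        shell = mask.border_shell(0.44) > 0
        idx = np.argwhere(shell)
        chosen = idx[:: 10]  # every 10th shell voxel ≈ 10%
        sub = np.zeros(shape, dtype=bool)
        sub[tuple(chosen.T)] = True
        rec = record_from_mask(sub)
        expected = 100.0 * len(chosen) / shell.sum()
        assert periphery_coverage([rec], mask, 0.44) == pytest.approx(expected)

    def test_empty_shell_errors(self):
        mask = NucleusMask(np.zeros((5, 5, 5), dtype=np.int32), ISO)
        with pytest.raises(ValueError):
            periphery_coverage([], mask)


class TestMaskedSignal:
    def test_uniform_sum(self):
        labels = np.zeros((5, 5, 5), dtype=np.int32)
        labels[0, :, :] = 1  # 25 voxels
        labels[1, :, :] = 1  # 50 total
        sig = VoxelGrid(np.full((5, 5, 5), 100.0), ISO)
        table = masked_signal(labels, sig, baseline=0.0)
        assert table["sum"].iloc[0] == 5000.0

    def test_baseline_equals_signal_gives_zero(self):
        labels = np.ones((3, 3, 3), dtype=np.int32)
        sig = VoxelGrid(np.full((3, 3, 3), 40.0), ISO)
        table = masked_signal(labels, sig, baseline=40.0)
        assert table["sum"].iloc[0] == 0.0

    def test_linearity_in_signal(self):
        rng = np.random.default_rng(5)
        labels = (rng.random((6, 6, 6)) > 0.5).astype(np.int32)
        data = rng.random((6, 6, 6)) * 10
        t1 = masked_signal(labels, VoxelGrid(data, ISO))
        t3 = masked_signal(labels, VoxelGrid(3 * data, ISO))
        assert t3["sum"].iloc[0] == pytest.approx(3 * t1["sum"].iloc[0])

    def test_empty_mask_empty_table(self):
        table = masked_signal(
            np.zeros((3, 3, 3), dtype=np.int32), VoxelGrid(np.ones((3, 3, 3)), ISO)
        )
        assert table.empty

    def test_elevated_chromocenter_signal_detected(self):
        # stage-II-like stack: replication signal enriched at chromocenters
        shape = (20, 40, 40)
        cc = np.zeros(shape, dtype=np.int32)
        cc[ball_mask(shape, (10, 12, 12), 4)] = 1
        cc[ball_mask(shape, (10, 28, 28), 4)] = 2
        rng = np.random.default_rng(6)
        rep = rng.normal(50, 2, size=shape)
        rep[cc > 0] += 100.0
        table = masked_signal(cc, VoxelGrid(rep, ISO), baseline=0.0)
        outside_mean = rep[cc == 0].mean()
        assert (table["mean"] > outside_mean + 50).all()


class TestHistoneRatio:
    @pytest.mark.parametrize(
        "cc, np_, expected",
        [
            ([2, 2, 2, 2], [1, 1, 1, 1], 2.0),
            ([1.5, 1.5, 1.5, 1.5], [1.5, 1.5, 1.5, 1.5], 1.0),
            ([3, 1, 2, 2], [2, 2, 2, 2], 1.0),
        ],
    )
    def test_examples(self, cc, np_, expected):
        assert histone_cc_ratio(cc, np_) == pytest.approx(expected)

    def test_zero_nucleoplasm_rejected(self):
        with pytest.raises(ValueError):
            histone_cc_ratio([1, 1, 1, 1], [0, 0, 0, 0])

    def test_wrong_roi_count_rejected(self):
        with pytest.raises(ValueError):
            histone_cc_ratio([1, 1], [1, 1, 1, 1])


class TestChromocenters:
    def _stack(self, centers, radius=4, shape=(24, 64, 64)):
        nucleus = ball_mask(shape, (12, 32, 32), 28)
        nucleus[:, :, :] = nucleus  # nucleus may exceed z range; fine
        data = np.where(nucleus, 100.0, 5.0)
        for c in centers:
            data[ball_mask(shape, c, radius)] = 300.0
        return (
            VoxelGrid(data, ISO),
            NucleusMask(nucleus.astype(np.int32), ISO),
        )

    def test_sphere_shape_factor_near_one(self):
        dapi, mask = self._stack([(12, 32, 32)], radius=5)
        table = chromocenter_props(dapi, mask)
        assert len(table) == 1
        assert 0.8 < table.shape_factor.iloc[0] <= 1.1
        assert table.compaction.iloc[0] > 1.5

    def test_elongated_object_less_spherical(self):
        shape = (24, 64, 64)
        nucleus = np.ones(shape, dtype=bool)
        data = np.full(shape, 100.0)
        zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
        ellipsoid = (
            ((zz - 12) / 3.0) ** 2 + ((yy - 32) / 3.0) ** 2 + ((xx - 32) / 14.0) ** 2
        ) <= 1.0
        data[ellipsoid] = 300.0
        dapi = VoxelGrid(data, ISO)
        mask = NucleusMask(nucleus.astype(np.int32), ISO)
        table = chromocenter_props(dapi, mask)
        sphere_dapi, sphere_mask = self._stack([(12, 32, 32)], radius=5)
        sphere = chromocenter_props(sphere_dapi, sphere_mask)
        assert table.shape_factor.iloc[0] < sphere.shape_factor.iloc[0]

    def test_count_recovery(self):
        # 12 well-separated blobs on a grid inside one big nucleus
        shape = (24, 80, 80)
        nucleus = np.ones(shape, dtype=bool)
        data = np.full(shape, 100.0)
        for i in range(12):
            z = 6 + 10 * (i % 2)
            y = 14 + 18 * (i // 4)
            x = 14 + 18 * (i % 4)
            data[ball_mask(shape, (z, y, x), 5)] = 300.0
        table = chromocenter_props(
            VoxelGrid(data, ISO), NucleusMask(nucleus.astype(np.int32), ISO)
        )
        assert len(table) == 12

    def test_no_chromocenters_zero_rows(self):
        shape = (10, 20, 20)
        data = np.full(shape, 100.0)
        table = chromocenter_props(
            VoxelGrid(data, ISO), NucleusMask(np.ones(shape, dtype=np.int32), ISO)
        )
        assert table.empty


class TestStageHelper:
    def test_rule_ordering(self):
        shape = (31, 31, 31)
        nucleus = ball_mask(shape, (15, 15, 15), 12)
        mask = NucleusMask(nucleus.astype(np.int32), ISO)
        dapi = VoxelGrid(np.where(nucleus, 100.0, 5.0), ISO)
        # too few foci: end-of-S-phase pattern
        assert focikit.classify_s_phase_stage([], mask, dapi) == "Y"
        # many interior foci at nuclear DAPI level: early pattern
        recs = []
        for i in range(25):
            m = np.zeros(shape, dtype=bool)
            m[10 + (i % 5), 10 + (i // 5), 12:15] = True
            r = record_from_mask(m, i)
            r.mean_intensity["dapi"] = 100.0
            recs.append(r)
        assert focikit.classify_s_phase_stage(recs, mask, dapi) == "I"
        # same foci but DAPI-bright (chromocenter-overlapping): mid pattern
        for r in recs:
            r.mean_intensity["dapi"] = 200.0
        assert focikit.classify_s_phase_stage(recs, mask, dapi) == "II"
        # foci tiling the periphery shell: stage III pattern
        shell_rec = record_from_mask(mask.border_shell(0.44) > 0)
        shell_rec.mean_intensity["dapi"] = 100.0
        shell_recs = [shell_rec] + recs[:24]
        for r in shell_recs:
            r.mean_intensity["dapi"] = 100.0
        assert focikit.classify_s_phase_stage(shell_recs, mask, dapi) == "III"
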