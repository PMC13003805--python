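"""Morphometry cascade: segmentation, lumen filling, skeleton, radii, VSD."""

import numpy as np
import pytest
from scipy import ndimage

from vsdprint.core import BinaryVascularVolume, IntensityVolume, VoxelGrid
from vsdprint.morphometry import (
    VesselTable,
    compute_cbv,
    compute_vsd,
    enhance_contrast,
    fill_lumens,
    mean_radius_from_vsd,
    mean_radius_true,
    segment,
    skeletonize_and_label,
    starline_radii,
    starline_radius,
    vessel_table,
    vsd_from_radii,
)

from conftest import make_ball, make_cylinder


class TestContrastAndSegmentation:
    def test_clahe_of_constant_volume_is_constant(self):
        vol = IntensityVolume(np.full((24, 24, 24), 7.0), VoxelGrid((24, 24, 24), 1.8))
        out = enhance_contrast(vol)
        assert np.ptp(out.data) == 0.0
        assert out.data.shape == vol.data.shape

    def test_clahe_does_not_reduce_bimodal_contrast(self, rng):
        data = np.full((32, 32, 32), 0.3) + rng.normal(0, 0.01, (32, 32, 32))
        data[10:22, 10:22, 10:22] = 0.5 + rng.normal(0, 0.01, (12, 12, 12))
        vol = IntensityVolume(data, VoxelGrid((32, 32, 32), 1.8))
        out = enhance_contrast(vol)
        inner = np.zeros_like(data, dtype=bool)
        inner[10:22, 10:22, 10:22] = True
        gap_before = data[inner].mean() - data[~inner].mean()
        gap_after = out.data[inner].mean() - out.data[~inner].mean()
        assert gap_after >= gap_before

    def test_segmentation_recovers_known_mask(self, rng):
        mask_vol, _ = make_cylinder(n=48, radius_vox=6.0, direction=(1, 0.3, 0.1))
        truth = mask_vol.mask
        data = np.where(truth, 200.0, 50.0) + rng.normal(0, 10.0, truth.shape)
        seg = segment(IntensityVolume(data, mask_vol.grid))
        dice = 2 * (seg.mask & truth).sum() / (seg.mask.sum() + truth.sum())
        assert dice >= 0.95
        assert seg.meta["threshold"] is not None

    def test_segment_constant_volume_warns_and_is_empty(self):
        vol = IntensityVolume(np.ones((16, 16, 16)), VoxelGrid((16, 16, 16), 1.8))
        with pytest.warns(UserWarning, match="constant"):
            seg = segment(vol)
        assert not seg.mask.any()

    def test_threshold_invariant_to_additive_shift(self, rng):
        data = rng.normal(0, 1, (20, 20, 20))
        data[:10] += 4.0
        grid = VoxelGrid((20, 20, 20), 1.8)
        a = segment(IntensityVolume(data, grid))
        b = segment(IntensityVolume(data + 13.5, grid))
        assert np.array_equal(a.mask, b.mask)


class TestLumenFilling:
    def test_hollow_shell_is_filled(self):
        # wall of thickness 1 voxel around a 2-voxel-radius lumen
        grid = VoxelGrid((24, 24, 24), 1.0)
        ax = np.arange(24, dtype=float)
        y, z = np.meshgrid(ax - 11.5, ax - 11.5, indexing="ij")
        rho = np.sqrt(y**2 + z**2)
        shell3d = np.broadcast_to((rho >= 2) & (rho < 3.2), (24, 24, 24)).copy()
        filled = fill_lumens(BinaryVascularVolume(shell3d, grid), kernel_radius_um=2.0)
        lumen = np.broadcast_to(rho < 2, (24, 24, 24))
        assert filled.mask[lumen].all()

    def test_solid_cylinder_essentially_unchanged(self):
        vol, _ = make_cylinder(n=32, radius_vox=5.0)
        out = fill_lumens(vol)
        added = out.mask & ~vol.mask
        assert not (vol.mask & ~out.mask).any()  # closing never removes
        assert added.sum() <= 0.1 * vol.mask.sum()  # ≤ small boundary residue

    def test_largest_component_rule(self):
        grid = VoxelGrid((30, 30, 30), 1.0)
        m = np.zeros((30, 30, 30), dtype=bool)
        m[2:22, 5:12, 5:12] = True  # ~1000 voxels
        m[25:27, 25:29, 25:29] = False
        m[26, 26, 26] = True  # isolated speck
        out = fill_lumens(BinaryVascularVolume(m, grid))
        assert not out.mask[26, 26, 26]
        assert out.mask[10, 8, 8]

    def test_empty_mask_passthrough(self):
        grid = VoxelGrid((16, 16, 16), 1.8)
        out = fill_lumens(BinaryVascularVolume(np.zeros((16, 16, 16), bool), grid))
        assert not out.mask.any()


class TestCbv:
    def test_empty_and_full(self):
        grid = VoxelGrid((16, 16, 16), 1.8)
        assert compute_cbv(BinaryVascularVolume(np.zeros((16, 16, 16), bool), grid)) == 0.0
        assert compute_cbv(BinaryVascularVolume(np.ones((16, 16, 16), bool), grid)) == 1.0

    def test_rotation_invariance(self):
        vol, _ = make_cylinder(n=32, radius_vox=4.0, direction=(1, 0.4, 0.2))
        base = compute_cbv(vol)
        for k in range(1, 4):
            rot = BinaryVascularVolume(np.rot90(vol.mask, k, axes=(0, 1)), vol.grid)
            assert compute_cbv(rot) == base


class TestSkeleton:
    def test_straight_tube_single_branch(self):
        vol, _ = make_cylinder(n=40, radius_vox=3.0)
        graph = skeletonize_and_label(vol)
        assert graph.n_branches == 1
        assert graph.points.shape[0] == pytest.approx(40, abs=6)

    def test_y_junction_gives_three_branches(self):
        from vsdprint.synth import TubeSpec, rasterize_mask

        grid = VoxelGrid((48, 48, 48), 1.0)
        c = (24.0, 24.0, 24.0)
        tubes = [
            TubeSpec((24.0, 24.0, 2.0), c, 3.0),
            TubeSpec(c, (8.0, 24.0, 44.0), 3.0),
            TubeSpec(c, (40.0, 24.0, 44.0), 3.0),
        ]
        vol = BinaryVascularVolume(rasterize_mask(tubes, grid), grid)
        graph = skeletonize_and_label(vol)
        assert graph.n_branches == 3

    def test_skeleton_contained_in_mask(self, rng):
        from vsdprint.synth import generate_network

        grid = VoxelGrid((40, 40, 40), 2.0)
        vol, _ = generate_network(grid, 0.08, {"kind": "uniform", "low": 3, "high": 9}, seed=2)
        graph = skeletonize_and_label(vol)
        assert vol.mask[tuple(graph.points.T)].all()
        assert graph.branch_label.min() >= 1
        # labels contiguous from 1
        assert set(np.unique(graph.branch_label)) == set(range(1, graph.n_branches + 1))

    def test_empty_mask_empty_graph(self):
        grid = VoxelGrid((16, 16, 16), 1.8)
        graph = skeletonize_and_label(BinaryVascularVolume(np.zeros((16, 16, 16), bool), grid))
        assert graph.n_branches == 0
        assert graph.points.shape == (0, 3)


class TestStarline:
    def test_ball_center_radius(self):
        vol, center = make_ball(n=24, radius_vox=5.0)
        r = starline_radius(vol, center.astype(int))
        assert r == pytest.approx(5.0, abs=0.5)

    @pytest.mark.parametrize("direction", [(1, 0, 0), (1, 1, 0.3), (0.2, 1, 0.9)])
    def test_cylinder_axis_radius_vs_distance_transform(self, direction):
        vol, tube = make_cylinder(n=40, radius_vox=4.0, direction=direction)
        # oracle: Euclidean distance transform at the most interior central point
        dt = ndimage.distance_transform_edt(vol.mask)
        central = np.zeros_like(dt)
        central[12:28, 12:28, 12:28] = dt[12:28, 12:28, 12:28]
        p = np.unravel_index(np.argmax(central), dt.shape)
        oracle = dt[p]
        est = starline_radius(vol, np.array(p))
        assert est == pytest.approx(4.0, abs=0.5)
        assert est == pytest.approx(oracle, abs=0.6)

    def test_point_outside_mask_raises(self):
        vol, _ = make_cylinder(n=24, radius_vox=3.0)
        with pytest.raises(ValueError, match="inside"):
            starline_radius(vol, np.array([0, 0, 0]))

    def test_full_mask_capped(self):
        grid = VoxelGrid((16, 16, 16), 1.0)
        vol = BinaryVascularVolume(np.ones((16, 16, 16), bool), grid)
        r = starline_radius(vol, np.array([8, 8, 8]), max_radius_um=50.0)
        # at least half the grid extent (minus the half-voxel boundary crossing)
        assert r >= 7.4


class TestVesselTable:
    def test_single_tube_mean_radius(self):
        vol, _ = make_cylinder(n=40, voxel_size=2.0, radius_vox=4.0)
        graph = skeletonize_and_label(vol)
        table = vessel_table(graph, vol)
        assert len(table) == 1
        assert table.radii[0] == pytest.approx(4.0 * 2.0, abs=0.5 * 2.0)
        assert table.vvf.sum() == pytest.approx(vol.cbv, abs=1e-12)

    def test_two_tubes_vvf_ratio(self):
        from vsdprint.synth import TubeSpec, rasterize_mask

        grid = VoxelGrid((64, 64, 64), 1.0)
        tubes = [
            TubeSpec((-2.0, 16.3, 16.2), (66.0, 16.3, 16.2), 3.0),
            TubeSpec((-2.0, 45.4, 45.3), (66.0, 45.4, 45.3), 8.0),
        ]
        vol = BinaryVascularVolume(rasterize_mask(tubes, grid), grid)
        graph = skeletonize_and_label(vol)
        table = vessel_table(graph, vol)
        assert len(table) == 2
        vvf = np.sort(table.vvf)
        assert vvf[0] / vvf[1] == pytest.approx(9.0 / 64.0, rel=0.15)
        assert table.vvf.sum() == pytest.approx(vol.cbv, abs=1e-12)


class TestVsd:
    def test_single_vessel_delta(self):
        table = VesselTable(
            __import__("pandas").DataFrame({"id": [1], "mean_radius_um": [5.0], "vvf": [0.04]})
        )
        vsd = compute_vsd(table)
        assert vsd.values[5] == 1.0
        assert vsd.values.sum() == 1.0

    def test_hand_computed_histogram(self):
        vsd = vsd_from_radii(np.array([3.4, 3.2, 7.5]), np.array([0.010, 0.020, 0.020]))
        assert vsd.raw_vvf_sums[3] == pytest.approx(0.030)
        assert vsd.raw_vvf_sums[7] == pytest.approx(0.020)
        assert vsd.values[3] == pytest.approx(1.0)
        assert vsd.values[7] == pytest.approx(2.0 / 3.0)
        assert vsd.values.sum() == pytest.approx(1.0 + 2.0 / 3.0)

    def test_normalization_invariant(self, rng):
        for _ in range(20):
            k = rng.integers(1, 12)
            vsd = vsd_from_radii(rng.uniform(0.5, 39.5, k), rng.uniform(1e-4, 0.05, k))
            assert vsd.values.max() == pytest.approx(1.0)
            assert ((vsd.values >= 0) & (vsd.values <= 1)).all()

    def test_empty_table_all_zero(self):
        vsd = vsd_from_radii(np.empty(0), np.empty(0))
        assert not vsd.values.any()

    def test_oversize_radius_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            vsd = vsd_from_radii(np.array([45.0]), np.array([0.01]))
        assert vsd.values[39] == 1.0


class TestMeanRadii:
    def test_true_mean_is_unweighted(self):
        import pandas as pd

        table = VesselTable(
            pd.DataFrame({"id": [1, 2, 3], "mean_radius_um": [2.0, 2.0, 8.0], "vvf": [0.3, 0.3, 0.001]})
        )
        assert mean_radius_true(table) == pytest.approx(4.0)

    def test_true_mean_examples_and_empty(self):
        import pandas as pd

        t = VesselTable(pd.DataFrame({"id": [1, 2], "mean_radius_um": [3.0, 5.0], "vvf": [0.1, 0.1]}))
        assert mean_radius_true(t) == pytest.approx(4.0)
        empty = VesselTable(pd.DataFrame({"id": [], "mean_radius_um": [], "vvf": []}))
        with pytest.raises(ValueError):
            mean_radius_true(empty)

    def test_vsd_weighted_mean(self):
        vsd = vsd_from_radii(np.array([5.5]), np.array([0.02]))
        assert mean_radius_from_vsd(vsd) == pytest.approx(5.5)
        vsd2 = vsd_from_radii(np.array([3.4, 7.5]), np.array([0.030, 0.020]))
        assert mean_radius_from_vsd(vsd2) == pytest.approx(5.10, abs=0.01)

    def test_uniform_histogram_mean_is_center(self):
        from vsdprint.morphometry import VSDHistogram

        vsd = VSDHistogram(values=np.ones(40), raw_vvf_sums=np.ones(40))
        assert mean_radius_from_vsd(vsd) == pytest.approx(20.0)
        zero = VSDHistogram(values=np.zeros(40), raw_vvf_sums=np.zeros(40))
        with pytest.raises(ValueError):
            mean_radius_from_vsd(zero)


def test_starline_unbiased_across_radii_and_orientations():
    """Mean star-line radius over axis points within ±0.5 voxel of nominal."""
    rng = np.random.default_rng(3)
    for radius_vox in (2, 5, 9, 11):
        for _ in range(2):
            d = rng.standard_normal(3)
            d /= np.linalg.norm(d)
            vol, _ = make_cylinder(n=40, radius_vox=float(radius_vox), direction=d)
            dt = ndimage.distance_transform_edt(vol.mask)
            central = np.zeros_like(dt)
            central[12:28, 12:28, 12:28] = dt[12:28, 12:28, 12:28]
            pts = np.argwhere(central >= central.max() - 0.5)[:40]  # near-axis, interior
            est = starline_radii(vol, pts).mean()
            assert est == pytest.approx(radius_vox, abs=0.5), (radius_vox, d)
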