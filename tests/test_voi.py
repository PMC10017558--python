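import numpy as np
import pytest

from pcatcalib.centerline import Centerline
from pcatcalib.grid import CTVolume, GridGeometry
from pcatcalib.phantom import generate_phantom
from pcatcalib.voi import (
    LumenSegmentationError,
    TubeVOI,
    VOIError,
    build_tube_voi,
    estimate_diameter,
    segment_lumen,
    transfer_voi,
)

from _bruteforce import brute_tube_voi


def random_case(rng, max_side=32):
    """Random small grid + polyline inside it + diameter."""
    shape = tuple(int(s) for s in rng.integers(8, max_side + 1, size=3))
    spacing = tuple(float(s) for s in rng.uniform(0.4, 1.2, size=3))
    origin = tuple(float(o) for o in rng.uniform(-5.0, 5.0, size=3))
    extent = np.array(shape) * np.array(spacing)
    n_pts = int(rng.integers(2, 6))
    pts = np.array(origin) + rng.uniform(0.15, 0.85, size=(n_pts, 3)) * extent
    grid = GridGeometry(shape=shape, spacing=spacing, origin=origin)
    diameter = float(rng.uniform(0.6, 3.0))
    return grid, Centerline(points=pts), diameter


class TestSegmentLumen:
    def test_recovers_ground_truth_lumen(self, zero_noise_series, straight_centerline):
        ph = zero_noise_series[(120, "IR")]
        mask = segment_lumen(ph.volume, straight_centerline, 200.0)
        truth = ph.mask("lumen")
        dice = 2 * (mask & truth).sum() / (mask.sum() + truth.sum())
        assert dice >= 0.95

    def test_threshold_above_lumen_hu_errors(self, zero_noise_series, straight_centerline):
        ph = zero_noise_series[(120, "IR")]
        with pytest.raises(LumenSegmentationError, match="contrast"):
            segment_lumen(ph.volume, straight_centerline, 600.0)

    def test_second_vessel_not_picked_up(self):
        """Two bright vessels; the mask must only contain the traced one."""
        grid = GridGeometry(shape=(40, 24, 30), spacing=(0.5, 0.5, 0.5))
        x, y, z = grid.voxel_centers()
        data = np.full(grid.shape, -75.0)
        data[np.hypot(x - 4.0, y - 6.0) <= 1.5] = 400.0
        data[np.hypot(x - 14.0, y - 6.0) <= 1.5] = 400.0
        vol = CTVolume(data, grid)
        cl = Centerline(points=[[4.0, 6.0, 2.0], [4.0, 6.0, 12.0]])
        mask = segment_lumen(vol, cl, 200.0)
        other = np.hypot(x - 14.0, y - 6.0) <= 1.5
        assert mask.any()
        assert not (mask & other).any()


class TestEstimateDiameter:
    def test_cylinder_radius_recovered(self, iso_cylinder_spec, iso_cylinder_phantom):
        cl = Centerline(points=iso_cylinder_spec.vessel_path)
        d = estimate_diameter(
            iso_cylinder_phantom.mask("lumen"), cl, iso_cylinder_spec.grid
        )
        assert d == pytest.approx(3.0, abs=0.2)

    @pytest.mark.parametrize("radius", [1.0, 1.5, 2.0, 3.0])
    def test_radius_sweep_within_voxel_tolerance(self, radius):
        grid = GridGeometry(shape=(36, 36, 80), spacing=(0.5, 0.5, 0.5))
        x, y, _ = grid.voxel_centers()
        mask = np.hypot(x - 8.93, y - 9.07) <= radius
        cl = Centerline(points=[[8.93, 9.07, 2.0], [8.93, 9.07, 38.0]])
        d = estimate_diameter(mask, cl, grid)
        assert d == pytest.approx(2 * radius, abs=0.5)

    def test_cone_reports_median_station_diameter(self):
        grid = GridGeometry(shape=(36, 36, 90), spacing=(0.5, 0.5, 0.5))
        x, y, z = grid.voxel_centers()
        r_of_z = 1.0 + np.clip((z - 2.0) / 40.0, 0.0, 1.0)  # 1 mm -> 2 mm over 40 mm
        mask = np.hypot(x - 8.93, y - 9.07) <= r_of_z
        mask &= (z >= 2.0) & (z <= 42.0)
        cl = Centerline(points=[[8.93, 9.07, 2.0], [8.93, 9.07, 42.0]])
        d = estimate_diameter(mask, cl, grid)
        assert d == pytest.approx(3.0, abs=0.3)

    def test_single_voxel_mask_errors(self):
        grid = GridGeometry(shape=(20, 20, 40), spacing=(0.5, 0.5, 0.5))
        mask = np.zeros(grid.shape, dtype=bool)
        mask[10, 10, 20] = True
        cl = Centerline(points=[[5.0, 5.0, 2.0], [5.0, 5.0, 18.0]])
        with pytest.raises(VOIError, match="stations|degenerate"):
            estimate_diameter(mask, cl, grid)

    def test_empty_mask_errors(self):
        grid = GridGeometry(shape=(10, 10, 10), spacing=(1, 1, 1))
        cl = Centerline(points=[[5, 5, 1], [5, 5, 9]])
        with pytest.raises(VOIError, match="empty"):
            estimate_diameter(np.zeros(grid.shape, bool), cl, grid)


class TestBuildTubeVOI:
    def test_inclusion_exclusion_at_known_distances(self):
        """diameter 2 mm, 1 mm voxels: in at 2.5 mm, out at 3.5 mm, vessel at 0.5 mm."""
        grid = GridGeometry(shape=(11, 11, 12), spacing=(1.0, 1.0, 1.0))
        cl = Centerline(points=[[5.5, 5.0, 1.0], [5.5, 5.0, 10.0]])
        voi = build_tube_voi(cl, 2.0, None, grid)
        got = voi.as_set()
        assert (8, 5, 5) in got  # |8 - 5.5| = 2.5 in (1, 3]
        assert (9, 5, 5) not in got  # 3.5 > 3
        assert (5, 5, 5) not in got  # 0.5 <= 1: vessel
        assert (5, 5, 5) in set(map(tuple, voi.lumen_indices))

    def test_nonpositive_diameter_rejected(self):
        grid = GridGeometry(shape=(10, 10, 10), spacing=(1, 1, 1))
        cl = Centerline(points=[[5, 5, 1], [5, 5, 9]])
        with pytest.raises(VOIError):
            build_tube_voi(cl, 0.0, None, grid)

    def test_deterministic_index_sets(self):
        rng = np.random.default_rng(11)
        grid, cl, d = random_case(rng)
        a = build_tube_voi(cl, d, None, grid)
        b = build_tube_voi(cl, d, None, grid)
        assert np.array_equal(a.voxel_indices, b.voxel_indices)
        assert np.array_equal(a.lumen_indices, b.lumen_indices)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng([21, seed])
        grid, cl, d = random_case(rng, max_side=20)
        lumen = rng.random(grid.shape) < 0.02
        try:
            voi = build_tube_voi(cl, d, lumen, grid)
        except VOIError:
            pytest.skip("degenerate random case: empty VOI")
        tube, excluded = brute_tube_voi(cl.points, d, grid, lumen)
        assert voi.as_set() == tube
        assert set(map(tuple, voi.lumen_indices)) == excluded

    def test_shift_equivariance(self):
        rng = np.random.default_rng(33)
        grid, cl, d = random_case(rng, max_side=16)
        shift = np.array([3.7, -1.2, 0.9])
        grid2 = GridGeometry(
            shape=grid.shape,
            spacing=grid.spacing,
            origin=tuple(np.asarray(grid.origin) + shift),
        )
        cl2 = Centerline(points=cl.points + shift)
        a = build_tube_voi(cl, d, None, grid)
        b = build_tube_voi(cl2, d, None, grid2)
        assert a.as_set() == b.as_set()

    def test_nesting_in_outer_extent(self):
        """Fixed inner bound: a wider radial margin strictly contains a narrower one."""
        grid = GridGeometry(shape=(24, 24, 24), spacing=(0.8, 0.8, 0.8))
        cl = Centerline(points=[[9.0, 9.0, 3.0], [10.0, 9.5, 16.0]])
        small = build_tube_voi(cl, 1.5, None, grid, inner_offset_mm=1.0)
        big = build_tube_voi(cl, 3.0, None, grid, inner_offset_mm=1.0)
        assert small.as_set() <= big.as_set()

    def test_empty_voi_errors(self):
        grid = GridGeometry(shape=(6, 6, 6), spacing=(10.0, 10.0, 10.0))
        cl = Centerline(points=[[30.0, 30.0, 12.0], [30.0, 30.0, 40.0]])
        with pytest.raises(VOIError, match="empty"):
            build_tube_voi(cl, 0.05, None, grid)


class TestTransfer:
    def test_identity_on_same_grid(self, zero_noise_series, straight_centerline):
        ph = zero_noise_series[(120, "IR")]
        lumen = segment_lumen(ph.volume, straight_centerline, 200.0)
        voi = build_tube_voi(straight_centerline, 3.0, lumen, ph.volume.grid)
        target = zero_noise_series[(80, "FBP")].volume
        out = transfer_voi(voi, target)
        assert np.array_equal(out.voxel_indices, voi.voxel_indices)

    def test_grid_mismatch_errors(self):
        grid = GridGeometry(shape=(12, 12, 12), spacing=(1, 1, 1))
        cl = Centerline(points=[[6, 6, 2], [6, 6, 10]])
        voi = build_tube_voi(cl, 2.0, None, grid)
        other = GridGeometry(shape=(12, 12, 12), spacing=(1, 1, 1.5))
        target = CTVolume(np.zeros(other.shape), other)
        with pytest.raises(VOIError, match="resample|register"):
            transfer_voi(voi, target)

    def test_tiny_origin_jitter_within_tolerance_passes(self):
        grid = GridGeometry(shape=(12, 12, 12), spacing=(1, 1, 1))
        cl = Centerline(points=[[6, 6, 2], [6, 6, 10]])
        voi = build_tube_voi(cl, 2.0, None, grid)
        near = GridGeometry(shape=(12, 12, 12), spacing=(1, 1, 1), origin=(1e-8, 0, 0))
        out = transfer_voi(voi, CTVolume(np.zeros(near.shape), near))
        assert out.size_voxels == voi.size_voxels


class TestTubeVOIInvariants:
    def test_overlapping_sets_rejected(self):
        grid = GridGeometry(shape=(5, 5, 5), spacing=(1, 1, 1))
        with pytest.raises(VOIError, match="overlap"):
            TubeVOI(grid, np.array([[1, 1, 1]]), np.array([[1, 1, 1]]), 2.0)

    def test_out_of_grid_indices_rejected(self):
        grid = GridGeometry(shape=(5, 5, 5), spacing=(1, 1, 1))
        with pytest.raises(VOIError, match="outside"):
            TubeVOI(grid, np.array([[9, 1, 1]]), np.empty((0, 3), int), 2.0)

    def test_empty_voi_rejected(self):
        grid = GridGeometry(shape=(5, 5, 5), spacing=(1, 1, 1))
        with pytest.raises(VOIError, match="empty"):
            TubeVOI(grid, np.empty((0, 3), int), np.empty((0, 3), int), 2.0)
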