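"""Baseline detector tests: threshold, components, size filter, composition."""

import numpy as np
import pytest

import stereobench as sb
from oracles import flood_fill_labels, partition_of

UNIT = (1.0, 1.0, 1.0)


def stack_of(data):
    return sb.ImageStack(np.asarray(data), UNIT)


class TestThreshold:
    def test_inclusive_convention(self):
        stack = stack_of(np.full((2, 2, 2), 7.0))
        assert sb.threshold_stack(stack, 7.0).all()

    def test_above_max_gives_empty_mask(self):
        stack = stack_of(np.full((2, 2, 2), 7.0))
        assert not sb.threshold_stack(stack, 8.0).any()

    def test_two_valued_stack_split_exactly(self):
        rng = np.random.default_rng(0)
        data = rng.choice([10.0, 200.0], size=(4, 5, 6))
        mask = sb.threshold_stack(stack_of(data), 100.0)
        assert np.array_equal(mask, data == 200.0)

    def test_raising_threshold_never_adds_foreground(self):
        rng = np.random.default_rng(1)
        data = rng.integers(0, 255, size=(5, 6, 7))
        stack = stack_of(data)
        counts = [sb.threshold_stack(stack, t).sum() for t in range(0, 260, 16)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestConnectedComponents:
    def test_separated_cubes_get_two_labels(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[1:4, 1:4, 1:4] = True
        mask[6:9, 6:9, 6:9] = True
        for conn in (6, 18, 26):
            assert sb.connected_components_3d(mask, conn).n_labels == 2

    def test_face_sharing_cubes_merge_at_all_connectivities(self):
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[1:4, 1:4, 1:4] = True
        mask[1:4, 1:4, 4:7] = True  # shares a face
        for conn in (6, 18, 26):
            assert sb.connected_components_3d(mask, conn).n_labels == 1

    def test_corner_touch_depends_on_connectivity(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1, 1, 1] = True
        mask[2, 2, 2] = True  # touch only at a corner
        assert sb.connected_components_3d(mask, 26).n_labels == 1
        assert sb.connected_components_3d(mask, 18).n_labels == 2
        assert sb.connected_components_3d(mask, 6).n_labels == 2

    def test_edge_touch_depends_on_connectivity(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1, 1, 1] = True
        mask[1, 2, 2] = True  # share an edge
        assert sb.connected_components_3d(mask, 26).n_labels == 1
        assert sb.connected_components_3d(mask, 18).n_labels == 1
        assert sb.connected_components_3d(mask, 6).n_labels == 2

    @pytest.mark.parametrize("conn", [6, 18, 26])
    def test_partition_matches_flood_fill_oracle(self, conn):
        rng = np.random.default_rng(42)
        for _ in range(8):
            mask = rng.uniform(size=(20, 20, 10)) < 0.35
            vol = sb.connected_components_3d(mask, conn)
            oracle = flood_fill_labels(mask, conn)
            assert partition_of(vol.labels) == partition_of(oracle)

    def test_labels_ordered_by_first_raster_voxel(self):
        mask = np.zeros((3, 5, 5), dtype=bool)
        mask[2, 4, 4] = True   # raster-last voxel
        mask[0, 0, 0] = True   # raster-first voxel
        mask[1, 2, 2] = True
        vol = sb.connected_components_3d(mask, 6)
        assert vol.labels[0, 0, 0] == 1
        assert vol.labels[1, 2, 2] == 2
        assert vol.labels[2, 4, 4] == 3


class TestSizeFilter:
    def _volume_with_sizes(self, sizes):
        total = sum(sizes)
        data = np.zeros((1, 1, total + len(sizes)), dtype=np.int32)
        pos = 0
        for k, size in enumerate(sizes, start=1):
            data[0, 0, pos : pos + size] = k
            pos += size + 1  # gap
        return sb.LabeledVolume(data, UNIT, 26)

    def test_region_below_cutoff_removed(self):
        vol = self._volume_with_sizes([999])
        assert sb.size_filter(vol, 1000).n_labels == 0

    def test_region_at_cutoff_kept(self):
        vol = self._volume_with_sizes([1000])
        out = sb.size_filter(vol, 1000)
        assert out.n_labels == 1
        assert out.sizes[0] == 1000

    def test_zero_cutoff_is_identity(self):
        vol = self._volume_with_sizes([3, 7, 1])
        out = sb.size_filter(vol, 0)
        assert np.array_equal(out.labels, vol.labels)

    def test_survivors_compacted_in_order(self):
        vol = self._volume_with_sizes([2, 9, 1, 5])
        out = sb.size_filter(vol, 4)
        assert out.n_labels == 2
        assert list(out.sizes) == [9, 5]

    def test_voxel_conservation(self):
        rng = np.random.default_rng(7)
        mask = rng.uniform(size=(15, 15, 8)) < 0.3
        vol = sb.connected_components_3d(mask, 26)
        total = vol.labels.size
        for v in (vol, sb.size_filter(vol, 5)):
            background = (v.labels == 0).sum()
            assert v.sizes.sum() + background == total


class TestPhysicalSizeFilter:
    """The published voxel-count filters in physical units."""

    def test_fine_spacing_thousand_voxels(self):
        vol = sb.min_voxels_volume(1000, (0.102134, 0.101507, 0.5))
        assert sb.round_half_away(vol, 1) == 5.2

    def test_coarse_spacing_twentyfive_voxels(self):
        vol = sb.min_voxels_volume(25, (0.46056, 0.46056, 1.0))
        assert sb.round_half_away(vol, 1) == 5.3

    def test_finest_spacing_thousand_voxels(self):
        vol = sb.min_voxels_volume(1000, (0.075173, 0.074300, 0.5))
        assert sb.round_half_away(vol, 1) == 2.8


class TestDetect:
    def test_recovers_well_separated_cells(self, easy_profile, easy_population,
                                           easy_detector, default_noise):
        stack, gt, _ = sb.generate_stack(easy_profile, easy_population,
                                         default_noise, seed=13)
        vol, det = sb.detect(stack, easy_detector)
        assert vol.n_labels == easy_population.n_cells
        assert len(det) == easy_population.n_cells

    def test_empty_stack_gives_no_markers(self, default_noise):
        prof = sb.preset_profile("3A").scaled(64, 64, 8)
        stack, _, _ = sb.generate_stack(prof, sb.CellPopulationSpec(n_cells=0),
                                        default_noise, seed=1)
        vol, det = sb.detect(stack, sb.DetectorParams(threshold=140, min_voxels=50))
        assert vol.n_labels == 0
        assert len(det) == 0

    def test_touching_cells_merge_into_one_region(self):
        """Cells closer than the blur scale under-segment: the known failure."""
        prof = sb.preset_profile("3A").scaled(200, 120, 24)
        dx, dy, dz = prof.spacing
        data = np.zeros(prof.grid_shape)
        centers_um = [(6.0, 6.0, 6.0), (10.2, 6.0, 6.0)]  # 4.2 um apart
        for cx, cy, cz in centers_um:
            zz, yy, xx = np.mgrid[0:prof.n_planes, 0:prof.height, 0:prof.width]
            e = (((xx * dx - cx) / 2.2) ** 2 + ((yy * dy - cy) / 2.2) ** 2
                 + ((zz * dz - cz) / 2.2) ** 2)
            data[e <= 1] = 1.0
        stack = sb.ImageStack(sb.quantize(
            0.08 + 0.9 * sb.gaussian_smooth_3d(
                sb.ImageStack(data, prof.spacing), sb.SmoothingSpec(3, 3, 2)).data),
            prof.spacing)
        vol, det = sb.detect(stack, sb.DetectorParams(threshold=100, min_voxels=100))
        assert vol.n_labels == 1
        assert len(det) == 1

    def test_markers_carry_sizes_and_positions(self, easy_profile, easy_population,
                                               easy_detector, default_noise):
        stack, gt, _ = sb.generate_stack(easy_profile, easy_population,
                                         default_noise, seed=17)
        vol, det = sb.detect(stack, easy_detector)
        assert det.sizes is not None
        assert (det.sizes >= easy_detector.min_voxels).all()
        res = sb.match(gt, det, sb.ToleranceSpec(3.0, 1.5))
        assert res.r_tp == 1.0
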