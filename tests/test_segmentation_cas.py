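import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import ndimage

import bmlquant as bq

from conftest import OFFSETS_8_IN_SLICE, OFFSETS_26, flood_fill_components


def _threshold(value, k=2.0):
    sd = 10.0
    return bq.compute_threshold(bq.ReferenceStats(value - k * sd, sd, 100), k)


def _target(slice_index, r0=-0.5, c0=-0.5, r1=19.5, c1=19.5):
    return bq.RegionSpec(
        f"target{slice_index}",
        "target_femur_medial",
        slice_index,
        [[r0, c0], [r0, c1], [r1, c1], [r1, c0]],
    )


def _grid(intensities):
    return bq.VoxelGrid(intensities, 1.0, 1.0, 4.0, 0.4)


class TestSegmentAboveThreshold:
    def test_strict_inequality_leaves_at_threshold_voxels_out(self):
        grid = _grid(np.full((3, 20, 20), 100.0))
        mask = bq.segment_above_threshold(grid, [_target(1)], _threshold(100.0))
        assert mask.count == 0

    def test_single_supra_threshold_voxel_selected(self):
        data = np.full((3, 20, 20), 100.0)
        data[1, 5, 7] = 260.0
        mask = bq.segment_above_threshold(_grid(data), [_target(1)], _threshold(219.0))
        assert mask.count == 1
        assert mask.flags[1, 5, 7]

    def test_selection_confined_to_target_polygon(self):
        data = np.full((3, 20, 20), 300.0)
        mask = bq.segment_above_threshold(
            _grid(data), [_target(1, -0.5, -0.5, 9.5, 9.5)], _threshold(200.0)
        )
        assert mask.count == 100

    def test_gaussian_upper_tail_fraction(self):
        spec = bq.PhantomSpec(
            shape=(4, 120, 120),
            pixel_spacing_row=1.0,
            pixel_spacing_col=1.0,
            reference_slices=(0,),
            target_slices=(2,),
            target_rect_mm=(5.0, 5.0, 114.0, 114.0),
            seed=21,
        )
        grid, regions, _ = bq.generate_phantom(spec)
        targets = [r for r in regions if r.role == "target_femur_medial"]
        threshold = bq.compute_threshold(bq.ReferenceStats(185.0, 34.0, 100), 2.0)
        mask = bq.segment_above_threshold(grid, targets, threshold)
        n_region = bq.rasterize_union(targets, grid).count
        assert n_region >= 10_000
        fraction = 100.0 * mask.count / n_region
        assert fraction == pytest.approx(2.28, abs=0.5)

    def test_mixed_or_missing_targets_rejected(self):
        grid = _grid(np.full((3, 20, 20), 100.0))
        with pytest.raises(ValueError, match="no target"):
            bq.segment_above_threshold(grid, [], _threshold(100.0))
        ref = bq.RegionSpec("r", "reference_femur", 0, [[0, 0], [0, 5], [5, 5]])
        with pytest.raises(ValueError, match="target role"):
            bq.segment_above_threshold(grid, [ref], _threshold(100.0))

    def test_volume_non_increasing_in_threshold(self, lesion_phantom):
        _, grid, regions, _ = lesion_phantom
        targets = [r for r in regions if r.role == "target_femur_medial"]
        stats = bq.ReferenceStats(185.0, 34.0, 100)
        counts = [
            bq.segment_above_threshold(grid, targets, bq.compute_threshold(stats, k)).count
            for k in (0.5, 1.0, 2.0, 3.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestClusterFilter:
    def test_four_voxel_component_removed_five_kept(self):
        flags = np.zeros((3, 10, 10), dtype=bool)
        flags[1, 2, 2:6] = True  # 4 voxels
        filtered = bq.filter_small_clusters(bq.BinaryMask(flags), min_size=5)
        assert filtered.count == 0
        flags[1, 2, 6] = True  # now 5 voxels
        filtered = bq.filter_small_clusters(bq.BinaryMask(flags), min_size=5)
        assert filtered.count == 5

    def test_empty_mask_unchanged(self):
        mask = bq.BinaryMask(np.zeros((2, 5, 5), dtype=bool))
        assert bq.filter_small_clusters(mask).count == 0

    def test_min_size_below_one_rejected(self):
        mask = bq.BinaryMask(np.zeros((2, 5, 5), dtype=bool))
        with pytest.raises(ValueError):
            bq.filter_small_clusters(mask, min_size=0)

    def test_diagonal_and_cross_slice_adjacency(self):
        flags = np.zeros((3, 5, 5), dtype=bool)
        # a 26-connected diagonal chain through slices; disconnected in-slice
        for i in range(3):
            flags[i, i, i] = True
        vol = bq.filter_small_clusters(
            bq.BinaryMask(flags), min_size=3, connectivity="volumetric_26"
        )
        assert vol.count == 3
        in_slice = bq.filter_small_clusters(
            bq.BinaryMask(flags), min_size=3, connectivity="in_slice_8"
        )
        assert in_slice.count == 0

    @pytest.mark.parametrize(
        "connectivity,offsets",
        [("volumetric_26", OFFSETS_26), ("in_slice_8", OFFSETS_8_IN_SLICE)],
    )
    def test_components_match_flood_fill_oracle(self, connectivity, offsets):
        rng = np.random.default_rng(99)
        shapes = [(3, 3, 3)] * 40 + [(3, 8, 8)] * 20
        structure = bq.segmentation_cas.connectivity_structure(connectivity)
        for shape in shapes:
            flags = rng.random(shape) < 0.4
            _, n = ndimage.label(flags, structure=structure)
            comps = flood_fill_components(flags, offsets)
            assert n == len(comps)
            for min_size in (1, 2, 5):
                filtered = bq.filter_small_clusters(
                    bq.BinaryMask(flags), min_size, connectivity
                )
                expected = set().union(
                    *[c for c in comps if len(c) >= min_size], set()
                )
                assert set(zip(*np.nonzero(filtered.flags))) == expected

    @given(st.integers(0, 2**30))
    def test_filtered_is_subset_and_never_larger(self, seed):
        rng = np.random.default_rng(seed)
        flags = rng.random((3, 8, 8)) < 0.3
        mask = bq.BinaryMask(flags)
        filtered = bq.filter_small_clusters(mask, min_size=5)
        assert filtered.count <= mask.count
        assert not np.any(filtered.flags & ~mask.flags)


class TestQuantify:
    def test_per_slice_areas_and_pitch_volume(self):
        data = np.full((3, 20, 20), 100.0)
        grid = _grid(data)
        targets = [_target(s) for s in range(3)]
        flags = np.zeros((3, 20, 20), dtype=bool)
        flags[0, :10, :10] = True  # 100 mm^2
        flags[1, :5, :10] = True  # 50 mm^2
        quant = bq.quantify(bq.BinaryMask(flags), targets, grid)
        assert quant.per_slice_areas == {0: 100.0, 1: 50.0, 2: 0.0}
        assert quant.total_volume == pytest.approx(150 * 4.4)
        assert sum(quant.per_slice_areas.values()) * grid.slice_pitch == pytest.approx(
            quant.total_volume
        )

    def test_empty_mask_is_zero_percent(self):
        grid = _grid(np.full((3, 20, 20), 100.0))
        quant = bq.quantify(
            bq.BinaryMask(np.zeros((3, 20, 20), bool)), [_target(1)], grid
        )
        assert quant.total_volume == 0.0
        assert quant.relative_percent == 0.0
        assert quant.n_clusters == 0

    def test_mask_outside_targets_rejected(self):
        grid = _grid(np.full((3, 20, 20), 100.0))
        flags = np.zeros((3, 20, 20), bool)
        flags[2, 0, 0] = True
        with pytest.raises(ValueError, match="outside"):
            bq.quantify(bq.BinaryMask(flags), [_target(1)], grid)

    def test_percent_is_pitch_invariant(self):
        flags = np.zeros((3, 20, 20), bool)
        flags[1, :10, :10] = True
        for gap in (0.0, 0.4, 2.0):
            grid = bq.VoxelGrid(np.full((3, 20, 20), 100.0), 1, 1, 4.0, gap)
            quant = bq.quantify(bq.BinaryMask(flags), [_target(1)], grid)
            assert quant.relative_percent == pytest.approx(100 * 100 / 400)


class TestRelativeInvolvement:
    @pytest.mark.parametrize(
        "bml,region,rounded",
        [(357.0, 896.0, 40), (442.0, 686.0, 64), (123.0, 896.0, 14), (0.0, 896.0, 0)],
    )
    def test_worked_examples_round_half_up(self, bml, region, rounded):
        percent = bq.relative_involvement(bml, region)
        assert percent == pytest.approx(100 * bml / region)
        assert bq.round_half_up(percent) == rounded

    def test_half_rounds_up(self):
        assert bq.round_half_up(13.5) == 14
        assert bq.round_half_up(12.4999) == 12

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bq.relative_involvement(10.0, 0.0)
        with pytest.raises(ValueError):
            bq.relative_involvement(10.0, -5.0)
        with pytest.raises(ValueError):
            bq.relative_involvement(20.0, 10.0)
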