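import numpy as np
import pytest

from _oracles import brute_force_max_projection
from conftest import make_volume
from exmorph import (
    PlanarImage,
    ROIPair,
    generate_compartment_image,
    max_project,
    pairs_from_labels,
    patch_area_fraction,
    patch_matrix_ratio,
)


class TestMaxProject:
    def test_single_plane_is_identity(self):
        rng = np.random.default_rng(0)
        plane = rng.uniform(0, 1, (1, 6, 6))
        assert np.array_equal(max_project(make_volume(plane)).data, plane[0])

    def test_two_plane_max(self):
        stack = np.zeros((2, 1, 1))
        stack[0, 0, 0], stack[1, 0, 0] = 3 / 10, 7 / 10
        assert max_project(make_volume(stack)).data[0, 0] == 0.7

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        stack = rng.uniform(0, 1, (5, 8, 8))
        ours = max_project(make_volume(stack)).data
        np.testing.assert_array_equal(ours, brute_force_max_projection(stack))


def _pair(shape, patch_box, matrix_box, pair_id="p"):
    patch = np.zeros(shape, dtype=bool)
    matrix = np.zeros(shape, dtype=bool)
    patch[patch_box] = True
    matrix[matrix_box] = True
    return ROIPair(patch, matrix, pair_id)


class TestPatchMatrixRatio:
    def test_uniform_image_ratio_one(self):
        image = PlanarImage(np.full((10, 10), 7.0))
        pair = _pair((10, 10), np.s_[1:3, 1:3], np.s_[6:8, 6:8])
        result = patch_matrix_ratio(image, [pair])
        assert result.per_pair_ratio == [1.0]
        assert result.mean_ratio == 1.0

    def test_constructed_two_to_one_ratio(self):
        img, patch_labels, matrix_labels, true_ratio = generate_compartment_image(
            shape=(128, 128), n_patches=3, patch_intensity=200, matrix_intensity=100, seed=1
        )
        result = patch_matrix_ratio(img, pairs_from_labels(patch_labels, matrix_labels))
        assert true_ratio == 2.0
        assert result.per_pair_ratio == pytest.approx([2.0] * 3)

    def test_hand_arithmetic_mean_of_pairs(self):
        image_data = np.full((10, 10), 100.0)
        image_data[0:2, 0:2] = 150.0
        image = PlanarImage(image_data)
        pairs = [
            _pair((10, 10), np.s_[0:2, 0:2], np.s_[5:7, 5:7], "a"),  # 150 / 100
            _pair((10, 10), np.s_[8:10, 0:2], np.s_[8:10, 4:6], "b"),  # 100 / 100
        ]
        result = patch_matrix_ratio(image, pairs)
        assert result.per_pair_ratio == pytest.approx([1.5, 1.0])
        assert result.mean_ratio == pytest.approx(1.25)

    def test_zero_matrix_mean_excluded_with_warning(self):
        image = PlanarImage(np.zeros((6, 6)))
        ok = _pair((6, 6), np.s_[0:2, 0:2], np.s_[4:6, 4:6], "z")
        with pytest.warns(UserWarning, match="zero matrix mean"):
            result = patch_matrix_ratio(image, [ok])
        assert result.n_pairs_excluded == 1
        assert np.isnan(result.mean_ratio)

    def test_global_intensity_scaling_invariance(self):
        img, pl, ml, _ = generate_compartment_image(shape=(96, 96), n_patches=2, seed=3, noise_sd=4.0)
        pairs = pairs_from_labels(pl, ml)
        base = patch_matrix_ratio(img, pairs)
        scaled = patch_matrix_ratio(PlanarImage(img.data * 3.7), pairs)
        assert scaled.per_pair_ratio == pytest.approx(base.per_pair_ratio, rel=1e-12)

    def test_mask_swap_inverts_ratio_exactly(self):
        img, pl, ml, _ = generate_compartment_image(shape=(96, 96), n_patches=2, seed=4, noise_sd=4.0)
        fwd = patch_matrix_ratio(img, pairs_from_labels(pl, ml))
        rev = patch_matrix_ratio(img, pairs_from_labels(ml, pl))
        np.testing.assert_allclose(np.array(rev.per_pair_ratio), 1 / np.array(fwd.per_pair_ratio))

    def test_overlapping_masks_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            _pair((6, 6), np.s_[0:3, 0:3], np.s_[2:5, 2:5])

    def test_unpaired_labels_rejected(self):
        patch = np.zeros((6, 6), dtype=np.int32)
        matrix = np.zeros((6, 6), dtype=np.int32)
        patch[0, 0] = 1
        matrix[5, 5] = 2
        with pytest.raises(ValueError, match="unpaired"):
            pairs_from_labels(patch, matrix)


class TestPatchAreaFraction:
    def test_no_patches(self):
        assert patch_area_fraction([], np.ones((10, 10), dtype=bool)) == 0.0

    def test_tiling_patches(self):
        region = np.ones((10, 10), dtype=bool)
        assert patch_area_fraction([region.copy()], region) == 1.0

    def test_overlap_union_arithmetic(self):
        region = np.ones((10, 100), dtype=bool)
        a = np.zeros_like(region)
        b = np.zeros_like(region)
        a[:, 0:10] = True  # 100 px
        b[:, 8:18] = True  # 100 px, 20 px overlap
        assert patch_area_fraction([a, b], region) == pytest.approx(180 / 1000)

    def test_monotone_under_added_patches(self):
        region = np.ones((20, 20), dtype=bool)
        rng = np.random.default_rng(0)
        patches = [rng.uniform(0, 1, (20, 20)) > 0.8 for _ in range(4)]
        fractions = [patch_area_fraction(patches[: k + 1], region) for k in range(4)]
        assert all(b >= a for a, b in zip(fractions, fractions[1:]))

    def test_patch_outside_region_rejected(self):
        region = np.zeros((10, 10), dtype=bool)
        region[:5] = True
        stray = np.zeros_like(region)
        stray[7, 7] = True
        with pytest.raises(ValueError, match="outside"):
            patch_area_fraction([stray], region)
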