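import dataclasses

import numpy as np
import pytest
from scipy import ndimage
from skimage.morphology import skeletonize as sk_skeletonize

from conftest import make_mask
from exmorph import (
    MorphometryResult,
    mean_radius,
    measure,
    skeleton_length_density,
    skeletonize,
    to_tissue_units,
    volume_fraction,
)


def _bar_mask(shape=(64, 64, 100)):
    data = np.zeros(shape, dtype=bool)
    data[30:33, 30:33, :] = True
    return make_mask(data)


def _cylinder(radius, length=60, offset=(0.0, 0.0)):
    side = 2 * radius + 9
    y, x = np.mgrid[:side, :side]
    disk = (y - side // 2 - offset[0]) ** 2 + (x - side // 2 - offset[1]) ** 2 <= radius**2
    return make_mask(np.broadcast_to(disk, (length, side, side)).copy())


class TestVolumeFraction:
    def test_full_mask(self):
        assert volume_fraction(make_mask(np.ones((3, 3, 3)))) == 1.0

    def test_empty_mask(self):
        assert volume_fraction(make_mask(np.zeros((3, 3, 3)))) == 0.0

    def test_bar_count_arithmetic(self):
        assert volume_fraction(_bar_mask()) == 900 / 409600

    def test_spacing_cancels(self, anisotropic_spacing):
        data = np.random.default_rng(0).uniform(0, 1, (5, 5, 5)) > 0.5
        iso = volume_fraction(make_mask(data))
        aniso = volume_fraction(make_mask(data, spacing=anisotropic_spacing))
        assert iso == aniso


class TestSkeletonize:
    def test_single_voxel(self):
        data = np.zeros((5, 5, 5), dtype=bool)
        data[2, 2, 2] = True
        graph = skeletonize(make_mask(data))
        assert graph.n_nodes == 1 and len(graph.edges) == 0

    def test_empty_mask_empty_graph(self):
        graph = skeletonize(make_mask(np.zeros((4, 4, 4))))
        assert graph.n_nodes == 0 and graph.total_length_um == 0.0

    def test_straight_bar_centerline_length(self):
        graph = skeletonize(_bar_mask())
        assert graph.total_length_um == pytest.approx(99, abs=3)

    def test_two_disjoint_bars_two_trees(self):
        data = np.zeros((20, 20, 40), dtype=bool)
        data[4:7, 4:7, 2:38] = True
        data[13:16, 13:16, 2:38] = True
        graph = skeletonize(make_mask(data))
        assert graph.n_components == 2
        # spanning forest: |E| = |V| - #components
        assert len(graph.edges) == graph.n_nodes - 2

    def test_skeleton_subset_of_foreground(self, small_phantom):
        _, _, mask, _ = small_phantom
        graph = skeletonize(mask)
        zyx = graph.nodes
        assert mask.data[zyx[:, 0], zyx[:, 1], zyx[:, 2]].all()

    def test_thinning_idempotent(self, small_phantom):
        _, _, mask, _ = small_phantom
        skel = sk_skeletonize(mask.data)
        again = sk_skeletonize(skel)
        np.testing.assert_array_equal(skel, again)

    def test_edges_join_26_adjacent_voxels(self, small_phantom):
        _, _, mask, _ = small_phantom
        graph = skeletonize(mask)
        diffs = np.abs(graph.nodes[graph.edges[:, 0]] - graph.nodes[graph.edges[:, 1]])
        assert diffs.max() <= 1

    def test_forest_is_acyclic(self, small_phantom):
        _, _, mask, _ = small_phantom
        graph = skeletonize(mask)
        assert len(graph.edges) == graph.n_nodes - graph.n_components


class TestLengthDensity:
    def test_empty_skeleton_zero_density(self):
        mask = make_mask(np.zeros((4, 4, 4)))
        assert skeleton_length_density(skeletonize(mask), mask) == 0.0

    def test_bar_density_arithmetic(self):
        mask = _bar_mask()
        graph = skeletonize(mask)
        density = skeleton_length_density(graph, mask)
        assert density == pytest.approx(99 / 409600, rel=0.04)

    def test_doubling_axons_roughly_doubles_density(self):
        from exmorph import PhantomSpec, generate_axon_phantom

        _, m1, t1 = generate_axon_phantom(PhantomSpec(seed=21, n_axons=5, radius=2.5))
        _, m2, t2 = generate_axon_phantom(PhantomSpec(seed=21, n_axons=10, radius=2.5))
        d1 = skeleton_length_density(skeletonize(m1), m1)
        d2 = skeleton_length_density(skeletonize(m2), m2)
        expected = t2.length_density / t1.length_density
        assert d2 / d1 == pytest.approx(expected, rel=0.10)


class TestMeanRadius:
    def test_isolated_voxel_radius_one(self):
        data = np.zeros((5, 5, 5), dtype=bool)
        data[2, 2, 2] = True
        mask = make_mask(data)
        radius, empty = mean_radius(skeletonize(mask), mask)
        assert radius == pytest.approx(1.0)
        assert not empty

    def test_empty_skeleton_flagged(self):
        mask = make_mask(np.zeros((4, 4, 4)))
        radius, empty = mean_radius(skeletonize(mask), mask)
        assert radius == 0.0 and empty

    def test_cylinder_radius_recovered_on_interior(self):
        mask = _cylinder(4)
        graph = skeletonize(mask)
        edt = ndimage.distance_transform_edt(mask.data)
        interior = (graph.nodes[:, 0] >= 8) & (graph.nodes[:, 0] <= 51)
        zyx = graph.nodes[interior]
        assert edt[zyx[:, 0], zyx[:, 1], zyx[:, 2]].mean() == pytest.approx(4, abs=0.75)

    def test_two_cylinders_length_weighted_mean(self):
        thin = _cylinder(2, length=60)
        thick = _cylinder(6, length=60)
        pad = np.zeros((60, 40, 40), dtype=bool)
        pad[:, 3 : 3 + thin.data.shape[1], 3 : 3 + thin.data.shape[2]] |= thin.data
        pad[:, 17 : 17 + thick.data.shape[1], 17 : 17 + thick.data.shape[2]] |= thick.data
        mask = make_mask(pad)
        radius, _ = mean_radius(skeletonize(mask), mask)
        assert radius == pytest.approx(4, abs=0.75)

    def test_anisotropic_edt_uses_physical_distance(self):
        data = np.zeros((5, 5, 5), dtype=bool)
        data[2, 2, 2] = True
        mask = make_mask(data, spacing=(2.0, 1.0, 1.0))
        radius, _ = mean_radius(skeletonize(mask), mask)
        # nearest background voxel is one lateral step (1 µm), not the 2 µm z step
        assert radius == pytest.approx(1.0)


class TestTissueUnits:
    def _result(self):
        return MorphometryResult(
            volume_fraction=0.05,
            length_density_image=1e-3,
            mean_radius_image=8.0,
        )

    def test_identity_factor(self):
        res = to_tissue_units(self._result(), 1.0)
        assert res.mean_radius_tissue == 8.0
        assert res.length_density_tissue == 1e-3

    def test_radius_divides_by_factor(self):
        assert to_tissue_units(self._result(), 4.0).mean_radius_tissue == pytest.approx(2.0)

    def test_density_scales_by_factor_squared(self):
        assert to_tissue_units(self._result(), 4.0).length_density_tissue == pytest.approx(1.6e-2)

    def test_volume_fraction_unchanged(self):
        assert to_tissue_units(self._result(), 4.25).volume_fraction == 0.05

    @pytest.mark.parametrize("f", [0.0, -2.0])
    def test_nonpositive_factor_rejected(self, f):
        with pytest.raises(ValueError):
            to_tissue_units(self._result(), f)

    def test_roundtrip_f_then_inverse_is_identity(self):
        base = self._result()
        forward = to_tissue_units(base, 4.25)
        back = to_tissue_units(forward, 1 / 4.25)
        # image-space fields survive both conversions bit-exactly
        assert back.mean_radius_image == base.mean_radius_image
        assert back.length_density_image == base.length_density_image
        assert back.volume_fraction == base.volume_fraction
        # and converting with 1/f inverts the tissue-space scaling
        assert back.mean_radius_tissue == pytest.approx(
            forward.mean_radius_tissue * 4.25**2, rel=1e-15
        )


class TestMeasure:
    def test_phantom_recovery(self, small_phantom):
        _, _, mask, truth = small_phantom
        result = measure(mask, expansion_factor=4.25)
        assert result.volume_fraction == truth.volume_fraction
        assert abs(result.mean_radius_image - truth.mean_radius_um) <= 1.0
        assert result.total_skeleton_length_image == pytest.approx(truth.total_length_um, rel=0.10)
        assert result.mean_radius_tissue == pytest.approx(result.mean_radius_image / 4.25)

    def test_empty_mask_flagged_zeros(self):
        result = measure(make_mask(np.zeros((4, 4, 4))))
        assert result.empty
        assert result.volume_fraction == 0.0
        assert result.mean_radius_image == 0.0
        assert result.length_density_image == 0.0

    def test_axis_permutation_invariance(self, small_phantom):
        """Volume fraction is exactly permutation-invariant; the skeleton
        metrics shift only at the percent level (medial-axis thinning visits
        the six directions in a fixed order, so it is not exactly
        equivariant under axis permutation)."""
        _, _, mask, _ = small_phantom
        base = measure(mask)
        for axes in [(1, 2, 0), (2, 0, 1), (0, 2, 1)]:
            permuted = measure(make_mask(np.transpose(mask.data, axes)))
            assert permuted.volume_fraction == base.volume_fraction
            assert permuted.mean_radius_image == pytest.approx(base.mean_radius_image, rel=0.02)
            assert permuted.length_density_image == pytest.approx(base.length_density_image, rel=0.02)

    def test_translation_invariance_within_two_percent(self):
        data = np.zeros((40, 40, 40), dtype=bool)
        y, x = np.mgrid[:11, :11]
        disk = (y - 5) ** 2 + (x - 5) ** 2 <= 9
        data[4:36, 10:21, 10:21] = disk
        base = measure(make_mask(data))
        shifted = measure(make_mask(np.roll(data, (2, 3, -2), axis=(0, 1, 2))))
        assert shifted.volume_fraction == base.volume_fraction
        assert shifted.mean_radius_image == pytest.approx(base.mean_radius_image, rel=0.02)
        assert shifted.length_density_image == pytest.approx(base.length_density_image, rel=0.02)
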