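"""Surface and spot segmentation against generator ground truth and
constructed fixtures."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from nucspat3d import scenes, segmentation as seg
from nucspat3d.classify import object_stats
from nucspat3d.core import ImageStack, LabelVolume
from nucspat3d.segmentation import SpotParams, SurfaceParams
from nucspat3d.scenes import _add_gaussian, _sample_separated, _sphere_mask

from conftest import VOXEL, make_stack

BODY_PARAMS = SurfaceParams(
    threshold_method="absolute", threshold_value=80.0, min_volume=0.005
)


class TestNucleusSurface:
    def test_ellipsoid_volume_recovered(self, interphase_small):
        stack, gt = interphase_small
        nuc = seg.segment_nucleus(stack, "dna")
        vol = list(nuc.volumes().values())[0]
        true = 4.0 / 3.0 * np.pi * np.prod(gt.nucleus_semi_axes)
        assert vol == pytest.approx(true, rel=0.05)
        assert nuc.n_objects == 1

    def test_all_zero_channel_errors(self):
        stack = make_stack([np.zeros((10, 12, 12))], names=["dna"])
        with pytest.raises(ValueError):
            seg.segment_nucleus(stack, "dna")

    def test_two_nuclei_keep_largest(self):
        img = np.zeros((40, 120, 120))
        big = _sphere_mask(img.shape, VOXEL, (2.0, 1.6, 1.6), 1.4)
        small = _sphere_mask(img.shape, VOXEL, (2.0, 4.5, 4.5), 0.8)
        img[big] = 100.0
        img[small] = 100.0
        stack = make_stack([img], names=["dna"])
        nuc = seg.segment_nucleus(stack, "dna", SurfaceParams(keep="largest"))
        assert nuc.n_objects == 1
        com = np.argwhere(nuc.mask).mean(axis=0) * VOXEL
        assert np.linalg.norm(com - [2.0, 1.6, 1.6]) < 0.3  # the larger one

    def test_border_truncated_nucleus_rejected(self):
        img = np.zeros((20, 40, 40))
        img[:5] = 100.0  # slab touching the z border
        stack = make_stack([img], names=["dna"])
        with pytest.raises(ValueError, match="border"):
            seg.segment_nucleus(
                stack, "dna", SurfaceParams(exclude_border=True, fill_holes=False)
            )


class TestNucleolus:
    def test_spherical_void_volume(self):
        stack, gt = scenes.make_interphase_scene(
            seed=4, n_clusters=10, nucleus_semi_axes=(3, 4, 5), nucleolus_radius=1.5
        )
        nuc = seg.segment_nucleus(stack, "dna")
        nucl = seg.segment_nucleolus(stack, "dna", nuc)
        vols = list(nucl.volumes().values())
        assert len(vols) == 1
        assert vols[0] == pytest.approx(4.0 / 3.0 * np.pi * 1.5**3, rel=0.10)

    def test_uniform_nucleus_gives_empty_nucleolus(self):
        img = np.zeros((40, 80, 80))
        img[_sphere_mask(img.shape, VOXEL, (2, 2, 2), 1.5)] = 100.0
        rng = np.random.default_rng(0)
        img = np.clip(img + rng.normal(0, 2, img.shape), 0, None)
        stack = make_stack([img], names=["dna"])
        nuc = seg.segment_nucleus(stack, "dna")
        assert seg.segment_nucleolus(stack, "dna", nuc).n_objects == 0

    def test_cavity_touching_border_excluded(self):
        # a notch open to the outside is not a nucleolus
        img = np.zeros((30, 60, 60))
        ball = _sphere_mask(img.shape, VOXEL, (1.5, 1.5, 1.5), 1.2)
        img[ball] = 100.0
        notch = _sphere_mask(img.shape, VOXEL, (1.5, 1.5, 2.7), 0.5)
        img[notch] = 0.0
        stack = make_stack([img], names=["dna"])
        nuc = LabelVolume(ball.astype(np.int32), VOXEL, "nucleus")
        nucl = seg.segment_nucleolus(
            stack, "dna", nuc, SurfaceParams(threshold_method="absolute", threshold_value=50)
        )
        assert nucl.n_objects == 0


class TestBrightBodies:
    def test_cc_count_and_centers(self, interphase_small):
        stack, gt = interphase_small
        nuc = seg.segment_nucleus(stack, "dna")
        bodies = seg.segment_bright_bodies(stack, "dna", nuc, BODY_PARAMS)
        cc, nano = seg.split_by_volume(bodies, 0.1)
        assert cc.n_objects == len(gt.cc_centers)
        assert nano.n_objects == len(gt.nanocc_centers)
        regions = object_stats(cc, stack)
        det = np.array([r.center_of_mass for r in regions])
        d = cdist(np.array(gt.cc_centers), det)
        assert d.min(axis=1).max() < np.linalg.norm(VOXEL)  # within one voxel

    def test_threshold_above_max_gives_empty(self, interphase_small):
        stack, _ = interphase_small
        nuc = seg.segment_nucleus(stack, "dna")
        lv = seg.segment_bright_bodies(
            stack, "dna", nuc,
            SurfaceParams(threshold_method="absolute", threshold_value=1e9),
        )
        assert lv.n_objects == 0

    def test_touching_blobs_not_declumped(self):
        img = np.zeros((20, 60, 60))
        img[_sphere_mask(img.shape, VOXEL, (1.0, 1.0, 1.0), 0.4)] = 200.0
        img[_sphere_mask(img.shape, VOXEL, (1.0, 1.0, 1.6), 0.4)] = 200.0  # overlapping
        within = LabelVolume(np.ones(img.shape, np.int32), VOXEL, "nucleus")
        stack = make_stack([img], names=["dna"])
        lv = seg.segment_bright_bodies(
            stack, "dna", within,
            SurfaceParams(threshold_method="absolute", threshold_value=100),
        )
        assert lv.n_objects == 1  # documented behaviour


class TestSplitByVolume:
    def test_partition_exhaustive_disjoint(self, interphase_small):
        stack, _ = interphase_small
        nuc = seg.segment_nucleus(stack, "dna")
        bodies = seg.segment_bright_bodies(stack, "dna", nuc, BODY_PARAMS)
        cc, nano = seg.split_by_volume(bodies, 0.1)
        assert cc.n_objects + nano.n_objects == bodies.n_objects
        assert not (cc.mask & nano.mask).any()
        assert ((cc.mask | nano.mask) == bodies.mask).all()

    @pytest.mark.parametrize("cutoff,expect_large", [(0.0, True), (np.inf, False)])
    def test_degenerate_cutoffs(self, cutoff, expect_large, interphase_small):
        stack, _ = interphase_small
        nuc = seg.segment_nucleus(stack, "dna")
        bodies = seg.segment_bright_bodies(stack, "dna", nuc, BODY_PARAMS)
        cc, nano = seg.split_by_volume(bodies, cutoff)
        if expect_large:
            assert cc.n_objects == bodies.n_objects and nano.n_objects == 0
        else:
            assert nano.n_objects == bodies.n_objects and cc.n_objects == 0

    def test_negative_cutoff_rejected(self, interphase_small):
        stack, _ = interphase_small
        nuc = seg.segment_nucleus(stack, "dna")
        with pytest.raises(ValueError):
            seg.split_by_volume(nuc, -1.0)


class TestMaskChannel:
    def test_full_region_identity_and_empty_region_zero(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 100, (2, 8, 9, 10)).astype(float)
        stack = ImageStack(img, VOXEL, ["a", "b"])
        full = LabelVolume(np.ones((8, 9, 10), np.int32), VOXEL, "nucleus")
        np.testing.assert_array_equal(seg.mask_channel(stack, full).voxels, img)
        empty = LabelVolume(np.zeros((8, 9, 10), np.int32), VOXEL, "nucleus")
        assert seg.mask_channel(stack, empty).voxels.sum() == 0

    def test_in_region_intensity_conserved_exactly(self):
        rng = np.random.default_rng(2)
        img = rng.integers(0, 1000, (1, 10, 11, 12)).astype(float)
        mask = rng.random((10, 11, 12)) > 0.5
        stack = ImageStack(img, VOXEL, ["a"])
        region = LabelVolume(mask.astype(np.int32), VOXEL, "nucleus")
        masked = seg.mask_channel(stack, region)
        assert masked.voxels[0].sum() == img[0][mask].sum()  # integer exact

    def test_shape_mismatch_rejected(self):
        stack = ImageStack(np.zeros((1, 4, 5, 6)), VOXEL, ["a"])
        region = LabelVolume(np.ones((4, 5, 5), np.int32), VOXEL, "nucleus")
        with pytest.raises(ValueError, match="shape"):
            seg.mask_channel(stack, region)


class TestDetectSpots:
    def test_snr5_recall_and_precision(self):
        rng = np.random.default_rng(7)
        shape = tuple(int(6.0 / v) for v in VOXEL)
        img = np.zeros(shape)
        centers = _sample_separated(
            rng, 50, lambda: rng.uniform(0.6, 5.4, 3), lambda p: True, min_sep=0.8
        )
        for c in centers:
            _add_gaussian(img, VOXEL, c, (0.2, 0.12, 0.12), 20.0)
        img = np.clip(img + rng.normal(0, 4.0, shape), 0, None)  # peak SNR 5
        stack = make_stack([img], names=["foci"])
        spots = seg.detect_spots(stack, "foci", SpotParams(seed_diameter=0.4))
        d = cdist(np.array(centers), spots.centers)
        recall = (d.min(axis=1) < 0.2).sum() / 50
        precision = (d.min(axis=0) < 0.2).sum() / len(spots)
        assert recall >= 0.95
        assert precision >= 0.95

    def test_blank_channel_gives_empty_set(self):
        stack = make_stack([np.zeros((20, 30, 30))], names=["c"])
        assert len(seg.detect_spots(stack, "c", SpotParams(seed_diameter=0.3))) == 0

    def test_two_separated_foci_resolved(self):
        img = np.zeros((30, 60, 60))
        for c in [(1.5, 1.5, 1.1), (1.5, 1.5, 1.9)]:  # 2x seed diameter apart
            _add_gaussian(img, VOXEL, c, (0.12, 0.07, 0.07), 100.0)
        stack = make_stack([img], names=["c"])
        spots = seg.detect_spots(stack, "c", SpotParams(seed_diameter=0.4, min_quality=1.0))
        assert len(spots) == 2

    def test_subvoxel_seed_rejected(self):
        stack = make_stack([np.zeros((5, 6, 7))], names=["c"])
        with pytest.raises(ValueError, match="seed_diameter"):
            seg.detect_spots(stack, "c", SpotParams(seed_diameter=0.04))


class TestGrowSpots:
    def test_grown_diameter_matches_fwhm(self):
        img = np.zeros((60, 120, 120))
        sigma = 0.15
        _add_gaussian(img, VOXEL, (3, 3, 3), (sigma,) * 3, 100.0)
        stack = make_stack([img], names=["c"])
        seeds = seg.detect_spots(stack, "c", SpotParams(seed_diameter=0.3, min_quality=1.0))
        grown = seg.grow_spots(
            stack, "c", seeds, SpotParams(seed_diameter=0.3, grow_fraction=0.5, max_diameter=2.0)
        )
        fwhm = 2.0 * np.sqrt(2.0 * np.log(2.0)) * sigma
        assert grown[0].diameter == pytest.approx(fwhm, rel=0.15)

    def test_flat_surroundings_keep_seed_radius(self):
        img = np.full((20, 30, 30), 10.0)
        stack = make_stack([img], names=["c"])
        seeds = seg.detect_spots(stack, "c", SpotParams(seed_diameter=0.3, min_quality=1e9))
        assert len(seeds) == 0  # nothing above quality on a flat field

    def test_two_nearby_foci_get_disjoint_regions(self):
        img = np.zeros((30, 60, 60))
        for c in [(1.5, 1.5, 1.2), (1.5, 1.5, 1.8)]:
            _add_gaussian(img, VOXEL, c, (0.12, 0.08, 0.08), 100.0)
        stack = make_stack([img], names=["c"])
        params = SpotParams(seed_diameter=0.3, grow_fraction=0.3, max_diameter=1.2, min_quality=1.0)
        seeds = seg.detect_spots(stack, "c", params)
        assert len(seeds) == 2
        _, labels = seg.grow_spots(stack, "c", seeds, params, return_labels=True)
        # nearest-peak assignment: regions are disjoint by construction
        r1, r2 = labels == 1, labels == 2
        assert r1.any() and r2.any() and not (r1 & r2).any()
        # total assigned voxels cannot exceed the >= fraction*peak superset
        peak = img.max()
        assert (labels > 0).sum() <= (img >= 0.3 * peak * 0.9).sum() + 2


class TestIterativeCapture:
    def test_single_dominant_focus_captured_first_iteration(self):
        img = np.full((30, 60, 60), 1.0)
        _add_gaussian(img, VOXEL, (1.5, 1.5, 1.5), (0.2, 0.15, 0.15), 20000.0)
        stack = make_stack([img], names=["c"])
        within = LabelVolume(np.ones(img.shape, np.int32), VOXEL, "nucleus")
        total = img.sum()
        focus = img[img > 1.0].sum()
        assert focus / total > 0.9  # constructed fixture
        out = seg.iterative_spot_capture(
            stack, "c", within,
            SpotParams(seed_diameter=0.3, grow_fraction=0.02, max_diameter=2.5,
                       capture_target=0.9, max_iterations=5),
        )
        assert out.metadata["iterations"] == 1
        assert out.metadata["captured_fraction"] >= 0.9

    def test_unreachable_target_terminates_at_max_iterations(self):
        rng = np.random.default_rng(3)
        img = rng.poisson(5.0, (20, 40, 40)).astype(float)
        stack = make_stack([img], names=["c"])
        within = LabelVolume(np.ones(img.shape, np.int32), VOXEL, "nucleus")
        out = seg.iterative_spot_capture(
            stack, "c", within,
            SpotParams(seed_diameter=0.3, capture_target=1.0, max_iterations=3),
        )
        assert out.metadata["iterations"] <= 3
        assert out.metadata["captured_fraction"] < 1.0

    def test_invalid_capture_target_rejected(self):
        stack = make_stack([np.ones((5, 6, 7))], names=["c"])
        within = LabelVolume(np.ones((5, 6, 7), np.int32), VOXEL, "nucleus")
        with pytest.raises(ValueError, match="capture_target"):
            seg.iterative_spot_capture(
                stack, "c", within, SpotParams(capture_target=1.5)
            )


class TestCropRoi:
    def test_full_box_identity(self, interphase_small):
        stack, _ = interphase_small
        ext = [(0.0, s * v) for s, v in zip(stack.shape, stack.voxel_size)]
        out = seg.crop_roi(stack, ext)
        np.testing.assert_array_equal(out.voxels, stack.voxels)
        assert out.origin == stack.origin

    def test_absolute_coordinates_preserved(self):
        img = np.zeros((40, 80, 80))
        true_center = (2.0, 2.0, 2.0)
        _add_gaussian(img, VOXEL, true_center, (0.12, 0.08, 0.08), 200.0)
        stack = make_stack([img], names=["c"])
        params = SpotParams(seed_diameter=0.3, min_quality=1.0)
        before = seg.detect_spots(stack, "c", params).centers[0]
        cropped = seg.crop_roi(stack, [(1.0, 3.2), (0.8, 3.1), (0.9, 3.0)])
        assert cropped.shape[0] < stack.shape[0]
        after = seg.detect_spots(cropped, "c", params).centers[0]
        assert np.allclose(before, after, atol=1e-9)  # absolute µm unchanged

    def test_box_outside_image_rejected(self, interphase_small):
        stack, _ = interphase_small
        with pytest.raises(ValueError, match="intersect"):
            seg.crop_roi(stack, [(100.0, 101.0), (0.0, 1.0), (0.0, 1.0)])


def test_segmentation_is_deterministic(interphase_small):
    stack, _ = interphase_small
    a = seg.segment_nucleus(stack, "dna")
    b = seg.segment_nucleus(stack, "dna")
    np.testing.assert_array_equal(a.labels, b.labels)
    sa = seg.detect_spots(stack, "rnpii", SpotParams(seed_diameter=0.2), within=a)
    sb = seg.detect_spots(stack, "rnpii", SpotParams(seed_diameter=0.2), within=a)
    np.testing.assert_array_equal(sa.centers, sb.centers)
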