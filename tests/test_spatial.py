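"""Spatial statistics against brute-force oracles and analytic geometry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nucspat3d import spatial
from nucspat3d.core import LabelVolume, Spot, SpotSet
from nucspat3d.scenes import _sphere_mask
from nucspat3d.spatial import (
    DivisionAxes,
    ReferenceFrame,
    axial_classify,
    boundary_voxels,
    center_of_mass,
    division_angle,
    estimate_division_axes,
    knn_mean_distance,
    normalized_radial_position,
    overlap_volume_ratio,
    shortest_cross_distance,
    signed_distance_map,
    signed_distance_to_boundary,
)

VOXEL = (0.1, 0.05, 0.05)


def brute_force_signed_distance(points, mask, voxel_size):
    """Independent oracle: min distance over boundary-voxel centres."""
    bnd = np.argwhere(boundary_voxels(mask))
    bnd_phys = (bnd + 0.5) * voxel_size
    out = []
    for p in np.atleast_2d(points):
        d = np.sqrt(((bnd_phys - p) ** 2).sum(axis=1)).min()
        idx = np.clip(
            np.rint(p / np.asarray(voxel_size) - 0.5).astype(int), 0,
            np.array(mask.shape) - 1,
        )
        out.append(-d if mask[tuple(idx)] else d)
    return np.array(out)


def random_blob(rng, shape=(32, 32, 32)):
    """A random smooth blob mask for oracle comparisons."""
    from scipy import ndimage

    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=4)
    mask = field > np.quantile(field, 0.7)
    # keep the largest component so the mask is a sensible "surface"
    lab, n = ndimage.label(mask)
    if n == 0:
        return random_blob(rng, shape)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, np.arange(1, n + 1))
    return lab == (1 + np.argmax(sizes))


class TestCenterOfMass:
    def test_two_voxel_hand_arithmetic(self):
        lab = np.zeros((1, 1, 3), np.int32)
        lab[0, 0, 0] = lab[0, 0, 2] = 1
        lv = LabelVolume(lab, (0.1, 0.1, 0.1), "nucleus")
        com = center_of_mass(lv)
        assert com[2] == pytest.approx(0.15)  # midpoint of 0.05 and 0.25

    def test_sphere_center_within_half_voxel(self):
        shape = (40, 80, 80)
        mask = _sphere_mask(shape, VOXEL, (2, 2, 2), 1.2)
        lv = LabelVolume(mask.astype(np.int32), VOXEL, "nucleus")
        assert np.allclose(center_of_mass(lv), (2, 2, 2), atol=max(VOXEL) / 2)

    def test_constant_weight_equals_binary(self):
        rng = np.random.default_rng(0)
        mask = random_blob(rng)
        lv = LabelVolume(mask.astype(np.int32), VOXEL, "nucleus")
        w = np.full(mask.shape, 7.0)
        assert np.allclose(center_of_mass(lv), center_of_mass(lv, weight=w))

    def test_empty_region_rejected(self):
        lv = LabelVolume(np.zeros((3, 3, 3), np.int32), VOXEL, "nucleus")
        with pytest.raises(ValueError):
            center_of_mass(lv)


class TestSignedDistance:
    def test_sphere_center_depth(self):
        shape = (90, 180, 180)
        R = 4.0
        mask = _sphere_mask(shape, VOXEL, (4.5, 4.5, 4.5), R)
        lv = LabelVolume(mask.astype(np.int32), VOXEL, "nucleus")
        d = signed_distance_to_boundary(np.array([[4.5, 4.5, 4.5]]), lv)[0]
        assert d == pytest.approx(-R, abs=np.linalg.norm(VOXEL))

    def test_boundary_voxel_distance_zero(self):
        mask = np.zeros((9, 9, 9), bool)
        mask[2:7, 2:7, 2:7] = True
        lv = LabelVolume(mask.astype(np.int32), (0.1, 0.1, 0.1), "nucleus")
        p = (np.array([2, 4, 4]) + 0.5) * 0.1  # centre of a boundary voxel
        assert signed_distance_to_boundary(p, lv)[0] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_random_blobs(self, seed):
        rng = np.random.default_rng(seed)
        mask = random_blob(rng)
        lv = LabelVolume(mask.astype(np.int32), VOXEL, "nucleus")
        pts = rng.uniform(0.1, 1.4, size=(50, 3)) * np.array(mask.shape) * VOXEL / 1.6
        ours = signed_distance_to_boundary(pts, lv)
        oracle = brute_force_signed_distance(pts, mask, VOXEL)
        assert np.max(np.abs(ours - oracle)) <= 1e-9

    def test_map_agrees_with_point_queries(self):
        rng = np.random.default_rng(3)
        mask = random_blob(rng)
        lv = LabelVolume(mask.astype(np.int32), VOXEL, "nucleus")
        dmap = signed_distance_map(lv)
        idx = rng.integers(0, 32, size=(40, 3))
        pts = (idx + 0.5) * VOXEL
        ours = signed_distance_to_boundary(pts, lv)
        assert np.allclose(dmap[tuple(idx.T)], ours, atol=1e-9)

    def test_antisymmetric_under_complement_within_voxel(self):
        rng = np.random.default_rng(4)
        mask = random_blob(rng)
        inner = mask.copy()
        inner[[0, -1], :, :] = inner[:, [0, -1], :] = inner[:, :, [0, -1]] = False
        lv = LabelVolume(inner.astype(np.int32), VOXEL, "nucleus")
        lv_c = LabelVolume((~inner).astype(np.int32), VOXEL, "nucleus")
        pts = rng.uniform(0.3, 1.2, size=(30, 3))
        d = signed_distance_to_boundary(pts, lv)
        dc = signed_distance_to_boundary(pts, lv_c)
        # boundary voxel sets differ by one voxel shell
        assert np.max(np.abs(d + dc)) <= np.linalg.norm(VOXEL) + 1e-9


class TestNormalizedRadialPosition:
    def test_com_maps_to_minus_one_and_boundary_to_zero(self):
        shape = (60, 120, 120)
        mask = _sphere_mask(shape, VOXEL, (3, 3, 3), 2.0)
        lv = LabelVolume(mask.astype(np.int32), VOXEL, "nucleus")
        com = center_of_mass(lv)
        assert normalized_radial_position(np.array([com]), lv)[0] == pytest.approx(-1.0, abs=0.05)
        bnd = (np.argwhere(boundary_voxels(mask))[0] + 0.5) * VOXEL
        assert normalized_radial_position(np.array([bnd]), lv)[0] == pytest.approx(0.0, abs=1e-9)

    def test_mid_depth_point_in_sphere(self):
        shape = (60, 120, 120)
        mask = _sphere_mask(shape, VOXEL, (3, 3, 3), 2.0)
        lv = LabelVolume(mask.astype(np.int32), VOXEL, "nucleus")
        p = np.array([[3.0, 3.0, 4.0]])  # half-depth: 1 µm inside a 2 µm sphere
        assert normalized_radial_position(p, lv)[0] == pytest.approx(-0.5, abs=0.05)

    def test_degenerate_thin_surface_rejected(self):
        mask = np.zeros((5, 9, 9), bool)
        mask[2, :, :] = True  # one-voxel sheet: com lies on the boundary
        lv = LabelVolume(mask.astype(np.int32), (0.1, 0.1, 0.1), "nucleus")
        with pytest.raises(ValueError, match="degenerate"):
            normalized_radial_position(np.array([[0.25, 0.45, 0.45]]), lv)


class TestAxialClassify:
    @pytest.mark.parametrize(
        "z,expected",
        [(1.5, "middle"), (2.0, "middle"), (-2.0, "middle"), (2.01, "top"), (-3.0, "bottom")],
    )
    def test_band_membership_inclusive(self, z, expected):
        frame = ReferenceFrame(origin=(5.0, 5.0, 5.0))
        spots = SpotSet([Spot(center=(5.0 + z, 5.0, 5.0), radius=0.1)])
        axial_classify(spots, frame, half_width=2.0)
        assert spots[0].class_labels["axial"] == expected


class TestPointDistances:
    def test_shortest_cross_arithmetic(self):
        a = np.array([[0.0, 0.0, 0.0]])
        b = np.array([[0.0, 0.0, 3.0], [0.0, 4.0, 0.0]])
        assert shortest_cross_distance(a, b)[0] == pytest.approx(3.0)

    def test_identical_coordinates_give_zero(self):
        a = np.array([[1.0, 2.0, 3.0]])
        assert shortest_cross_distance(a, a.copy())[0] == 0.0

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            shortest_cross_distance(np.zeros((1, 3)), np.zeros((0, 3)))

    def test_cross_distance_matches_double_loop(self):
        rng = np.random.default_rng(5)
        a, b = rng.uniform(0, 10, (100, 3)), rng.uniform(0, 10, (80, 3))
        oracle = np.array([min(np.linalg.norm(p - q) for q in b) for p in a])
        assert np.array_equal(shortest_cross_distance(a, b), oracle) or np.allclose(
            shortest_cross_distance(a, b), oracle, atol=1e-12
        )

    def test_knn_collinear_hand_arithmetic(self):
        pts = np.array([[0, 0, 0], [0, 0, 1], [0, 0, 2]], float)
        means, flagged = knn_mean_distance(pts, k=2)
        assert means == pytest.approx([1.5, 1.0, 1.5])
        assert not flagged.any()

    def test_knn_fewer_neighbors_flags_rows(self):
        pts = np.array([[0, 0, 0], [0, 0, 1], [0, 0, 3]], float)
        means, flagged = knn_mean_distance(pts, k=5)
        # with k > n-1 every row uses all pairwise distances and is flagged
        assert means[0] == pytest.approx((1 + 3) / 2)
        assert flagged.all()

    def test_knn_matches_brute_force_sort(self):
        rng = np.random.default_rng(6)
        pts = rng.uniform(0, 5, (200, 3))
        means, _ = knn_mean_distance(pts, k=5)
        for i in [0, 17, 99, 199]:
            d = np.sort([np.linalg.norm(pts[i] - q) for j, q in enumerate(pts) if j != i])
            assert means[i] == pytest.approx(d[:5].mean(), abs=1e-12)

    def test_singleton_rejected(self):
        with pytest.raises(ValueError):
            knn_mean_distance(np.zeros((1, 3)), k=5)


class TestOverlap:
    def test_identity_disjoint_and_half_shift(self):
        a = np.zeros((10, 10, 10), bool)
        a[2:6, 2:6, 2:6] = True
        assert overlap_volume_ratio(a, a) == 1.0
        b = np.zeros_like(a)
        b[7:9, 7:9, 7:9] = True
        assert overlap_volume_ratio(a, b) == 0.0
        half = np.roll(a, 2, axis=2)  # shift by half the cube edge
        assert overlap_volume_ratio(a, half) == pytest.approx(0.5)

    def test_shared_intersection_identity(self):
        rng = np.random.default_rng(7)
        a = rng.random((8, 8, 8)) > 0.6
        b = rng.random((8, 8, 8)) > 0.4
        assert overlap_volume_ratio(a, b) * a.sum() == pytest.approx(
            overlap_volume_ratio(b, a) * b.sum()
        )

    def test_empty_object_rejected(self):
        with pytest.raises(ValueError):
            overlap_volume_ratio(np.zeros((3, 3, 3), bool), np.ones((3, 3, 3), bool))


class TestDivisionAngle:
    def axes(self, u, v):
        B = (0.0, 0.0, 0.0)
        return DivisionAxes(A=tuple(v), A_prime=tuple(u), B=B, C=(0.0, 0.0, 1.0))

    def test_parallel_and_orthogonal(self):
        assert division_angle(self.axes((0, 1, 0), (0, 2, 0))) == pytest.approx(0.0)
        assert division_angle(self.axes((0, 1, 0), (0, 0, 1))) == pytest.approx(90.0)

    def test_45_degree_analytic(self):
        assert division_angle(self.axes((0, 1, 1), (0, 1, 0))) == pytest.approx(45.0)

    def test_endpoint_swap_invariance(self):
        ax1 = DivisionAxes(A=(1, 2, 3), A_prime=(0, 1, 1), B=(0, 0, 0), C=(1, 0, 0))
        ax2 = DivisionAxes(A=(-1, -2, -3), A_prime=(0, 1, 1), B=(0, 0, 0), C=(1, 0, 0))
        assert division_angle(ax1) == pytest.approx(division_angle(ax2))

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_rotation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        u, v = rng.standard_normal(3), rng.standard_normal(3)
        if np.linalg.norm(u) < 1e-3 or np.linalg.norm(v) < 1e-3:
            return
        base = division_angle(self.axes(u, v))
        # random rotation via QR
        q, r = np.linalg.qr(rng.standard_normal((3, 3)))
        q *= np.sign(np.diag(r))
        rot = division_angle(self.axes(q @ u, q @ v))
        assert rot == pytest.approx(base, abs=1e-6)
        assert 0.0 <= base <= 90.0

    def test_zero_length_line_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            DivisionAxes(A=(0, 0, 0), A_prime=(1, 1, 1), B=(0, 0, 0), C=(1, 0, 0))


class TestEstimateAxes:
    def test_plates_along_principal_axis_give_zero_angle(self):
        shape = (40, 120, 40)
        cell = np.zeros(shape, bool)
        cell[10:30, 10:110, 10:30] = True  # elongated along y
        plates = np.zeros(shape, np.int32)
        plates[18:22, 40:44, 18:22] = 1
        plates[18:22, 76:80, 18:22] = 2
        axes = estimate_division_axes(
            LabelVolume(plates, VOXEL, "chromosome"),
            LabelVolume(cell.astype(np.int32), VOXEL, "cell"),
        )
        assert division_angle(axes, ("pulling", "elongation")) == pytest.approx(0.0, abs=1.0)

    def test_spherical_cell_is_ill_conditioned(self):
        shape = (60, 120, 120)
        cell = _sphere_mask(shape, VOXEL, (3, 3, 3), 2.0)
        plates = np.zeros(shape, np.int32)
        plates[28:32, 50:54, 58:62] = 1
        plates[28:32, 66:70, 58:62] = 2
        with pytest.raises(ValueError, match="ill-conditioned"):
            estimate_division_axes(
                LabelVolume(plates, VOXEL, "chromosome"),
                LabelVolume(cell.astype(np.int32), VOXEL, "cell"),
            )

    def test_wrong_plate_count_instructs_manual_entry(self):
        shape = (20, 40, 40)
        cell = np.zeros(shape, bool)
        cell[5:15, 5:35, 5:15] = True
        plates = np.zeros(shape, np.int32)
        plates[8:10, 8:10, 8:10] = 1
        with pytest.raises(ValueError, match="manual"):
            estimate_division_axes(
                LabelVolume(plates, VOXEL, "chromosome"),
                LabelVolume(cell.astype(np.int32), VOXEL, "cell"),
            )


class TestReferenceFrame:
    def test_axes_must_be_orthonormal_right_handed(self):
        with pytest.raises(ValueError):
            ReferenceFrame((0, 0, 0), axes=np.array([[1, 0, 0], [0, 2, 0], [0, 0, 1]]))
        left = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError, match="right-handed"):
            ReferenceFrame((0, 0, 0), axes=left)

    def test_local_coordinates(self):
        frame = ReferenceFrame((1.0, 2.0, 3.0))
        local = frame.to_local(np.array([[2.0, 2.0, 3.0]]))
        assert np.allclose(local, [[1.0, 0.0, 0.0]])
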