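"""Reference frames, signed distances, neighbour statistics, overlaps and
division-angle geometry.

Distance conventions
--------------------
The boundary of a mask is its set of foreground voxels adjacent (6-neighbour)
to background; distances are measured to the centres of these boundary
voxels, weighted by the anisotropic voxel size.  Signed distance is negative
inside the mask, positive outside and 0 on boundary voxels — interior
structures therefore plot at negative distance-to-periphery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .core import LabelVolume, RegionObject, Spot, SpotSet, index_to_phys, phys_to_index

__all__ = [
    "ReferenceFrame",
    "DivisionAxes",
    "center_of_mass",
    "boundary_voxels",
    "signed_distance_to_boundary",
    "signed_distance_map",
    "normalized_radial_position",
    "axial_classify",
    "shortest_cross_distance",
    "knn_mean_distance",
    "overlap_volume_ratio",
    "pair_by_overlap",
    "division_angle",
    "estimate_division_axes",
]


@dataclass
class ReferenceFrame:
    """Orthonormal coordinate system anchored at an object's centre of mass.

    ``axes`` rows are the new (z', y', x') directions expressed in image
    (z, y, x) components; default is the image frame itself.
    """

    origin: tuple[float, float, float]
    axes: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.axes = np.asarray(self.axes, float)
        if self.axes.shape != (3, 3):
            raise ValueError("axes must be a 3x3 matrix")
        if not np.allclose(self.axes @ self.axes.T, np.eye(3), atol=1e-9):
            raise ValueError("axes must be orthonormal (1e-9)")
        if np.linalg.det(self.axes) < 0:
            raise ValueError("axes must form a right-handed system")
        self.origin = tuple(float(v) for v in self.origin)

    def to_local(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        return (pts - np.asarray(self.origin)) @ self.axes.T


@dataclass
class DivisionAxes:
    """Measurement points for division-angle geometry.

    A–B is the cell elongation axis, A'–B the chromosome pulling axis and
    B–C a user reference axis (all through the shared point B).
    """

    A: tuple[float, float, float]
    A_prime: tuple[float, float, float]
    B: tuple[float, float, float]
    C: tuple[float, float, float]

    def __post_init__(self):
        b = np.asarray(self.B, float)
        for name in ("A", "A_prime", "C"):
            if np.allclose(np.asarray(getattr(self, name), float), b):
                raise ValueError(f"point B must be distinct from {name}")

    def direction(self, name: str) -> np.ndarray:
        b = np.asarray(self.B, float)
        ends = {
            "elongation": np.asarray(self.A, float),
            "pulling": np.asarray(self.A_prime, float),
            "reference": np.asarray(self.C, float),
        }
        if name not in ends:
            raise KeyError(f"unknown axis {name!r}; use elongation/pulling/reference")
        return ends[name] - b


# ---------------------------------------------------------------------------


def _points_from(obj) -> np.ndarray:
    """Coerce spots / regions / raw arrays to an (n, 3) µm point array."""
    if isinstance(obj, SpotSet):
        return obj.centers
    if isinstance(obj, Spot):
        return np.asarray([obj.center], float)
    if isinstance(obj, RegionObject):
        return np.asarray([obj.center_of_mass], float)
    if isinstance(obj, (list, tuple)) and obj and isinstance(obj[0], RegionObject):
        return np.asarray([o.center_of_mass for o in obj], float)
    pts = np.asarray(obj, float)
    if pts.ndim == 1:
        pts = pts[None]
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must have shape (n, 3)")
    return pts


def center_of_mass(region: LabelVolume, weight: np.ndarray | None = None):
    """Binary or intensity-weighted centroid of a mask in physical µm."""
    mask = region.mask
    if not mask.any():
        raise ValueError("cannot compute centre of mass of an empty region")
    idx = np.argwhere(mask)
    if weight is not None:
        w = np.asarray(weight, float)[mask]
        if w.sum() <= 0:
            raise ValueError("weights sum to zero inside the region")
        com_idx = (idx * w[:, None]).sum(axis=0) / w.sum()
    else:
        com_idx = idx.mean(axis=0)
    return tuple(float(v) for v in index_to_phys(com_idx, region.voxel_size, region.origin))


def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Foreground voxels 6-adjacent to background (image edges count as
    background, so truncated objects have a boundary there)."""
    er = ndimage.binary_erosion(mask, ndimage.generate_binary_structure(3, 1), border_value=0)
    return mask & ~er


def signed_distance_map(surface: LabelVolume) -> np.ndarray:
    """Per-voxel signed distance (µm) to the mask boundary; negative inside."""
    mask = surface.mask
    if not mask.any():
        raise ValueError("surface mask is empty")
    bnd = boundary_voxels(mask)
    dist = ndimage.distance_transform_edt(~bnd, sampling=surface.voxel_size)
    signed = np.where(mask, -dist, dist)
    return signed


def signed_distance_to_boundary(points, surface: LabelVolume) -> np.ndarray:
    """Anisotropy-aware Euclidean distance of points to the mask boundary.

    Negative inside, positive outside, 0 on boundary voxels.  Exact: the
    minimum over boundary-voxel centres (kd-tree), matching a brute-force
    double loop to machine precision.
    """
    pts = _points_from(points)
    mask = surface.mask
    if not mask.any():
        raise ValueError("surface mask is empty")
    bnd_idx = np.argwhere(boundary_voxels(mask))
    bnd_pts = index_to_phys(bnd_idx, surface.voxel_size, surface.origin)
    d, _ = cKDTree(bnd_pts).query(pts, k=1)
    # sign from the containing voxel
    idx = np.rint(phys_to_index(pts, surface.voxel_size, surface.origin)).astype(int)
    inside = np.zeros(len(pts), bool)
    ok = np.all((idx >= 0) & (idx < np.array(mask.shape)), axis=1)
    inside[ok] = mask[tuple(idx[ok].T)]
    return np.where(inside, -d, d)


def normalized_radial_position(points, surface: LabelVolume, com=None) -> np.ndarray:
    """Signed boundary distance normalized by the centre-of-mass depth.

    The centre of mass maps to −1 and the boundary to 0; values beyond −1
    are possible for points deeper than the centre of mass (aspherical
    nuclei).
    """
    if com is None:
        com = center_of_mass(surface)
    d_com = float(signed_distance_to_boundary(np.asarray([com]), surface)[0])
    if abs(d_com) <= min(surface.voxel_size):
        raise ValueError(
            f"degenerate surface: centre of mass lies on the boundary (d={d_com:.4g} µm)"
        )
    return signed_distance_to_boundary(points, surface) / abs(d_com)


def axial_classify(
    spots: SpotSet, frame: ReferenceFrame, half_width: float = 2.0
) -> SpotSet:
    """Classify spots by frame-relative axial (z') position.

    ``middle`` iff −half_width ≤ z' ≤ +half_width (boundaries inclusive),
    ``top`` above, ``bottom`` below.  The ±2 µm default matches the
    equatorial band used for nuclear-envelope clusters.
    """
    if len(spots):
        zloc = frame.to_local(spots.centers)[:, 0]
        for s, z in zip(spots, zloc):
            if z > half_width:
                s.class_labels["axial"] = "top"
            elif z < -half_width:
                s.class_labels["axial"] = "bottom"
            else:
                s.class_labels["axial"] = "middle"
    return spots


def shortest_cross_distance(set_a, set_b) -> np.ndarray:
    """Per-point shortest Euclidean distance from each a in A to the set B."""
    a = _points_from(set_a)
    b = _points_from(set_b)
    if len(b) == 0:
        raise ValueError("set B is empty")
    if len(a) == 0:
        return np.zeros(0)
    return cdist(a, b).min(axis=1)


def knn_mean_distance(spots, k: int = 5):
    """Mean distance of each point to its k nearest same-set neighbours.

    Self is excluded.  If fewer than k neighbours exist all are used and the
    point is flagged, rather than dropped.  Returns ``(means, flagged)``.
    """
    pts = _points_from(spots)
    n = len(pts)
    if n < 2:
        raise ValueError("need at least 2 points for neighbour distances")
    kk = min(k, n - 1)
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=kk + 1)
    means = d[:, 1:].mean(axis=1)
    flagged = np.full(n, n - 1 < k)
    return means, flagged


def _object_mask(vol, label=None) -> np.ndarray:
    if isinstance(vol, LabelVolume):
        return (vol.labels == label) if label is not None else vol.mask
    return np.asarray(vol, bool)


def overlap_volume_ratio(a, b, label_a=None, label_b=None) -> float:
    """Fraction of object a's volume lying inside object b: |a∩b| / |a|."""
    ma = _object_mask(a, label_a)
    mb = _object_mask(b, label_b)
    if ma.shape != mb.shape:
        raise ValueError("masks must share one voxel grid")
    na = int(ma.sum())
    if na == 0:
        raise ValueError("object a is empty")
    return float((ma & mb).sum()) / na


def pair_by_overlap(lv_a: LabelVolume, lv_b: LabelVolume):
    """For each object in a, the b object of maximal overlap and the ratio.

    Returns a list of ``(label_a, label_b_or_None, ratio)``; ratio is the
    fraction of a inside that best-matching b (0 when disjoint from all).
    """
    out = []
    b_labels = lv_b.object_labels()
    for la in lv_a.object_labels():
        ma = lv_a.labels == la
        na = int(ma.sum())
        inter = lv_b.labels[ma]
        best, best_n = None, 0
        for lb in b_labels:
            nb = int((inter == lb).sum())
            if nb > best_n:
                best, best_n = int(lb), nb
        out.append((int(la), best, best_n / na if na else 0.0))
    return out


def division_angle(axes: DivisionAxes, pair=("pulling", "elongation")) -> float:
    """3D angle in degrees between two named axes, folded to [0°, 90°].

    Axes are undirected: swapping a line's endpoints does not change the
    result, nor does a global rotation of all points.
    """
    u = axes.direction(pair[0])
    v = axes.direction(pair[1])
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("zero-length measurement line")
    c = abs(float(np.dot(u, v)) / (nu * nv))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def estimate_division_axes(
    chromosomes: LabelVolume,
    cell: LabelVolume,
    min_axis_ratio: float = 1.2,
) -> DivisionAxes:
    """Automated division axes from anaphase plates and the cell mask.

    The pulling axis runs through the two chromosome-plate centroids; the
    elongation axis is the principal (largest-variance) axis of the cell
    mask; B sits at the midpoint of the plates.  A cell whose two leading
    principal-axis eigenvalues differ by less than ``min_axis_ratio`` has no
    well-defined elongation axis and is rejected.
    """
    cmask = chromosomes.mask
    if chromosomes.n_objects == 2:
        lab = chromosomes.labels
        ids = chromosomes.object_labels()
    else:
        lab, n = ndimage.label(cmask, ndimage.generate_binary_structure(3, 2))
        if n != 2:
            raise ValueError(
                f"expected exactly 2 chromosome plates, found {n}; "
                "supply manual measurement points instead"
            )
        ids = np.array([1, 2])
    cents = []
    for l in ids:
        idx = np.argwhere(lab == l)
        cents.append(index_to_phys(idx.mean(axis=0), chromosomes.voxel_size, chromosomes.origin))
    c1, c2 = np.asarray(cents[0]), np.asarray(cents[1])

    if not cell.mask.any():
        raise ValueError("cell mask is empty")
    idx = np.argwhere(cell.mask)
    pts = index_to_phys(idx, cell.voxel_size, cell.origin)
    centroid = pts.mean(axis=0)
    cov = np.cov((pts - centroid).T)
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] <= 0 or evals[-1] / max(evals[-2], 1e-30) < min_axis_ratio:
        raise ValueError(
            "cell elongation axis ill-conditioned "
            f"(eigenvalue ratio {evals[-1] / max(evals[-2], 1e-30):.3g} < {min_axis_ratio})"
        )
    elong = evecs[:, -1]

    B = (c1 + c2) / 2.0
    scale = float(np.linalg.norm(c1 - c2)) or 1.0
    A = B + elong * scale
    A_prime = c1
    C = B + np.array([1.0, 0.0, 0.0]) * scale  # image z axis as reference
    return DivisionAxes(
        A=tuple(A), A_prime=tuple(A_prime), B=tuple(B), C=tuple(C)
    )
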