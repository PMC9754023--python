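"""Surface and spot segmentation of 3D fluorescence channels.

Surfaces (nucleus, nucleolus, chromocenters, bodies, chromosomes, cell) are
threshold-based connected components; point-like signals are detected as
scale-matched Laplacian-of-Gaussian blobs and optionally expanded to their
local signal extent ("growing spots": fraction-of-peak region growing with
nearest-peak tie breaking).

All thresholds are computed inside the parent mask, never globally, so that
background voxels do not dominate the intensity statistics.  Segmentation is
deterministic: local-maximum ties are broken by lexicographic (z, y, x)
order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu

from .core import ImageStack, LabelVolume, Spot, SpotSet, index_to_phys, phys_to_voxel

__all__ = [
    "SurfaceParams",
    "SpotParams",
    "segment_nucleus",
    "segment_nucleolus",
    "segment_bright_bodies",
    "split_by_volume",
    "mask_channel",
    "detect_spots",
    "grow_spots",
    "iterative_spot_capture",
    "crop_roi",
]


@dataclass
class SurfaceParams:
    """Parameters of threshold-based surface segmentation.

    smoothing_sigma
        Gaussian pre-smoothing in µm; default one finest-axis voxel
        (resolved at call time when None).
    threshold_method
        ``otsu`` (within the parent mask), ``quantile`` (threshold_value is a
        cumulative fraction of in-mask intensities) or ``absolute``.
    min_volume
        Discard components below this µm³.
    fill_holes / keep
        Morphological hole filling; keep the largest component or all.
    """

    smoothing_sigma: float | None = None  # µm
    threshold_method: str = "otsu"
    threshold_value: float | None = None
    min_volume: float = 0.0
    fill_holes: bool = True
    keep: str = "largest"  # or "all"
    closing: bool = True
    exclude_border: bool = False

    def __post_init__(self):
        if self.threshold_method not in ("otsu", "quantile", "absolute"):
            raise ValueError(f"unknown threshold_method {self.threshold_method!r}")
        if self.threshold_method == "quantile":
            if self.threshold_value is None or not 0 < self.threshold_value < 1:
                raise ValueError("quantile threshold_value must be in (0,1)")
        if self.threshold_method == "absolute" and self.threshold_value is None:
            raise ValueError("absolute threshold requires threshold_value")
        if self.min_volume < 0:
            raise ValueError("min_volume must be >= 0")
        if self.keep not in ("largest", "all"):
            raise ValueError("keep must be 'largest' or 'all'")


@dataclass
class SpotParams:
    """Parameters of seeded / adaptive ("growing") spot detection.

    seed_diameter
        Expected object diameter in µm; 0.2 for meiotic foci, 0.3 for FISH
        signals, larger for envelope clusters.
    grow_fraction
        Region-growing cutoff as a fraction of the local peak (0.5 ~ FWHM).
    max_diameter
        Cap on the grown equivalent-sphere diameter, µm.
    min_quality
        Threshold on the scale-normalized LoG response (a.u.); None means
        10 % of the maximum response in the searched region.
    capture_target
        Target fraction of channel intensity for iterative capture.
    """

    seed_diameter: float = 0.2
    adaptive: bool = True
    grow_fraction: float = 0.5
    max_diameter: float = 1.0
    min_quality: float | None = None
    max_iterations: int = 10
    capture_target: float = 0.8

    def __post_init__(self):
        if self.seed_diameter <= 0:
            raise ValueError("seed_diameter must be > 0")
        if not 0 < self.grow_fraction < 1:
            raise ValueError("grow_fraction must be in (0,1)")
        if self.max_diameter < self.seed_diameter:
            raise ValueError("max_diameter must be >= seed_diameter")


# ---------------------------------------------------------------------------
# helpers


def _smooth(channel: np.ndarray, voxel_size, sigma_um: float | None) -> np.ndarray:
    if sigma_um is None:
        sigma_um = min(voxel_size)  # one finest-axis voxel
    if sigma_um <= 0:
        return channel.astype(float)
    sigma_vox = [sigma_um / v for v in voxel_size]
    return ndimage.gaussian_filter(channel.astype(float), sigma=sigma_vox)


def _threshold(values: np.ndarray, params: SurfaceParams) -> float:
    if params.threshold_method == "otsu":
        if values.size == 0 or values.min() == values.max():
            raise ValueError("cannot compute Otsu threshold on constant data")
        return float(threshold_otsu(values))
    if params.threshold_method == "quantile":
        return float(np.quantile(values, params.threshold_value))
    return float(params.threshold_value)


def _label_sorted(binary: np.ndarray, min_voxels: float, connectivity: int = 1):
    """Label connected components, drop small ones, order by falling size.

    Ties in size are broken by the first voxel in (z,y,x) scan order, so the
    labelling is deterministic.
    """
    struct = ndimage.generate_binary_structure(3, connectivity)
    lab, n = ndimage.label(binary, structure=struct)
    if n == 0:
        return np.zeros_like(lab), 0
    idx = np.arange(1, n + 1)
    counts = ndimage.sum_labels(np.ones_like(lab, dtype=np.int64), lab, idx)
    keepers = idx[counts >= max(min_voxels, 1)]
    if keepers.size == 0:
        return np.zeros_like(lab), 0
    order = keepers[np.argsort(-counts[keepers - 1], kind="stable")]
    out = np.zeros_like(lab)
    for new, old in enumerate(order, start=1):
        out[lab == old] = new
    return out, len(order)


def _largest_component(binary: np.ndarray) -> np.ndarray:
    lab, n = _label_sorted(binary, 1)
    return lab == 1


# ---------------------------------------------------------------------------
# surfaces


def segment_nucleus(
    stack: ImageStack,
    dna_channel,
    params: SurfaceParams | None = None,
) -> LabelVolume:
    """Segment one connected nucleus from the DNA channel.

    Gaussian pre-smooth → threshold → fill holes → largest component →
    binary closing.  With ``exclude_border`` nuclei touching the image
    border (truncated in the field of view) are rejected.
    """
    params = params or SurfaceParams()
    ch = stack.channel(dna_channel)
    sm = _smooth(ch, stack.voxel_size, params.smoothing_sigma)
    thr = _threshold(sm.ravel(), params)
    binary = sm > thr
    if not binary.any():
        raise ValueError(f"empty nucleus mask at threshold {thr:.4g}")
    if params.fill_holes:
        binary = ndimage.binary_fill_holes(binary)
    if params.keep == "largest":
        binary = _largest_component(binary)
    if params.exclude_border:  # before closing: closing pads edges with 0
        border = np.zeros_like(binary)
        border[0], border[-1] = True, True
        border[:, 0], border[:, -1] = True, True
        border[:, :, 0], border[:, :, -1] = True, True
        lab, n = _label_sorted(binary, 1)
        keep = np.zeros_like(binary)
        for l in range(1, n + 1):
            comp = lab == l
            if not (comp & border).any():
                keep |= comp
        binary = _largest_component(keep) if keep.any() else keep
        if not binary.any():
            raise ValueError("all nuclei touch the image border (truncated)")
    if params.closing:
        binary = ndimage.binary_closing(binary, iterations=1)
        binary = ndimage.binary_fill_holes(binary)
    min_vox = params.min_volume / np.prod(stack.voxel_size)
    lab, n = _label_sorted(binary, min_vox)
    if n == 0:
        raise ValueError(f"no nucleus above min_volume at threshold {thr:.4g}")
    return LabelVolume(lab.astype(np.int32), stack.voxel_size, "nucleus", stack.origin)


def segment_nucleolus(
    stack: ImageStack,
    dna_channel,
    nucleus: LabelVolume,
    params: SurfaceParams | None = None,
) -> LabelVolume:
    """Segment the nucleolus as the largest low-DNA cavity strictly inside
    the nucleus.

    The default threshold is Otsu computed over in-nucleus intensities
    (which places the cut half-way between cavity and nucleoplasm levels);
    a low quantile of in-nucleus intensities is available instead.  Cavities
    touching the nucleus boundary are excluded.  An empty result is returned
    (not an error) when no cavity reaches ``min_volume``: not every nucleus
    section resolves a nucleolus.
    """
    params = params or SurfaceParams(min_volume=0.25)
    nmask = nucleus.mask
    if not nmask.any():
        raise ValueError("nucleus mask is empty")
    ch = stack.channel(dna_channel)
    sm = _smooth(ch, stack.voxel_size, params.smoothing_sigma)
    if params.threshold_method == "otsu":
        # two-stage Otsu: the first cut splits off bright heterochromatin,
        # the second separates the cavity from the nucleoplasm
        vals = sm[nmask]
        t1 = _threshold(vals, SurfaceParams(threshold_method="otsu"))
        low_vals = vals[vals < t1]
        if low_vals.size and low_vals.min() < low_vals.max():
            thr = _threshold(low_vals, SurfaceParams(threshold_method="otsu"))
        else:
            thr = t1
    elif params.threshold_method == "quantile":
        thr = float(np.quantile(sm[nmask], params.threshold_value))
    else:
        thr = float(params.threshold_value)
    low = (sm < thr) & nmask
    # strictly inside: exclude cavities adjacent to non-nucleus voxels
    rim = ndimage.binary_dilation(~nmask) & nmask
    lab, n = _label_sorted(low, 1)
    voxvol = stack.voxel_volume
    keep = np.zeros_like(low)
    kept = []
    for l in range(1, n + 1):
        comp = lab == l
        if (comp & rim).any():
            continue
        if comp.sum() * voxvol < params.min_volume:
            continue
        kept.append(comp)
    if kept:
        if params.keep == "largest":
            kept = [max(kept, key=lambda c: c.sum())]
        for comp in kept:
            keep |= comp
    out, _ = _label_sorted(keep, 1)
    return LabelVolume(out.astype(np.int32), stack.voxel_size, "nucleolus", stack.origin)


def segment_bright_bodies(
    stack: ImageStack,
    channel,
    within: LabelVolume,
    params: SurfaceParams | None = None,
    object_type: str = "body",
) -> LabelVolume:
    """Segment bright connected regions (chromocenters, speckles, bodies,
    FISH domains) inside a parent mask.

    Components are labelled in order of decreasing volume.  Touching blobs
    are not declumped: they yield a single label (documented behaviour).
    An empty result is allowed.
    """
    params = params or SurfaceParams()
    mask = within.mask
    if not mask.any():
        raise ValueError("parent mask is empty")
    ch = stack.channel(channel)
    sm = _smooth(ch, stack.voxel_size, params.smoothing_sigma)
    vals = sm[mask]
    try:
        thr = _threshold(vals, params)
    except ValueError:
        return LabelVolume(
            np.zeros(stack.shape, np.int32), stack.voxel_size, object_type, stack.origin
        )
    binary = (sm > thr) & mask
    min_vox = params.min_volume / stack.voxel_volume
    lab, _ = _label_sorted(binary, min_vox)
    return LabelVolume(lab.astype(np.int32), stack.voxel_size, object_type, stack.origin)


def split_by_volume(
    bodies: LabelVolume,
    cutoff: float,
    large_type: str = "chromocenter",
    small_type: str = "nanochromocenter",
) -> tuple[LabelVolume, LabelVolume]:
    """Partition labelled bodies by volume: ``>= cutoff`` µm³ go to the
    first (chromocenter) volume, the rest to the second (nanochromocenter).

    The partition is exhaustive and disjoint; relative label order is kept.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    vols = bodies.volumes()
    large = np.zeros_like(bodies.labels)
    small = np.zeros_like(bodies.labels)
    nl = ns = 0
    for lbl in sorted(vols):
        if vols[lbl] >= cutoff:
            nl += 1
            large[bodies.labels == lbl] = nl
        else:
            ns += 1
            small[bodies.labels == lbl] = ns
    mk = lambda arr, t: LabelVolume(arr.astype(np.int32), bodies.voxel_size, t, bodies.origin)
    return mk(large, large_type), mk(small, small_type)


def mask_channel(stack: ImageStack, region: LabelVolume, channels=None) -> ImageStack:
    """Zero all voxels outside ``region``; in-region intensity is conserved
    exactly."""
    if region.labels.shape != stack.shape:
        raise ValueError(
            f"shape mismatch: stack {stack.shape} vs region {region.labels.shape}"
        )
    if channels is None:
        idx = list(range(stack.n_channels))
    else:
        idx = [stack.channel_index(c) for c in channels]
    voxels = stack.voxels[idx].copy()
    voxels[:, ~region.mask] = 0
    return ImageStack(
        voxels=voxels,
        voxel_size=stack.voxel_size,
        channel_names=[stack.channel_names[i] for i in idx],
        image_id=stack.image_id,
        origin=stack.origin,
    )


# ---------------------------------------------------------------------------
# spots


def _log_response(channel: np.ndarray, voxel_size, seed_diameter: float) -> np.ndarray:
    """Scale-normalized (negated) Laplacian of Gaussian matched to the seed.

    For a 3D blob of radius r the matched scale is sigma = r / sqrt(3).
    """
    sigma_um = seed_diameter / 2.0 / np.sqrt(3.0)
    sigma_vox = [max(sigma_um / v, 0.5) for v in voxel_size]
    resp = -ndimage.gaussian_laplace(channel.astype(float), sigma=sigma_vox)
    return resp * float(np.mean(sigma_vox)) ** 2


def _sphere_window(shape, voxel_size, center_idx, radius_um):
    """Slices and in-window ellipsoid mask of a physical sphere."""
    rv = [max(int(np.ceil(radius_um / v)), 1) for v in voxel_size]
    sl = tuple(
        slice(max(c - r, 0), min(c + r + 1, s))
        for c, r, s in zip(center_idx, rv, shape)
    )
    grids = np.meshgrid(
        *[(np.arange(s.start, s.stop) - c) * v for s, c, v in zip(sl, center_idx, voxel_size)],
        indexing="ij",
    )
    dist2 = sum(g**2 for g in grids)
    return sl, dist2 <= radius_um**2


def _measure_sphere(stack: ImageStack, center_um, radius_um):
    """Per-channel mean/sum inside a physical sphere around the centre."""
    cidx = phys_to_voxel(center_um, stack.voxel_size, stack.origin)
    cidx = np.clip(cidx, 0, np.array(stack.shape) - 1)
    sl, inside = _sphere_window(stack.shape, stack.voxel_size, cidx, radius_um)
    out = {}
    for ci, name in enumerate(stack.channel_names):
        vals = stack.voxels[ci][sl][inside]
        out[name] = {
            "mean": float(vals.mean()) if vals.size else 0.0,
            "sum": float(vals.sum()),
        }
    return out


def detect_spots(
    stack: ImageStack,
    channel,
    params: SpotParams | None = None,
    within: LabelVolume | None = None,
    noise_floor: str = "strict",
) -> SpotSet:
    """Detect point-like signals as LoG blobs of fixed seed size.

    Local maxima of the scale-matched LoG response above ``min_quality``
    become spots of radius ``seed_diameter / 2``; candidates closer than one
    seed diameter to a stronger candidate are suppressed.  Intensities are
    measured in-sphere on every channel.

    When ``min_quality`` is None the threshold is automatic: a robust
    (median + 5 MAD) floor, raised under the ``strict`` policy to the
    magnitude of the strongest *negative* response excursion — under
    symmetric noise the negative tail estimates the null, so maxima above
    it are genuine blobs and a noise-only channel yields (almost) nothing.
    ``noise_floor="permissive"`` keeps only the MAD floor, for exhaustive
    signal-coverage passes.
    """
    params = params or SpotParams()
    vs = stack.voxel_size
    if params.seed_diameter < min(vs):
        raise ValueError(
            f"seed_diameter {params.seed_diameter} µm is below one voxel ({min(vs)} µm)"
        )
    if params.seed_diameter < 2 * min(vs):
        warnings.warn("seed_diameter spans fewer than 2 voxels on the finest axis")
    ch = stack.channel(channel)
    mask = within.mask if within is not None else np.ones(stack.shape, bool)
    resp = _log_response(ch, vs, params.seed_diameter)
    if not mask.any():
        return SpotSet(metadata={"channel": str(channel)})
    minq = params.min_quality
    if minq is None:
        # robust noise floor of the response inside the search region
        vals = resp[mask]
        rmax = float(vals.max())
        if rmax <= 0:
            return SpotSet(metadata={"channel": str(channel)})
        med = float(np.median(vals))
        mad = float(np.median(np.abs(vals - med)))
        minq = med + 5.0 * 1.4826 * mad if mad > 0 else 0.1 * rmax
        if noise_floor == "strict":
            # 1.1: intensities are clipped at 0, skewing the noise positive
            minq = max(minq, -1.1 * float(vals.min()))
    fp = tuple(max(3, 2 * int(np.ceil(params.seed_diameter / 2 / v)) + 1) for v in vs)
    local_max = resp == ndimage.maximum_filter(resp, size=fp, mode="nearest")
    cand = np.argwhere(local_max & mask & (resp > minq))
    if cand.size == 0:
        return SpotSet(metadata={"channel": str(channel)})
    qual = resp[tuple(cand.T)]
    # strongest first; ties by (z,y,x) for determinism
    order = np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0], -qual))
    cand, qual = cand[order], qual[order]
    phys = index_to_phys(cand, vs, stack.origin)
    kept: list[int] = []
    min_sep2 = params.seed_diameter**2
    for i in range(len(cand)):
        p = phys[i]
        if all(np.sum((p - phys[j]) ** 2) >= min_sep2 for j in kept):
            kept.append(i)
    if params.min_quality is None and len(kept) >= 3:
        # refine the automatic floor: when candidate qualities are strongly
        # bimodal (true blobs vs residual texture), drop the dim group
        q = qual[kept]
        try:
            split = float(threshold_otsu(q))
        except ValueError:
            split = -np.inf
        hi, lo = q[q > split], q[q <= split]
        if hi.size and lo.size and hi.mean() >= 4.0 * lo.mean():
            kept = [i for i in kept if qual[i] > split]
            minq = max(minq, split)
    spots = []
    for i in kept:
        center = tuple(float(v) for v in phys[i])
        s = Spot(center=center, radius=params.seed_diameter / 2.0, quality=float(qual[i]))
        s.intensity = _measure_sphere(stack, center, s.radius)
        spots.append(s)
    return SpotSet(spots=spots, metadata={"channel": str(channel), "min_quality": float(minq)})


def _grow_regions(
    channel_data: np.ndarray,
    voxel_size,
    origin,
    seeds: SpotSet,
    params: SpotParams,
    within_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Region-grow each seed on voxels >= grow_fraction x its local peak.

    Voxels contested by several seeds go to the nearest peak (physical
    distance); each grown region is the connected component containing its
    peak voxel.  Returns an int32 label array (seed i -> label i+1).
    """
    shape = channel_data.shape
    labels = np.zeros(shape, np.int32)
    if len(seeds) == 0:
        return labels
    vs = np.asarray(voxel_size, float)
    seed_r = params.seed_diameter / 2.0
    max_r = params.max_diameter / 2.0
    # local peak value and position within the seed sphere
    peak_vals = np.empty(len(seeds))
    peak_pos_idx = np.empty((len(seeds), 3), int)
    for i, s in enumerate(seeds):
        cidx = phys_to_voxel(s.center, vs, origin)
        cidx = np.clip(cidx, 0, np.array(shape) - 1)
        sl, inside = _sphere_window(shape, vs, cidx, seed_r)
        win = channel_data[sl]
        masked = np.where(inside, win, -np.inf)
        flat = int(np.argmax(masked))
        off = np.unravel_index(flat, win.shape)
        peak_pos_idx[i] = [s.start + o for s, o in zip(sl, off)]
        peak_vals[i] = win[off]
    peak_phys = index_to_phys(peak_pos_idx, vs, origin)
    tree = cKDTree(peak_phys / 1.0)
    struct = ndimage.generate_binary_structure(3, 1)
    for i in range(len(seeds)):
        thr = params.grow_fraction * peak_vals[i]
        cidx = peak_pos_idx[i]
        sl, inside = _sphere_window(shape, vs, cidx, max_r)
        win = channel_data[sl]
        sel = inside & (win >= thr) & (win > 0)
        if within_mask is not None:
            sel &= within_mask[sl]
        if not sel.any():
            sel = np.zeros_like(sel)
        # nearest-peak assignment for contested voxels
        idx_local = np.argwhere(sel)
        if idx_local.size:
            idx_global = idx_local + [s.start for s in sl]
            pts = index_to_phys(idx_global, vs, origin)
            _, nearest = tree.query(pts, k=1)
            sel[tuple(idx_local.T)] = nearest == i
        # keep the component connected to the peak voxel
        lab, _ = ndimage.label(sel, structure=struct)
        peak_local = tuple(cidx - np.array([s.start for s in sl]))
        comp = lab[peak_local] if sel[peak_local] else 0
        if comp == 0:
            region = np.zeros_like(sel)
            region[peak_local] = True
        else:
            region = lab == comp
        target = labels[sl]
        target[region & (target == 0)] = i + 1
        labels[sl] = target
    return labels


def grow_spots(
    stack: ImageStack,
    channel,
    seeds: SpotSet,
    params: SpotParams | None = None,
    within: LabelVolume | None = None,
    return_labels: bool = False,
):
    """Expand seed spots to their local signal extent.

    Each spot's radius becomes the equivalent-sphere radius of its grown
    region (voxels >= ``grow_fraction`` x local peak, nearest-peak
    assignment), capped at ``max_diameter / 2``.  Intensities are re-measured
    over the grown region.
    """
    params = params or SpotParams()
    ch = stack.channel(channel)
    wmask = within.mask if within is not None else None
    labels = _grow_regions(ch, stack.voxel_size, stack.origin, seeds, params, wmask)
    voxvol = stack.voxel_volume
    grown = []
    for i, s in enumerate(seeds):
        region = labels == i + 1
        n = int(region.sum())
        vol = n * voxvol
        radius = (3.0 * vol / (4.0 * np.pi)) ** (1.0 / 3.0) if n else s.radius
        radius = min(max(radius, s.radius), params.max_diameter / 2.0)
        g = Spot(
            center=s.center,
            radius=float(radius),
            class_labels=dict(s.class_labels),
            quality=s.quality,
            volume=float(vol) if n else None,
        )
        if n:
            g.intensity = {
                name: {
                    "mean": float(stack.voxels[ci][region].mean()),
                    "sum": float(stack.voxels[ci][region].sum()),
                }
                for ci, name in enumerate(stack.channel_names)
            }
        else:
            g.intensity = dict(s.intensity)
        grown.append(g)
    out = SpotSet(spots=grown, metadata=dict(seeds.metadata))
    if return_labels:
        return out, labels
    return out


def iterative_spot_capture(
    stack: ImageStack,
    channel,
    within: LabelVolume,
    params: SpotParams | None = None,
) -> SpotSet:
    """Iterated growing-spot segmentation of a diffuse + clustered signal.

    Repeats (detect on the residual → grow → zero the captured voxels) until
    the captured fraction of in-mask channel intensity reaches
    ``capture_target`` or ``max_iterations`` is hit.  The achieved fraction
    and iteration count are reported in the returned set's metadata.
    """
    params = params or SpotParams()
    if not 0 < params.capture_target <= 1:
        raise ValueError("capture_target must be in (0, 1]")
    mask = within.mask
    ci = stack.channel_index(channel)
    original = stack.channel(channel).astype(float)
    total = float(original[mask].sum())
    all_spots: list[Spot] = []
    captured = np.zeros(stack.shape, bool)
    fraction = 0.0
    iterations = 0
    if total <= 0:
        return SpotSet(metadata={"captured_fraction": 0.0, "iterations": 0})
    residual = original.copy()
    residual[~mask] = 0
    det_params = SpotParams(
        seed_diameter=params.seed_diameter,
        grow_fraction=params.grow_fraction,
        max_diameter=params.max_diameter,
        min_quality=params.min_quality,
        max_iterations=params.max_iterations,
        capture_target=params.capture_target,
    )
    res_stack = ImageStack(
        residual[None], stack.voxel_size, [stack.channel_names[ci]],
        stack.image_id, stack.origin,
    )
    for iterations in range(1, params.max_iterations + 1):
        seeds = detect_spots(res_stack, 0, det_params, within, noise_floor="permissive")
        if len(seeds) == 0:
            iterations -= 1
            break
        grown, labels = grow_spots(res_stack, 0, seeds, det_params, within, return_labels=True)
        new = (labels > 0) & mask & ~captured
        captured |= new
        residual[labels > 0] = 0
        # report intensities of the grown regions from the original image
        for i, g in enumerate(grown):
            region = labels == i + 1
            n = int(region.sum())
            if n:
                vals = original[region]
                g.intensity = {
                    stack.channel_names[ci]: {
                        "mean": float(vals.mean()),
                        "sum": float(vals.sum()),
                    }
                }
            all_spots.append(g)
        fraction = float(original[captured].sum()) / total
        if fraction >= params.capture_target:
            break
    return SpotSet(
        spots=all_spots,
        metadata={
            "captured_fraction": fraction,
            "iterations": iterations,
            "capture_target": params.capture_target,
        },
    )


# ---------------------------------------------------------------------------
# ROI


def crop_roi(stack: ImageStack, box) -> ImageStack:
    """Crop a physical µm bounding box ``((z0,z1),(y0,y1),(x0,x1))``.

    The voxel size is preserved and the origin offset recorded, so absolute
    physical coordinates of objects are unchanged.
    """
    box = [(float(lo), float(hi)) for lo, hi in box]
    slices = []
    new_origin = []
    for (lo, hi), v, o, s in zip(box, stack.voxel_size, stack.origin, stack.shape):
        i0 = int(np.floor((lo - o) / v))
        i1 = int(np.ceil((hi - o) / v))
        i0, i1 = max(i0, 0), min(i1, s)
        if i1 <= i0:
            raise ValueError(f"ROI box {box} does not intersect the image")
        slices.append(slice(i0, i1))
        new_origin.append(o + i0 * v)
    return ImageStack(
        voxels=stack.voxels[(slice(None), *slices)].copy(),
        voxel_size=stack.voxel_size,
        channel_names=list(stack.channel_names),
        image_id=stack.image_id,
        origin=tuple(new_origin),
    )
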