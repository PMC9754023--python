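"""Per-object statistics, normalizations, ratios, classifications and
chromatin compaction density.

Normalization references are always explicit (image mean, parent-surface
mean or channel maximum) and recorded with the result, because fluorescence
intensities are uncalibrated arbitrary units that vary between images.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
from scipy import ndimage

from .core import ImageStack, LabelVolume, RegionObject, SpotSet, index_to_phys, phys_to_voxel
from .spatial import signed_distance_to_boundary, _points_from

__all__ = [
    "QuantileBreaks",
    "ProbeAnnotation",
    "object_stats",
    "normalization_reference",
    "normalize_intensity",
    "intensity_ratio",
    "quantile_classify",
    "inside_outside_classify",
    "filter_spots",
    "distance_bin_classify",
    "compaction_density",
]


@dataclass
class QuantileBreaks:
    """Cumulative top-fraction breaks and the class names they delimit.

    ``breaks=(0.02, 0.04)`` with names ``("T1","T2","T3")`` puts the top 2 %
    of objects (by the ranking statistic) in T1, the next 2 % in T2 and the
    rest in T3.
    """

    breaks: tuple[float, ...] = (0.02, 0.04)
    names: tuple[str, ...] = ("T1", "T2", "T3")

    def __post_init__(self):
        b = tuple(float(x) for x in self.breaks)
        if not all(0 < x < 1 for x in b) or any(b2 <= b1 for b1, b2 in zip(b, b[1:])):
            raise ValueError("breaks must be strictly increasing in (0,1)")
        if len(self.names) != len(b) + 1:
            raise ValueError("need one more class name than breaks")
        self.breaks = b
        self.names = tuple(self.names)


@dataclass
class ProbeAnnotation:
    """A FISH probe painting a genomic span of known size."""

    name: str
    mb: float  # genomic span in Mb
    channel: str | int | None = None

    def __post_init__(self):
        if self.mb <= 0:
            raise ValueError("probe genomic span must be > 0 Mb")


# ---------------------------------------------------------------------------


def object_stats(
    regions: LabelVolume,
    stack: ImageStack,
    weight_channel=None,
) -> list[RegionObject]:
    """Measure volume, centre of mass, bounding box and per-channel
    mean/sum/sd over each labelled object's voxels."""
    if regions.labels.shape != stack.shape:
        raise ValueError("label volume and stack do not share one grid")
    labels = regions.labels
    ids = regions.object_labels()
    if ids.size == 0:
        return []
    voxvol = regions.voxel_volume
    counts = ndimage.sum_labels(np.ones_like(labels, np.int64), labels, ids)
    slices = ndimage.find_objects(labels)
    weight = stack.channel(weight_channel) if weight_channel is not None else None
    out = []
    for j, lbl in enumerate(ids):
        sl = slices[int(lbl) - 1]
        sub = labels[sl] == lbl
        idx = np.argwhere(sub) + [s.start for s in sl]
        if weight is not None:
            w = weight[sl][sub].astype(float)
            com_idx = (idx * w[:, None]).sum(axis=0) / w.sum()
            weighting = str(weight_channel)
        else:
            com_idx = idx.mean(axis=0)
            weighting = "binary"
        com = tuple(float(v) for v in index_to_phys(com_idx, regions.voxel_size, regions.origin))
        lo = index_to_phys(idx.min(axis=0), regions.voxel_size, regions.origin)
        hi = index_to_phys(idx.max(axis=0), regions.voxel_size, regions.origin)
        intensity = {}
        for ci, name in enumerate(stack.channel_names):
            vals = stack.voxels[ci][sl][sub].astype(float)
            intensity[name] = {
                "mean": float(vals.mean()),
                "sum": float(vals.sum()),
                "sd": float(vals.std()),
            }
        out.append(
            RegionObject(
                label=int(lbl),
                object_type=regions.object_type,
                volume=float(counts[j]) * voxvol,
                center_of_mass=com,
                com_weighting=weighting,
                intensity=intensity,
                bounding_box=tuple((float(a), float(b)) for a, b in zip(lo, hi)),
            )
        )
    return out


def normalization_reference(
    stack: ImageStack,
    channel,
    mode: str = "image_mean",
    surface: LabelVolume | None = None,
) -> float:
    """Compute the scalar reference used to normalize intensities.

    ``image_mean``: mean over all voxels of the channel; ``parent_surface_mean``:
    mean inside the given mask; ``channel_max``: channel maximum.
    """
    ch = stack.channel(channel)
    if mode == "image_mean":
        ref = float(ch.mean())
    elif mode == "parent_surface_mean":
        if surface is None:
            raise ValueError("parent_surface_mean requires a surface mask")
        ref = float(ch[surface.mask].mean())
    elif mode == "channel_max":
        ref = float(ch.max())
    else:
        raise ValueError(f"unknown normalization reference {mode!r}")
    if ref <= 0:
        raise ValueError(f"normalization reference is not positive ({ref})")
    return ref


def normalize_intensity(values, reference: float) -> np.ndarray:
    """Divide per-object values by a positive scalar reference."""
    if reference <= 0:
        raise ValueError("normalization reference must be > 0")
    return np.asarray(values, float) / float(reference)


def intensity_ratio(objects, numerator, denominator):
    """Per-object ratio of channel intensity means (e.g. protein : DNA).

    Objects with a zero denominator yield NaN and are flagged, never dropped
    silently.  Returns ``(ratios, flagged)``.
    """
    items = list(objects)
    ratios = np.empty(len(items))
    flagged = np.zeros(len(items), bool)
    for i, obj in enumerate(items):
        num = obj.intensity[str(numerator)]["mean"]
        den = obj.intensity[str(denominator)]["mean"]
        if den <= 0:
            ratios[i] = np.nan
            flagged[i] = True
        else:
            ratios[i] = num / den
    return ratios, flagged


def quantile_classify(values, breaks: QuantileBreaks | None = None) -> list[str]:
    """Top-quantile classification of per-object values.

    Values are ranked descending (stable: ties keep input order); the first
    class takes ``ceil(f1 * n)`` objects, the next ``ceil((f2 - f1) * n)``
    and so on, the last class the remainder.  Class sizes therefore depend
    only on n and the breaks, never on the values.
    """
    breaks = breaks or QuantileBreaks()
    values = np.asarray(values, float)
    n = len(values)
    if n == 0:
        return []
    order = np.argsort(-values, kind="stable")
    classes = [breaks.names[-1]] * n
    prev = 0.0
    start = 0
    for frac, name in zip(breaks.breaks, breaks.names):
        take = min(ceil((frac - prev) * n), n - start)
        for pos in order[start : start + take]:
            classes[pos] = name
        start += take
        prev = frac
    for pos in order[start:]:
        classes[pos] = breaks.names[-1]
    return classes


def inside_outside_classify(spots: SpotSet, surface: LabelVolume) -> SpotSet:
    """Label each spot ``inside`` or ``outside`` a surface by its centre
    voxel (boundary voxels count as inside, matching the sign convention of
    the signed distance)."""
    shape = np.array(surface.labels.shape)
    for s in spots:
        idx = phys_to_voxel(s.center, surface.voxel_size, surface.origin)
        if np.any(idx < 0) or np.any(idx >= shape):
            raise ValueError(f"spot centre {s.center} outside the image")
        s.class_labels["location"] = (
            "inside" if surface.labels[tuple(idx)] > 0 else "outside"
        )
    return spots


def filter_spots(
    spots: SpotSet,
    max_diameter: float | None = None,
    max_boundary_distance: float | None = None,
    surface: LabelVolume | None = None,
) -> SpotSet:
    """Curate spots by size and peripherality.

    Keeps spots with grown equivalent diameter ≤ ``max_diameter`` (boundary
    inclusive: "up to 600 nm" means ≤ 0.6 µm) and with |signed distance to
    the surface| ≤ ``max_boundary_distance`` (drops interior outliers caused
    by surface invaginations).  Removal counts per criterion are recorded in
    the returned set's metadata.
    """
    keep = list(spots.spots)
    removed_size = removed_dist = 0
    if max_diameter is not None:
        kept = [s for s in keep if s.diameter <= max_diameter]
        removed_size = len(keep) - len(kept)
        keep = kept
    if max_boundary_distance is not None:
        if surface is None:
            raise ValueError("peripherality filter requires a surface")
        if keep:
            d = signed_distance_to_boundary(
                np.array([s.center for s in keep]), surface
            )
            kept = [s for s, di in zip(keep, d) if abs(di) <= max_boundary_distance]
            removed_dist = len(keep) - len(kept)
            keep = kept
    meta = dict(spots.metadata)
    meta.update(removed_by_size=removed_size, removed_by_distance=removed_dist)
    return SpotSet(spots=keep, metadata=meta)


def distance_bin_classify(objects, reference: LabelVolume, bin_edges) -> list[str]:
    """Bin objects by shortest distance to the nearest reference object.

    Bins are left-inclusive: ``[0, e0), [e0, e1), ..., [ek, inf)``; an object
    touching or inside a reference region has distance 0 and falls in the
    first bin.
    """
    edges = [float(e) for e in bin_edges]
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    if not reference.mask.any():
        raise ValueError("reference label volume is empty")
    pts = _points_from(objects)
    # distance to the nearest reference voxel, 0 inside
    d = signed_distance_to_boundary(pts, reference)
    d = np.maximum(d, 0.0)
    names = []
    bounds = [0.0] + edges
    for lo, hi in zip(bounds, edges):
        names.append(f"[{lo:g},{hi:g})")
    names.append(f">={edges[-1]:g}")
    out = []
    for di in d:
        out.append(names[int(np.searchsorted(edges, di, side="right"))])
    return out


def compaction_density(region, probe: ProbeAnnotation) -> float:
    """Chromatin compaction of a painted region in Mb/µm³.

    Probe genomic span divided by the measured 3D volume of its FISH
    domain.  Homogeneous: doubling the volume halves the density exactly.
    """
    volume = region.volume if isinstance(region, RegionObject) else float(region)
    if volume <= 0:
        raise ValueError("region volume must be > 0")
    return probe.mb / volume
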