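"""Core data model: image stacks, label volumes, spots, measurement tables.

All physical quantities are expressed in micrometres (µm).  Voxel grids are
indexed ``(z, y, x)`` (channel first for multi-channel stacks) and the
physical coordinate of a voxel is its *centre*::

    physical = (index + 0.5) * voxel_size + origin

Anisotropic voxel sizes ``(dz, dy, dx)`` are carried through every
computation; grids are never resampled to isotropy.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("nucspat3d")

#: object types a LabelVolume may represent
OBJECT_TYPES = (
    "nucleus",
    "nucleolus",
    "chromocenter",
    "nanochromocenter",
    "body",
    "speckle",
    "sc_surface",
    "chromosome",
    "fish_region",
    "cell",
)


def index_to_phys(index, voxel_size, origin=(0.0, 0.0, 0.0)):
    """Physical µm coordinate of a (fractional) voxel index (voxel-centre)."""
    index = np.asarray(index, dtype=float)
    return (index + 0.5) * np.asarray(voxel_size, float) + np.asarray(origin, float)


def phys_to_index(point, voxel_size, origin=(0.0, 0.0, 0.0)):
    """Fractional voxel index of a physical µm coordinate."""
    point = np.asarray(point, dtype=float)
    return (point - np.asarray(origin, float)) / np.asarray(voxel_size, float) - 0.5


def phys_to_voxel(point, voxel_size, origin=(0.0, 0.0, 0.0)):
    """Nearest integer voxel index of a physical µm coordinate."""
    return np.rint(phys_to_index(point, voxel_size, origin)).astype(int)


@dataclass
class ImageStack:
    """A 3D multi-channel intensity grid with physical voxel sizes.

    Parameters
    ----------
    voxels
        Array of shape ``(channel, z, y, x)``; non-negative finite
        intensities in arbitrary units.
    voxel_size
        ``(dz, dy, dx)`` in µm, all > 0.
    channel_names
        One name per channel.
    image_id
        Identifier carried into exported tables.
    origin
        Physical µm offset of the voxel grid (non-zero after ROI cropping so
        that coordinates remain absolute).
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_names: list[str] = field(default_factory=list)
    image_id: str = "image"
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim == 3:
            self.voxels = self.voxels[None]
        if self.voxels.ndim != 4:
            raise ValueError(f"voxels must be (c,z,y,x); got ndim={self.voxels.ndim}")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be 3 positive values; got {self.voxel_size}")
        self.voxel_size = vs
        self.origin = tuple(float(v) for v in self.origin)
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.voxels.shape[0])]
        if len(self.channel_names) != self.voxels.shape[0]:
            raise ValueError("channel_names length does not match channel count")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("intensities must be finite")
        if np.any(self.voxels < 0):
            raise ValueError("intensities must be >= 0")

    # -- convenience -------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        """Spatial (z, y, x) shape."""
        return self.voxels.shape[1:]

    @property
    def voxel_volume(self) -> float:
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    def channel_index(self, channel: int | str) -> int:
        """Resolve a channel by name (preferred) or integer index."""
        if isinstance(channel, str):
            try:
                return self.channel_names.index(channel)
            except ValueError:
                raise KeyError(
                    f"channel {channel!r} not in {self.channel_names}"
                ) from None
        i = int(channel)
        if not 0 <= i < self.n_channels:
            raise IndexError(f"channel index {i} out of range")
        return i

    def channel(self, channel: int | str) -> np.ndarray:
        return self.voxels[self.channel_index(channel)]


@dataclass
class LabelVolume:
    """Integer label mask on the same grid as its source stack.

    ``0`` is background; objects are consecutive positive integers.
    """

    labels: np.ndarray
    voxel_size: tuple[float, float, float]
    object_type: str = "body"
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D (z,y,x) array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-typed")
        if self.labels.min(initial=0) < 0:
            raise ValueError("labels must be non-negative")
        vs = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in vs):
            raise ValueError("voxel_size components must be > 0")
        self.voxel_size = vs
        self.origin = tuple(float(v) for v in self.origin)
        if self.object_type not in OBJECT_TYPES:
            raise ValueError(f"unknown object_type {self.object_type!r}")

    @property
    def voxel_volume(self) -> float:
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    def object_labels(self) -> np.ndarray:
        lab = np.unique(self.labels)
        return lab[lab > 0]

    @property
    def n_objects(self) -> int:
        return int(self.object_labels().size)

    def volumes(self) -> dict[int, float]:
        """Per-object volume in µm³ (voxel count × voxel volume)."""
        lab, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        return {int(l): float(c) * self.voxel_volume for l, c in zip(lab, counts)}


@dataclass
class RegionObject:
    """Per-object measurements of one labelled region."""

    label: int
    object_type: str
    volume: float  # µm³
    center_of_mass: tuple[float, float, float]  # (z,y,x) µm
    com_weighting: str = "binary"  # or the weighting channel name
    intensity: dict = field(default_factory=dict)  # channel -> {mean,sum,sd}
    bounding_box: tuple | None = None  # ((z0,z1),(y0,y1),(x0,x1)) µm
    class_labels: dict = field(default_factory=dict)

    @property
    def equivalent_diameter(self) -> float:
        return float((6.0 * self.volume / np.pi) ** (1.0 / 3.0))


@dataclass
class Spot:
    """A point-like object: centre, radius and per-channel intensities."""

    center: tuple[float, float, float]  # (z,y,x) µm, absolute
    radius: float  # µm
    intensity: dict = field(default_factory=dict)  # channel -> {mean,sum}
    class_labels: dict = field(default_factory=dict)
    quality: float = float("nan")
    volume: float | None = None  # grown-region volume, µm³ (None: sphere)

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("spot radius must be > 0")

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius

    def sphere_volume(self) -> float:
        return float(4.0 / 3.0 * np.pi * self.radius**3)


@dataclass
class SpotSet:
    """An ordered collection of spots plus run metadata."""

    spots: list[Spot] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.spots)

    def __iter__(self):
        return iter(self.spots)

    def __getitem__(self, i):
        return self.spots[i]

    @property
    def centers(self) -> np.ndarray:
        """(n, 3) array of centres in µm."""
        if not self.spots:
            return np.zeros((0, 3))
        return np.array([s.center for s in self.spots], dtype=float)

    def radii(self) -> np.ndarray:
        return np.array([s.radius for s in self.spots], dtype=float)


# ---------------------------------------------------------------------------
# long-format measurement table


class ObjectTable:
    """Long-format measurement table, one row per

    ``(image_id, object_type, object_id, variable, channel)``.

    Every row carries a unit; class labels are extra columns.  This is the
    export surface consumed by downstream plotting tools.
    """

    COLUMNS = ["image_id", "object_type", "object_id", "variable", "channel", "value", "unit"]

    def __init__(self):
        self._rows: list[dict] = []

    def add(
        self,
        image_id: str,
        object_type: str,
        object_id,
        variable: str,
        value: float,
        unit: str,
        channel: str = "",
        **class_labels,
    ) -> None:
        self._rows.append(
            dict(
                image_id=image_id,
                object_type=object_type,
                object_id=object_id,
                variable=variable,
                channel=channel,
                value=value,
                unit=unit,
                **class_labels,
            )
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self._rows, columns=None)
        if df.empty:
            df = pd.DataFrame(columns=self.COLUMNS)
        else:
            front = [c for c in self.COLUMNS if c in df.columns]
            rest = [c for c in df.columns if c not in front]
            df = df[front + rest]
        self._check_unique(df)
        return df

    @staticmethod
    def _check_unique(df: pd.DataFrame) -> None:
        key = ["image_id", "object_type", "object_id", "variable", "channel"]
        if not df.empty and df.duplicated(subset=key).any():
            dup = df[df.duplicated(subset=key, keep=False)].iloc[0]
            raise ValueError(
                "duplicate measurement row: "
                f"{tuple(dup[k] for k in key)}"
            )

    def __len__(self) -> int:
        return len(self._rows)

    def write_csv(self, path) -> None:
        df = self.to_dataframe()
        df.to_csv(path, index=False, float_format="%.6g", encoding="utf-8")


# ---------------------------------------------------------------------------
# workflow configuration


@dataclass
class WorkflowConfig:
    """All parameters that alter a workflow's output, serialized with results."""

    workflow: str
    channels: dict = field(default_factory=dict)  # role -> channel name/index
    params: dict = field(default_factory=dict)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "workflow": self.workflow,
            "channels": dict(self.channels),
            "params": _plain(self.params),
            "seed": int(self.seed),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "WorkflowConfig":
        return cls(
            workflow=d["workflow"],
            channels=dict(d.get("channels", {})),
            params=dict(d.get("params", {})),
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path) -> "WorkflowConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _plain(obj):
    """Recursively convert numpy scalars/arrays to plain Python for YAML."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _plain(obj.tolist())
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


# ---------------------------------------------------------------------------
# I/O


def save_stack(stack: ImageStack, path) -> None:
    """Write a stack as OME-TIFF with voxel sizes and channel names."""
    dz, dy, dx = stack.voxel_size
    data = stack.voxels
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.uint16 if data.max(initial=0) < 2**16 else np.uint32)
    else:
        data = data.astype(np.float32)
    tifffile.imwrite(
        path,
        data,
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeX": dx,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": dy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": dz,
            "PhysicalSizeZUnit": "µm",
            "Channel": {"Name": list(stack.channel_names)},
        },
    )


def _ome_voxel_size(tf: tifffile.TiffFile):
    """Extract (dz, dy, dx) in µm from OME metadata, or None."""
    if not tf.ome_metadata:
        return None, None
    try:
        root = ET.fromstring(tf.ome_metadata)
    except ET.ParseError:
        return None, None
    ns = {"ome": root.tag.split("}")[0].strip("{")} if "}" in root.tag else {}
    pix = root.find(".//ome:Pixels" if ns else ".//Pixels", ns)
    if pix is None:
        return None, None
    sizes = []
    for ax in ("Z", "Y", "X"):
        v = pix.get(f"PhysicalSize{ax}")
        sizes.append(float(v) if v is not None else None)
    names = [c.get("Name") for c in pix.findall("ome:Channel" if ns else "Channel", ns)]
    vs = tuple(sizes) if all(s is not None for s in sizes) else None
    return vs, (names if names and all(n for n in names) else None)


def load_stack(path, voxel_size_override=None, channel_names=None, image_id=None) -> ImageStack:
    """Load a TIFF / OME-TIFF as an :class:`ImageStack`.

    The channel axis is normalized to first position; 3D files become
    1-channel stacks.  Voxel sizes are taken from OME / ImageJ metadata
    unless ``voxel_size_override`` (``(dz, dy, dx)`` µm) is given.  A file
    with no recoverable voxel size and no override is an error, because all
    downstream distances would be meaningless.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes.upper()
        vs_meta, names_meta = _ome_voxel_size(tf)
        if vs_meta is None and tf.imagej_metadata:
            ij = tf.imagej_metadata
            spacing = ij.get("spacing")
            page = tf.pages[0]
            xres = page.tags.get("XResolution")
            yres = page.tags.get("YResolution")
            if spacing and xres and yres:
                dx = xres.value[1] / xres.value[0]
                dy = yres.value[1] / yres.value[0]
                vs_meta = (float(spacing), float(dy), float(dx))

    if data.ndim == 2:
        raise ValueError(f"{path.name}: 2D image; 3D (z,y,x) stacks are required")
    if data.ndim == 3:
        data = data[None]
        axes = "C" + axes if len(axes) == 3 else "CZYX"
    elif data.ndim == 4:
        # move the non-spatial axis first
        spatial = {"Z", "Y", "X"}
        order = [i for i, a in enumerate(axes) if a not in spatial]
        if len(order) != 1:
            raise ValueError(f"{path.name}: cannot identify channel axis in {axes!r}")
        data = np.moveaxis(data, order[0], 0)
    else:
        raise ValueError(f"{path.name}: unsupported dimensionality {data.ndim}")

    voxel_size = tuple(voxel_size_override) if voxel_size_override is not None else vs_meta
    if voxel_size is None:
        raise ValueError(
            f"{path.name}: no voxel size in metadata and no override given; "
            "physical distances would be meaningless"
        )
    names = list(channel_names) if channel_names else (names_meta or [])
    return ImageStack(
        voxels=np.ascontiguousarray(data),
        voxel_size=voxel_size,
        channel_names=names,
        image_id=image_id or path.stem,
    )


def save_labels(lv: LabelVolume, path) -> None:
    """Write a label mask as an integer OME-TIFF (lossless round trip)."""
    dtype = np.uint16 if lv.labels.max(initial=0) < 2**16 else np.uint32
    stack = ImageStack(
        voxels=lv.labels.astype(dtype)[None],
        voxel_size=lv.voxel_size,
        channel_names=[lv.object_type],
        image_id=lv.object_type,
        origin=lv.origin,
    )
    save_stack(stack, path)


def load_labels(path, object_type: str, voxel_size_override=None) -> LabelVolume:
    """Reload a label mask written by :func:`save_labels` (or user-supplied)."""
    stack = load_stack(path, voxel_size_override=voxel_size_override)
    labels = np.asarray(stack.voxels[0])
    if not np.issubdtype(labels.dtype, np.integer):
        if not np.allclose(labels, np.rint(labels)):
            raise ValueError(f"{path}: label image has non-integer values")
        labels = np.rint(labels).astype(np.int64)
    return LabelVolume(
        labels=labels.astype(np.int32),
        voxel_size=stack.voxel_size,
        object_type=object_type,
    )


# ---------------------------------------------------------------------------
# table export


_REGION_VARS = {"volume": "µm³", "equivalent_diameter": "µm"}
_SPOT_VARS = {"diameter": "µm", "volume": "µm³"}


def export_table(
    objects: Sequence[RegionObject] | SpotSet | Iterable,
    image_id: str,
    path=None,
    object_type: str | None = None,
    config: WorkflowConfig | None = None,
) -> ObjectTable:
    """Export measured objects as a long-format table (optionally CSV).

    Each region contributes a volume / equivalent-diameter row plus one row
    per (intensity statistic, channel); each spot contributes diameter,
    volume and per-channel mean/sum rows.  When ``path`` is given the CSV is
    written and, if a config is supplied, a YAML sidecar next to it.
    """
    table = ObjectTable()
    items = list(objects)
    for i, obj in enumerate(items):
        if isinstance(obj, RegionObject):
            otype = obj.object_type
            oid = obj.label
            cls = obj.class_labels
            table.add(image_id, otype, oid, "volume", obj.volume, "µm³", **cls)
            table.add(
                image_id, otype, oid, "equivalent_diameter", obj.equivalent_diameter, "µm", **cls
            )
            for axis, c in zip("zyx", obj.center_of_mass):
                table.add(image_id, otype, oid, f"center_{axis}", c, "µm", **cls)
            for ch, stats in obj.intensity.items():
                for stat, val in stats.items():
                    table.add(
                        image_id, otype, oid, f"intensity_{stat}", val, "a.u.",
                        channel=str(ch), **cls,
                    )
        elif isinstance(obj, Spot):
            otype = object_type or "spot"
            oid = i + 1
            cls = obj.class_labels
            table.add(image_id, otype, oid, "diameter", obj.diameter, "µm", **cls)
            vol = obj.volume if obj.volume is not None else obj.sphere_volume()
            table.add(image_id, otype, oid, "volume", vol, "µm³", **cls)
            for axis, c in zip("zyx", obj.center):
                table.add(image_id, otype, oid, f"center_{axis}", c, "µm", **cls)
            for ch, stats in obj.intensity.items():
                for stat, val in stats.items():
                    table.add(
                        image_id, otype, oid, f"intensity_{stat}", val, "a.u.",
                        channel=str(ch), **cls,
                    )
        else:
            raise TypeError(f"cannot export object of type {type(obj).__name__}")
    # validate uniqueness eagerly
    table.to_dataframe()
    if path is not None:
        table.write_csv(path)
        if config is not None:
            sidecar = Path(path).with_suffix(".config.yaml")
            config.to_yaml(sidecar)
    return table
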