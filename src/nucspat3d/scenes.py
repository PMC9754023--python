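"""Ground-truth 3D phantom scenes for every workflow.

Each generator renders a multi-channel stack through a simple imaging
model — Gaussian PSF blur (axial sigma >= lateral, as in any fluorescence
microscope), Poisson shot noise on signal plus background, then additive
Gaussian read noise — and returns the exact geometry that produced it, so
every measurement operation can be validated without microscope data.

The phantoms emulate geometry and contrast, not optics: there is no full
vectorial PSF, no reconstruction artefact, and the reticulate polymerase
background is a thresholded band-pass noise field standing in for the real
reticulum, whose generative model is unknown.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from scipy import ndimage

from .core import ImageStack, _plain

__all__ = [
    "RenderParams",
    "SceneGroundTruth",
    "make_interphase_scene",
    "make_ne_scene",
    "make_meiotic_scene",
    "make_chromosome_scene",
    "make_rabl_scene",
    "make_anaphase_scene",
    "rasterize_tubes",
]


@dataclass
class RenderParams:
    """Imaging model parameters shared by all scenes.

    Voxel size defaults to 0.1 x 0.05 x 0.05 µm (axial coarser) and PSF
    sigmas to 0.15 / 0.06 µm (axial / lateral) — super-resolution-scale
    sampling.  Noise: Poisson on signal + background, then Gaussian read
    noise of the given sd.
    """

    voxel_size: tuple[float, float, float] = (0.1, 0.05, 0.05)
    psf_sigma: tuple[float, float] = (0.15, 0.06)  # (axial, lateral) µm
    background: float = 2.0
    noise_model: str = "poisson_gaussian"
    gaussian_sd: float = 2.0

    def __post_init__(self):
        if self.psf_sigma[0] < self.psf_sigma[1]:
            raise ValueError("axial PSF sigma must be >= lateral sigma")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be > 0")


@dataclass
class SceneGroundTruth:
    """True per-object parameters of a rendered scene (serializable)."""

    scene: str = ""
    seed: int = 0
    voxel_size: tuple = (0.1, 0.05, 0.05)
    shape: tuple = ()
    nucleus_center: tuple | None = None
    nucleus_semi_axes: tuple | None = None  # (az, ay, ax) µm
    nucleolus_center: tuple | None = None
    nucleolus_radius: float | None = None
    cc_centers: list = field(default_factory=list)
    cc_radii: list = field(default_factory=list)
    nanocc_centers: list = field(default_factory=list)
    nanocc_radii: list = field(default_factory=list)
    cluster_centers: list = field(default_factory=list)
    cluster_sigmas: list = field(default_factory=list)
    cluster_amplitudes: list = field(default_factory=list)
    shell_radius: float | None = None
    shell_thickness: float | None = None
    equatorial_factor: float | None = None
    spot_centers: list = field(default_factory=list)
    spot_amplitudes: list = field(default_factory=list)
    spot_axial_class: list = field(default_factory=list)
    sc_curves: list = field(default_factory=list)  # list of (m,3) µm polylines
    sc_radius: float | None = None
    chromosome_radius: float | None = None
    foci_centers: list = field(default_factory=list)
    foci_amplitudes: list = field(default_factory=list)
    foci_tiers: list = field(default_factory=list)
    foci_on_curve: list = field(default_factory=list)
    segment_volumes: list = field(default_factory=list)
    segment_mb: list = field(default_factory=list)
    segment_bounds: list = field(default_factory=list)  # (y0, y1) µm per segment
    configuration: str | None = None
    cen_centers: list = field(default_factory=list)
    tel_centers: list = field(default_factory=list)
    plate_centroids: list = field(default_factory=list)
    division_angle_deg: float | None = None
    cell_center: tuple | None = None
    cell_axis: tuple | None = None

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(asdict(self)), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SceneGroundTruth":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(**d)


# ---------------------------------------------------------------------------
# rendering helpers


def _grid(shape, voxel_size):
    """Physical voxel-centre coordinate arrays (broadcastable)."""
    return [
        ((np.arange(s) + 0.5) * v).reshape([-1 if i == j else 1 for j in range(3)])
        for i, (s, v) in enumerate(zip(shape, voxel_size))
    ]


def _ellipsoid_mask(shape, voxel_size, center, semi_axes):
    z, y, x = _grid(shape, voxel_size)
    return (
        ((z - center[0]) / semi_axes[0]) ** 2
        + ((y - center[1]) / semi_axes[1]) ** 2
        + ((x - center[2]) / semi_axes[2]) ** 2
    ) <= 1.0


def _sphere_mask(shape, voxel_size, center, radius):
    return _ellipsoid_mask(shape, voxel_size, center, (radius,) * 3)


def _add_gaussian(channel, voxel_size, center, sigma, amplitude):
    """Add an anisotropic Gaussian blob within a 4-sigma window."""
    shape = channel.shape
    lo, hi, axes = [], [], []
    for c, s, v, n in zip(center, sigma, voxel_size, shape):
        r = 4.0 * s
        i0 = max(int((c - r) / v), 0)
        i1 = min(int((c + r) / v) + 1, n)
        if i1 <= i0:
            return
        lo.append(i0)
        hi.append(i1)
        axes.append((np.arange(i0, i1) + 0.5) * v - c)
    g = (
        np.exp(-0.5 * (axes[0] / sigma[0]) ** 2)[:, None, None]
        * np.exp(-0.5 * (axes[1] / sigma[1]) ** 2)[None, :, None]
        * np.exp(-0.5 * (axes[2] / sigma[2]) ** 2)[None, None, :]
    )
    channel[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += amplitude * g


def _render(channels: dict, params: RenderParams, rng, image_id: str) -> ImageStack:
    """Blur with the PSF, add background and noise, assemble the stack."""
    ax, lat = params.psf_sigma
    sigma_vox = (
        ax / params.voxel_size[0],
        lat / params.voxel_size[1],
        lat / params.voxel_size[2],
    )
    names, rendered = [], []
    for name, signal in channels.items():
        img = ndimage.gaussian_filter(signal.astype(float), sigma=sigma_vox)
        img = img + params.background
        if params.noise_model == "poisson_gaussian":
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
            img = img + rng.normal(0.0, params.gaussian_sd, img.shape)
        img = np.clip(img, 0, None)
        names.append(name)
        rendered.append(img.astype(np.float32))
    return ImageStack(
        voxels=np.stack(rendered),
        voxel_size=params.voxel_size,
        channel_names=names,
        image_id=image_id,
    )


def _sample_separated(
    rng, n, sampler, accept, min_sep, existing=None, existing_sep=None, max_tries=20000
):
    """Rejection-sample n points with pairwise separation >= min_sep
    (and >= existing_sep from already-placed points)."""
    prior = [np.asarray(p, float) for p in (existing or [])]
    existing_sep = min_sep if existing_sep is None else existing_sep
    pts: list[np.ndarray] = []
    tries = 0
    while len(pts) < n:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"cannot place {n} objects with separation {min_sep} µm "
                "inside the requested volume"
            )
        p = np.asarray(sampler(), float)
        if not accept(p):
            continue
        if any(np.linalg.norm(p - q) < existing_sep for q in prior):
            continue
        if all(np.linalg.norm(p - q) >= min_sep for q in pts):
            pts.append(p)
    return [tuple(float(v) for v in p) for p in pts]


def rasterize_tubes(curves, radius, shape, voxel_size, step=0.05):
    """Boolean mask of tubes of the given radius around µm polylines."""
    mask = np.zeros(shape, bool)
    for curve in curves:
        curve = np.asarray(curve, float)
        # resample densely along the polyline
        seglens = np.linalg.norm(np.diff(curve, axis=0), axis=1)
        t = np.concatenate([[0.0], np.cumsum(seglens)])
        total = t[-1]
        npts = max(int(total / step) + 1, 2)
        ts = np.linspace(0, total, npts)
        samples = np.stack([np.interp(ts, t, curve[:, k]) for k in range(3)], axis=1)
        for p in samples:
            mask |= _stamp_sphere(shape, voxel_size, p, radius)
    return mask


def _stamp_sphere(shape, voxel_size, center, radius):
    out = np.zeros(shape, bool)
    lo = [max(int((c - radius) / v), 0) for c, v in zip(center, voxel_size)]
    hi = [min(int((c + radius) / v) + 2, n) for c, v, n in zip(center, voxel_size, shape)]
    if any(h <= l for l, h in zip(lo, hi)):
        return out
    axes = [
        (np.arange(l, h) + 0.5) * v - c
        for l, h, v, c in zip(lo, hi, voxel_size, center)
    ]
    d2 = (
        (axes[0] ** 2)[:, None, None]
        + (axes[1] ** 2)[None, :, None]
        + (axes[2] ** 2)[None, None, :]
    )
    out[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = d2 <= radius**2
    return out


def _shape_for(extent, voxel_size):
    return tuple(int(np.ceil(e / v)) for e, v in zip(extent, voxel_size))


# ---------------------------------------------------------------------------
# scenes


def make_interphase_scene(
    params: RenderParams | None = None,
    n_cc: int = 8,
    n_nanocc: int = 20,
    n_clusters: int = 150,
    seed: int = 0,
    nucleus_semi_axes: tuple = (2.0, 2.5, 3.0),
    nucleolus_radius: float | None = None,
):
    """Interphase nucleus: DNA channel with nucleolar void, peripheral
    chromocenters and dim nanochromocenters; polymerase channel with a
    reticulate nucleoplasmic background plus clusters of variable size and
    amplitude.

    Contrast levels (a.u., pre-noise): nucleoplasm 40, nucleolus 8,
    chromocenters +160, nanochromocenters +120; reticulum 20 on ~40 % of
    the nucleoplasm; cluster amplitudes uniform in [100, 300] with lateral
    sigmas in [0.08, 0.2] µm (axial 1.5x) — clusters carry the dominant
    share of the polymerase signal, as in stained nuclei.
    """
    if min(n_cc, n_nanocc, n_clusters) < 0:
        raise ValueError("object counts must be >= 0")
    params = params or RenderParams()
    rng = np.random.default_rng(seed)
    vs = params.voxel_size
    margin = 0.6
    semi = np.asarray(nucleus_semi_axes, float)
    extent = 2 * semi + 2 * margin
    shape = _shape_for(extent, vs)
    center = extent / 2.0

    nucleus = _ellipsoid_mask(shape, vs, center, semi)
    nucl_center = center + np.array([0.0, 0.4, 0.0])
    nucl_radius = (
        float(nucleolus_radius)
        if nucleolus_radius is not None
        else min(0.9, 0.45 * semi.min())
    )
    if nucl_radius + 0.4 >= semi.min():
        raise ValueError("nucleolus does not fit inside the nucleus")
    nucleolus = _sphere_mask(shape, vs, nucl_center, nucl_radius)

    def in_nucleus(p, shrink):
        rel = (p - center) / semi
        return float(np.sum(rel**2)) <= shrink**2

    def sampler():
        return center + (rng.random(3) * 2 - 1) * semi

    cc_radii = rng.uniform(0.35, 0.45, n_cc)
    nano_radii = rng.uniform(0.16, 0.19, n_nanocc)

    def accept_cc(p):
        rel = np.linalg.norm((p - center) / semi)
        if not 0.55 <= rel <= 0.8:
            return False
        return np.linalg.norm(p - nucl_center) > nucl_radius + 0.6

    cc_centers = _sample_separated(rng, n_cc, sampler, accept_cc, min_sep=1.25)

    def accept_nano(p):
        if not in_nucleus(p, 0.85):
            return False
        return np.linalg.norm(p - nucl_center) > nucl_radius + 0.35

    nano_centers = _sample_separated(
        rng, n_nanocc, sampler, accept_nano, min_sep=0.55,
        existing=cc_centers, existing_sep=0.95,
    )

    dna = np.zeros(shape)
    dna[nucleus] = 40.0
    dna[nucleolus] = 8.0
    for c, r in zip(cc_centers, cc_radii):
        dna[_sphere_mask(shape, vs, c, r)] += 160.0
    for c, r in zip(nano_centers, nano_radii):
        dna[_sphere_mask(shape, vs, c, r)] += 120.0

    # polymerase channel
    nucleoplasm = nucleus & ~nucleolus
    for c, r in zip(cc_centers, cc_radii):
        nucleoplasm &= ~_sphere_mask(shape, vs, c, r)
    ret_field = ndimage.gaussian_filter(
        rng.standard_normal(shape), sigma=[0.15 / v for v in vs]
    )
    rnp = np.zeros(shape)
    if nucleoplasm.any():
        thr = np.quantile(ret_field[nucleoplasm], 0.6)
        rnp[(ret_field > thr) & nucleoplasm] = 20.0

    def accept_cluster(p):
        idx = tuple(np.clip((np.asarray(p) / vs).astype(int), 0, np.array(shape) - 1))
        return bool(nucleoplasm[idx])

    cl_centers = _sample_separated(rng, n_clusters, sampler, accept_cluster, min_sep=0.25)
    cl_sig_lat = rng.uniform(0.08, 0.2, n_clusters)
    cl_amp = rng.uniform(100.0, 300.0, n_clusters)
    cl_sigmas = [(1.5 * s, s, s) for s in cl_sig_lat]
    for c, s, a in zip(cl_centers, cl_sigmas, cl_amp):
        _add_gaussian(rnp, vs, c, s, a)

    stack = _render({"dna": dna, "rnpii": rnp}, params, rng, f"interphase_seed{seed}")
    gt = SceneGroundTruth(
        scene="interphase",
        seed=seed,
        voxel_size=vs,
        shape=shape,
        nucleus_center=tuple(center),
        nucleus_semi_axes=tuple(semi),
        nucleolus_center=tuple(nucl_center),
        nucleolus_radius=float(nucl_radius),
        cc_centers=list(cc_centers),
        cc_radii=[float(r) for r in cc_radii],
        nanocc_centers=list(nano_centers),
        nanocc_radii=[float(r) for r in nano_radii],
        cluster_centers=list(cl_centers),
        cluster_sigmas=[tuple(map(float, s)) for s in cl_sigmas],
        cluster_amplitudes=[float(a) for a in cl_amp],
    )
    return stack, gt


def make_ne_scene(
    params: RenderParams | None = None,
    equatorial_factor: float = 2.0,
    n_spots: int = 60,
    seed: int = 0,
    shell_radius: float = 3.5,
    shell_thickness: float = 0.25,
):
    """Nuclear-envelope shell with clusters enriched at the equator.

    Spots sit on a spherical shell; amplitudes of spots with frame-relative
    |z'| <= 2 µm (the equatorial band) are multiplied by
    ``equatorial_factor``.  A factor of 1 is the null scene.  Spots are not
    placed within 0.2 µm of the band boundary so their true class is
    unambiguous under blur.
    """
    params = params or RenderParams()
    rng = np.random.default_rng(seed)
    vs = params.voxel_size
    margin = 0.8
    extent = np.full(3, 2 * shell_radius + 2 * margin)
    shape = _shape_for(extent, vs)
    center = extent / 2.0

    z, y, x = _grid(shape, vs)
    r = np.sqrt((z - center[0]) ** 2 + (y - center[1]) ** 2 + (x - center[2]) ** 2)
    shell = np.abs(r - shell_radius) <= shell_thickness / 2.0
    ne = np.zeros(shape)
    ne[shell] = 15.0

    def sampler():
        v = rng.standard_normal(3)
        v /= np.linalg.norm(v)
        return center + shell_radius * v

    def accept(p):
        dz = abs(p[0] - center[0])
        return not (1.8 <= dz <= 2.2)  # keep classes unambiguous

    centers = _sample_separated(rng, n_spots, sampler, accept, min_sep=0.5)
    amps, classes = [], []
    for c in centers:
        dz = c[0] - center[0]
        if abs(dz) <= 2.0:
            cls = "middle"
            amp = 150.0 * equatorial_factor
        else:
            cls = "top" if dz > 0 else "bottom"
            amp = 150.0
        amps.append(amp)
        classes.append(cls)
        _add_gaussian(ne, vs, c, (0.15, 0.1, 0.1), amp)

    stack = _render({"ne_gfp": ne}, params, rng, f"ne_seed{seed}")
    gt = SceneGroundTruth(
        scene="ne",
        seed=seed,
        voxel_size=vs,
        shape=shape,
        nucleus_center=tuple(center),
        shell_radius=float(shell_radius),
        shell_thickness=float(shell_thickness),
        equatorial_factor=float(equatorial_factor),
        spot_centers=list(centers),
        spot_amplitudes=[float(a) for a in amps],
        spot_axial_class=classes,
    )
    return stack, gt


def make_meiotic_scene(
    params: RenderParams | None = None,
    n_foci: int = 240,
    tier_fractions: tuple = (0.02, 0.02, 0.96),
    off_curve_fraction: float = 0.1,
    seed: int = 0,
):
    """Meiotic prophase scene: synaptonemal-complex axes as bright 3D
    curves, a chromosome channel as thicker tubes around them, and
    recombination foci of ~200 nm on or off the axes.

    Foci amplitudes come in three well-separated tiers (600 / 300 / 100
    a.u.) with the given fractions, so intensity-sum classification can be
    validated against the true tier labels.
    """
    params = params or RenderParams()
    if abs(sum(tier_fractions) - 1.0) > 1e-9:
        raise ValueError("tier fractions must sum to 1")
    rng = np.random.default_rng(seed)
    vs = params.voxel_size
    extent = np.array([6.4, 8.0, 8.0])
    shape = _shape_for(extent, vs)
    margin = 0.7

    curves = []
    for _ in range(7):
        z0 = rng.uniform(1.5, extent[0] - 1.5)
        x0 = rng.uniform(1.5, extent[2] - 1.5)
        amp_z = rng.uniform(0.3, 0.8)
        amp_x = rng.uniform(0.3, 0.8)
        ph = rng.uniform(0, 2 * np.pi, 2)
        ys = np.linspace(margin, extent[1] - margin, 40)
        t = (ys - ys[0]) / (ys[-1] - ys[0])
        zs = np.clip(z0 + amp_z * np.sin(2 * np.pi * t + ph[0]), 0.8, extent[0] - 0.8)
        xs = np.clip(x0 + amp_x * np.sin(2 * np.pi * 1.5 * t + ph[1]), 0.8, extent[2] - 0.8)
        curves.append(np.stack([zs, ys, xs], axis=1))

    sc_radius, chrom_radius = 0.12, 0.35
    sc_mask = rasterize_tubes(curves, sc_radius, shape, vs)
    chrom_mask = rasterize_tubes(curves, chrom_radius, shape, vs)
    dapi = np.where(chrom_mask, 80.0, 0.0)
    zyp1 = np.where(sc_mask, 150.0, 0.0)

    # dense curve samples for on-curve placement and off-curve exclusion
    samples = []
    for c in curves:
        seglens = np.linalg.norm(np.diff(c, axis=0), axis=1)
        t = np.concatenate([[0.0], np.cumsum(seglens)])
        ts = np.linspace(0, t[-1], max(int(t[-1] / 0.05) + 1, 2))
        samples.append(np.stack([np.interp(ts, t, c[:, k]) for k in range(3)], axis=1))
    all_samples = np.concatenate(samples)

    n_off = int(round(n_foci * off_curve_fraction))
    n_on = n_foci - n_off

    def on_sampler():
        return all_samples[rng.integers(len(all_samples))] + rng.normal(0, 0.03, 3)

    on_centers = _sample_separated(rng, n_on, on_sampler, lambda p: True, min_sep=0.2)

    from scipy.spatial import cKDTree

    tree = cKDTree(all_samples)

    def off_sampler():
        return np.array(
            [rng.uniform(margin, e - margin) for e in extent]
        )

    def off_accept(p):
        return tree.query(p)[0] > 0.5

    off_centers = _sample_separated(
        rng, n_off, off_sampler, off_accept, min_sep=0.2, existing=on_centers
    )
    centers = list(on_centers) + list(off_centers)
    on_flags = [True] * n_on + [False] * n_off

    order = rng.permutation(n_foci)
    tier_amp = {"T1": 600.0, "T2": 300.0, "T3": 100.0}
    n1 = int(np.ceil(tier_fractions[0] * n_foci))
    n2 = int(np.ceil(tier_fractions[1] * n_foci))
    tiers = [""] * n_foci
    for rank, pos in enumerate(order):
        tiers[pos] = "T1" if rank < n1 else ("T2" if rank < n1 + n2 else "T3")
    amps = [tier_amp[t] * rng.uniform(0.9, 1.1) for t in tiers]

    dmc1 = np.zeros(shape)
    for c, a in zip(centers, amps):
        _add_gaussian(dmc1, vs, c, (0.12, 0.07, 0.07), a)

    stack = _render(
        {"dapi": dapi, "zyp1": zyp1, "dmc1": dmc1}, params, rng, f"meiotic_seed{seed}"
    )
    gt = SceneGroundTruth(
        scene="meiotic",
        seed=seed,
        voxel_size=vs,
        shape=shape,
        sc_curves=[c.tolist() for c in curves],
        sc_radius=float(sc_radius),
        chromosome_radius=float(chrom_radius),
        foci_centers=[tuple(map(float, c)) for c in centers],
        foci_amplitudes=[float(a) for a in amps],
        foci_tiers=tiers,
        foci_on_curve=on_flags,
    )
    return stack, gt


def make_chromosome_scene(
    params: RenderParams | None = None,
    segment_volumes: tuple = (1.144, 2.0),
    segment_mb: tuple = (39.0, 39.0),
    seed: int = 0,
    radius: float = 0.55,
):
    """Condensed metaphase chromosome (cylinder) with painted sub-regions of
    analytically known volume and genomic span.

    The default two segments carry equal genomic content in volumes of
    1.144 and 2.0 µm³, i.e. compaction densities of 34.1 and 19.5 Mb/µm³ —
    an interstitial-arm versus subtelomere-adjacent contrast.
    """
    params = params or RenderParams()
    if len(segment_volumes) != len(segment_mb):
        raise ValueError("one Mb value per segment is required")
    if any(v <= 0 for v in segment_volumes):
        raise ValueError("segment volumes must be > 0")
    rng = np.random.default_rng(seed)
    vs = params.voxel_size
    area = np.pi * radius**2
    lengths = [v / area for v in segment_volumes]
    gap = 0.3
    flank = 0.5
    total_len = sum(lengths) + gap * (len(lengths) - 1) + 2 * flank
    extent = np.array([2 * radius + 1.2, total_len + 1.0, 2 * radius + 1.2])
    shape = _shape_for(extent, vs)
    c_z, c_x = extent[0] / 2.0, extent[2] / 2.0

    z, y, x = _grid(shape, vs)
    rad2 = (z - c_z) ** 2 + (x - c_x) ** 2
    in_tube = rad2 <= radius**2

    y0 = 0.5
    dapi = np.zeros(shape)
    dapi[in_tube & (y >= y0) & (y <= y0 + total_len)] = 100.0

    channels = {"dapi": dapi}
    bounds = []
    pos = y0 + flank
    for i, L in enumerate(lengths):
        seg = np.zeros(shape)
        seg[in_tube & (y >= pos) & (y < pos + L)] = 120.0
        channels[f"fish_{i + 1}"] = seg
        bounds.append((float(pos), float(pos + L)))
        pos += L + gap

    stack = _render(channels, params, rng, f"chromosome_seed{seed}")
    gt = SceneGroundTruth(
        scene="chromosome",
        seed=seed,
        voxel_size=vs,
        shape=shape,
        chromosome_radius=float(radius),
        segment_volumes=[float(v) for v in segment_volumes],
        segment_mb=[float(m) for m in segment_mb],
        segment_bounds=bounds,
    )
    return stack, gt


def make_rabl_scene(
    params: RenderParams | None = None,
    configuration: str = "rabl",
    n_cen: int = 14,
    n_tel: int = 28,
    seed: int = 0,
    radius: float = 3.0,
):
    """Interphase nucleus with centromere and telomere FISH spots.

    ``rabl``: centromeres cluster in a polar cap near the surface at one
    pole and telomeres at the opposite pole (the Rabl configuration);
    ``non_rabl``: both sets are uniform in the nuclear volume.
    """
    if configuration not in ("rabl", "non_rabl"):
        raise ValueError("configuration must be 'rabl' or 'non_rabl'")
    params = params or RenderParams()
    rng = np.random.default_rng(seed)
    vs = params.voxel_size
    margin = 0.6
    extent = np.full(3, 2 * radius + 2 * margin)
    shape = _shape_for(extent, vs)
    center = extent / 2.0

    dna = np.zeros(shape)
    dna[_sphere_mask(shape, vs, center, radius)] = 40.0

    def cap_sampler(pole):
        # pole = +1 (centromeres, +z) or -1 (telomeres, -z)
        while True:
            v = rng.standard_normal(3)
            v /= np.linalg.norm(v)
            if pole * v[0] >= np.cos(np.radians(60.0)):
                break
        rr = radius * rng.uniform(0.75, 0.92)
        return center + rr * v

    def uniform_sampler():
        while True:
            p = (rng.random(3) * 2 - 1) * radius * 0.92
            if np.linalg.norm(p) <= radius * 0.92:
                return center + p

    if configuration == "rabl":
        cen = _sample_separated(rng, n_cen, lambda: cap_sampler(+1), lambda p: True, 0.5)
        tel = _sample_separated(rng, n_tel, lambda: cap_sampler(-1), lambda p: True, 0.45)
    else:
        cen = _sample_separated(rng, n_cen, uniform_sampler, lambda p: True, 0.5)
        tel = _sample_separated(rng, n_tel, uniform_sampler, lambda p: True, 0.45)

    cen_ch = np.zeros(shape)
    tel_ch = np.zeros(shape)
    for c in cen:
        _add_gaussian(cen_ch, vs, c, (0.12, 0.08, 0.08), 200.0)
    for c in tel:
        _add_gaussian(tel_ch, vs, c, (0.12, 0.08, 0.08), 200.0)

    stack = _render(
        {"dna": dna, "cen": cen_ch, "tel": tel_ch}, params, rng,
        f"rabl_{configuration}_seed{seed}",
    )
    gt = SceneGroundTruth(
        scene="rabl",
        seed=seed,
        voxel_size=vs,
        shape=shape,
        nucleus_center=tuple(center),
        shell_radius=float(radius),
        configuration=configuration,
        cen_centers=list(cen),
        tel_centers=list(tel),
    )
    return stack, gt


def make_anaphase_scene(
    params: RenderParams | None = None,
    angle: float = 30.0,
    seed: int = 0,
    cell_half_length: float = 5.0,
    cell_radius: float = 2.6,
    wall_thickness: float = 0.3,
    plate_sep: float = 3.0,
    plate_radius: float = 1.2,
    plate_thickness: float = 0.4,
):
    """Anaphase cell: autofluorescent wall (capsule) plus two chromosome
    plates whose pulling axis makes the requested angle with the cell's
    elongation axis (rotation in the y–x plane).

    Raises when the plates, at the requested angle, do not fit inside the
    cell interior.
    """
    params = params or RenderParams()
    rng = np.random.default_rng(seed)
    vs = params.voxel_size
    extent = np.array(
        [2 * cell_radius + 1.0, 2 * cell_half_length + 1.0, 2 * cell_radius + 1.0]
    )
    shape = _shape_for(extent, vs)
    center = extent / 2.0

    z, y, x = _grid(shape, vs)
    # capsule along y: distance to the axis segment
    half_core = max(cell_half_length - cell_radius, 0.0)
    dy = np.clip(np.abs(y - center[1]) - half_core, 0.0, None)
    d_axis = np.sqrt((z - center[0]) ** 2 + dy**2 + (x - center[2]) ** 2)
    wall = (d_axis <= cell_radius) & (d_axis >= cell_radius - wall_thickness)
    interior = d_axis < cell_radius - wall_thickness

    theta = np.radians(angle)
    u = np.array([0.0, np.cos(theta), np.sin(theta)])  # pulling direction (z,y,x)
    plate_centers = [center + 0.5 * plate_sep * u, center - 0.5 * plate_sep * u]

    rel = np.stack(
        [np.broadcast_to(z, shape), np.broadcast_to(y, shape), np.broadcast_to(x, shape)],
        axis=-1,
    )
    plates = np.zeros(shape, bool)
    for pc in plate_centers:
        dv = rel - pc
        along = dv @ u
        perp2 = np.sum(dv**2, axis=-1) - along**2
        disk = (np.abs(along) <= plate_thickness / 2.0) & (perp2 <= plate_radius**2)
        if (disk & ~interior).any():
            raise ValueError(
                f"plates at angle {angle}° do not fit inside the cell "
                f"(half-length {cell_half_length} µm, radius {cell_radius} µm)"
            )
        plates |= disk

    chrom = np.zeros(shape)
    chrom[wall] = 60.0
    chrom[plates] = 150.0

    cen_ch = np.zeros(shape)
    # a few centromere spots on each plate's inner face
    for pc, sign in zip(plate_centers, (+1, -1)):
        for _ in range(5):
            w = rng.standard_normal(3)
            w -= (w @ u) * u
            nw = np.linalg.norm(w)
            w = w / nw if nw > 0 else np.array([1.0, 0.0, 0.0])
            p = pc - sign * u * (plate_thickness / 2.0) + w * rng.uniform(
                0, 0.7 * plate_radius
            )
            _add_gaussian(cen_ch, vs, p, (0.12, 0.08, 0.08), 200.0)

    stack = _render(
        {"chromatin_wall": chrom, "centromeres": cen_ch}, params, rng,
        f"anaphase_{angle:g}deg_seed{seed}",
    )
    gt = SceneGroundTruth(
        scene="anaphase",
        seed=seed,
        voxel_size=vs,
        shape=shape,
        plate_centroids=[tuple(map(float, c)) for c in plate_centers],
        division_angle_deg=float(angle),
        cell_center=tuple(map(float, center)),
        cell_axis=(0.0, 1.0, 0.0),
    )
    return stack, gt
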