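"""End-to-end workflow chains: one entry point per analysis scenario.

Each workflow validates its configuration, runs the segmentation /
measurement chain, and returns a :class:`WorkflowResult` holding the
long-format measurement table, the label volumes, the spot sets and scalar
metrics.  When an output directory is given, everything is written to disk
(CSV, label TIFFs, YAML config sidecar, plain-text log) so a run is
reproducible from its sidecar alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import classify, segmentation as seg, spatial
from .core import (
    ImageStack,
    LabelVolume,
    ObjectTable,
    SpotSet,
    WorkflowConfig,
    export_table,
    load_stack,
    save_labels,
)

WORKFLOW_NAMES = (
    "w1_rnpii",
    "w2_ne",
    "w3_meiosis",
    "w4_bodies",
    "w5_chromosome",
    "w6_rabl",
    "w7_angle",
)


@dataclass
class WorkflowResult:
    workflow: str
    table: ObjectTable
    labels: dict = field(default_factory=dict)  # name -> LabelVolume
    spots: dict = field(default_factory=dict)  # name -> SpotSet
    metrics: dict = field(default_factory=dict)
    config: WorkflowConfig | None = None
    log: list = field(default_factory=list)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.table.write_csv(outdir / f"{self.workflow}_objects.csv")
        for name, lv in self.labels.items():
            save_labels(lv, outdir / f"{self.workflow}_{name}.ome.tif")
        if self.config is not None:
            self.config.to_yaml(outdir / f"{self.workflow}_config.yaml")
        with open(outdir / f"{self.workflow}_run.log", "w") as fh:
            fh.write("\n".join(self.log) + "\n")
        if self.metrics:
            with open(outdir / f"{self.workflow}_metrics.yaml", "w") as fh:
                import yaml

                yaml.safe_dump(
                    {k: float(v) if np.isscalar(v) else v for k, v in self.metrics.items()},
                    fh,
                )


def _require(cfg: WorkflowConfig, channel_roles, param_keys=()):
    missing = [f"channels.{r}" for r in channel_roles if r not in cfg.channels]
    missing += [f"params.{k}" for k in param_keys if k not in cfg.params]
    if missing:
        raise ValueError(
            f"config for {cfg.workflow} is missing required keys: {', '.join(missing)}"
        )


def _surface_params(d: dict | None) -> seg.SurfaceParams:
    return seg.SurfaceParams(**(d or {}))


def _spot_params(d: dict | None) -> seg.SpotParams:
    return seg.SpotParams(**(d or {}))


def _export_regions(table_objects, stack, image_id, obj_type=None):
    return export_table(table_objects, image_id, object_type=obj_type)


def _merge_tables(*tables) -> ObjectTable:
    out = ObjectTable()
    for t in tables:
        out._rows.extend(t._rows)
    out.to_dataframe()  # uniqueness check
    return out


def _add_distance_rows(table, image_id, obj_type, regions_or_spots, dists, variable, unit="µm", **extra):
    for i, d in enumerate(dists):
        oid = (
            regions_or_spots[i].label
            if hasattr(regions_or_spots[i], "label")
            else i + 1
        )
        cls = getattr(regions_or_spots[i], "class_labels", {})
        table.add(image_id, obj_type, oid, variable, float(d), unit, **cls, **extra)


# ---------------------------------------------------------------------------
# the seven workflows


def w1_rnpii(stack: ImageStack, cfg: WorkflowConfig) -> WorkflowResult:
    """Interphase transcription clusters: nucleus / nucleolus / CC / nanoCC
    surfaces, masked polymerase channel, iterative growing-spot capture,
    distances to the nuclear periphery and per-image intensity
    normalization."""
    _require(cfg, ("dna", "rnpii"))
    p = cfg.params
    log = []
    nucleus = seg.segment_nucleus(stack, cfg.channels["dna"], _surface_params(p.get("nucleus")))
    nucleolus = seg.segment_nucleolus(
        stack, cfg.channels["dna"], nucleus, _surface_params(p.get("nucleolus"))
    )
    bodies = seg.segment_bright_bodies(
        stack, cfg.channels["dna"], nucleus, _surface_params(p.get("bodies")),
        object_type="body",
    )
    cc, nanocc = seg.split_by_volume(bodies, float(p.get("cc_volume_cutoff", 0.1)))
    log.append(f"nucleus volume {list(nucleus.volumes().values())[0]:.3g} µm³")
    log.append(f"{cc.n_objects} chromocenters, {nanocc.n_objects} nanochromocenters")

    masked = seg.mask_channel(stack, nucleus)
    sp = _spot_params(p.get("spots", {"seed_diameter": 0.2, "capture_target": 0.8}))
    spots = seg.iterative_spot_capture(masked, cfg.channels["rnpii"], nucleus, sp)
    log.append(
        f"iterative capture: {spots.metadata['captured_fraction']:.3f} of signal "
        f"in {len(spots)} spots after {spots.metadata['iterations']} iterations"
    )

    com = spatial.center_of_mass(nucleus)
    ref = classify.normalization_reference(
        masked, cfg.channels["dna"], "parent_surface_mean", nucleus
    )
    table = ObjectTable()
    for lv, name in ((cc, "chromocenter"), (nanocc, "nanochromocenter")):
        regions = classify.object_stats(lv, stack)
        t = export_table(regions, stack.image_id)
        table._rows.extend(t._rows)
        if regions:
            d = spatial.signed_distance_to_boundary(regions, nucleus)
            dn = spatial.normalized_radial_position(regions, nucleus, com)
            _add_distance_rows(table, stack.image_id, name, regions, d, "distance_to_nucleus")
            _add_distance_rows(
                table, stack.image_id, name, regions, dn, "normalized_radial_position", unit=""
            )
            dna_name = str(
                stack.channel_names[stack.channel_index(cfg.channels["dna"])]
            )
            norm = classify.normalize_intensity(
                [r.intensity[dna_name]["mean"] for r in regions], ref
            )
            for r, v in zip(regions, norm):
                table.add(
                    stack.image_id, name, r.label, "intensity_mean_normalized", float(v),
                    "", channel=dna_name,
                )
    if len(spots):
        t = export_table(spots, stack.image_id, object_type="rnpii_cluster")
        table._rows.extend(t._rows)
        d = spatial.signed_distance_to_boundary(spots, nucleus)
        dn = spatial.normalized_radial_position(spots, nucleus, com)
        _add_distance_rows(table, stack.image_id, "rnpii_cluster", spots.spots, d, "distance_to_nucleus")
        _add_distance_rows(
            table, stack.image_id, "rnpii_cluster", spots.spots, dn,
            "normalized_radial_position", unit="",
        )
    table.to_dataframe()
    return WorkflowResult(
        "w1_rnpii",
        table,
        labels={"nucleus": nucleus, "nucleolus": nucleolus, "cc": cc, "nanocc": nanocc},
        spots={"rnpii": spots},
        metrics={
            "captured_fraction": spots.metadata.get("captured_fraction", 0.0),
            "n_cc": cc.n_objects,
            "n_nanocc": nanocc.n_objects,
        },
        config=cfg,
        log=log,
    )


def w2_ne(stack: ImageStack, cfg: WorkflowConfig) -> WorkflowResult:
    """Nuclear-envelope clusters: NE surface, centre-of-mass reference
    frame, adaptive spots, size and peripherality curation, axial
    top/middle/bottom classes (±2 µm) and NE-surface-mean normalization."""
    _require(cfg, ("ne",))
    p = cfg.params
    log = []
    # a thin shell is a tiny foreground fraction with a bright cluster tail,
    # where Otsu fails; a high quantile plus largest-component keep is robust
    surf_p = _surface_params(
        p.get("surface", {"threshold_method": "quantile", "threshold_value": 0.9,
                          "fill_holes": False, "closing": False})
    )
    surface = seg.segment_nucleus(stack, cfg.channels["ne"], surf_p)
    surface = LabelVolume(surface.labels, surface.voxel_size, "nucleus", surface.origin)
    com = spatial.center_of_mass(surface)
    frame = spatial.ReferenceFrame(origin=com)
    log.append(f"NE surface centre of mass at {tuple(round(c, 3) for c in com)} µm")

    masked = seg.mask_channel(stack, surface)
    sp = _spot_params(p.get("spots", {"seed_diameter": 0.4, "max_diameter": 0.6}))
    seeds = seg.detect_spots(masked, cfg.channels["ne"], sp, within=surface)
    # grow/measure on the raw channel: the thin shell mask would clip the
    # blur-spread half of every polar cluster and bias class intensities
    grown = seg.grow_spots(stack, cfg.channels["ne"], seeds, sp)
    spots = classify.filter_spots(
        grown,
        max_diameter=float(p.get("max_spot_diameter", 0.6)),
        max_boundary_distance=float(p.get("max_boundary_distance", 0.5)),
        surface=surface,
    )
    log.append(
        f"{len(grown)} spots detected, {spots.metadata['removed_by_size']} removed by size, "
        f"{spots.metadata['removed_by_distance']} removed by peripherality"
    )
    spots = spatial.axial_classify(spots, frame, float(p.get("equatorial_half_width", 2.0)))

    ref = classify.normalization_reference(
        stack, cfg.channels["ne"], "parent_surface_mean", surface
    )
    ne_name = stack.channel_names[stack.channel_index(cfg.channels["ne"])]
    table = export_table(spots, stack.image_id, object_type="ne_cluster")
    by_class: dict[str, list[float]] = {"top": [], "middle": [], "bottom": []}
    for i, s in enumerate(spots):
        v = s.intensity.get(ne_name, {}).get("mean", np.nan)
        nv = v / ref
        table.add(
            stack.image_id, "ne_cluster", i + 1, "intensity_mean_normalized",
            float(nv), "", channel=ne_name, **s.class_labels,
        )
        by_class[s.class_labels["axial"]].append(nv)
    metrics = {"n_spots": len(spots)}
    polar = by_class["top"] + by_class["bottom"]
    if by_class["middle"] and polar:
        metrics["equatorial_enrichment"] = float(
            np.mean(by_class["middle"]) / np.mean(polar)
        )
    table.to_dataframe()
    return WorkflowResult(
        "w2_ne", table, labels={"ne_surface": surface}, spots={"ne": spots},
        metrics=metrics, config=cfg, log=log,
    )


def w3_meiosis(stack: ImageStack, cfg: WorkflowConfig) -> WorkflowResult:
    """Meiotic foci: permissive chromosome surface and masking, SC surface,
    200 nm-seed foci, intensity-sum tier classification (2 % / 2 % quantiles
    → T1/T2/T3) and inside/outside-SC classification."""
    _require(cfg, ("dna", "sc", "foci"))
    p = cfg.params
    log = []
    chrom = seg.segment_nucleus(
        stack, cfg.channels["dna"],
        _surface_params(p.get("chromosomes", {"threshold_method": "quantile",
                                              "threshold_value": 0.8,
                                              "keep": "all", "fill_holes": False})),
    )
    chrom = LabelVolume(
        (chrom.labels > 0).astype(np.int32), chrom.voxel_size, "chromosome", chrom.origin
    )
    masked = seg.mask_channel(stack, chrom)
    sc = seg.segment_bright_bodies(
        masked, cfg.channels["sc"], chrom,
        _surface_params(p.get("sc", {"keep": "all"})), object_type="sc_surface",
    )
    sp = _spot_params(p.get("spots", {"seed_diameter": 0.2, "max_diameter": 0.4}))
    seeds = seg.detect_spots(masked, cfg.channels["foci"], sp, within=chrom)
    spots = seg.grow_spots(masked, cfg.channels["foci"], seeds, sp, within=chrom)
    log.append(f"{len(spots)} foci detected with {sp.seed_diameter*1000:.0f} nm seed")

    foci_name = stack.channel_names[stack.channel_index(cfg.channels["foci"])]
    sums = [s.intensity.get(foci_name, {}).get("sum", 0.0) for s in spots]
    breaks = classify.QuantileBreaks(
        tuple(p.get("quantile_breaks", (0.02, 0.04))),
        tuple(p.get("tier_names", ("T1", "T2", "T3"))),
    )
    tiers = classify.quantile_classify(sums, breaks)
    for s, t in zip(spots, tiers):
        s.class_labels["tier"] = t
    spots = classify.inside_outside_classify(spots, sc)
    n_inside = sum(1 for s in spots if s.class_labels["location"] == "inside")
    log.append(f"{n_inside}/{len(spots)} foci inside the SC surface")

    table = export_table(spots, stack.image_id, object_type="focus")
    table.to_dataframe()
    tier_counts = {t: tiers.count(t) for t in breaks.names}
    return WorkflowResult(
        "w3_meiosis", table,
        labels={"chromosomes": chrom, "sc": sc}, spots={"foci": spots},
        metrics={"tier_counts": tier_counts, "n_inside_sc": n_inside, "n_foci": len(spots)},
        config=cfg, log=log,
    )


def w4_bodies(stack: ImageStack, cfg: WorkflowConfig) -> WorkflowResult:
    """Nuclear bodies and speckles: nucleus / CC / body surfaces, distance
    to the periphery, protein:DNA enrichment ratio, distance-to-CC binning
    and overlapped volume ratios."""
    _require(cfg, ("dna", "body"))
    p = cfg.params
    log = []
    nucleus = seg.segment_nucleus(stack, cfg.channels["dna"], _surface_params(p.get("nucleus")))
    cc = seg.segment_bright_bodies(
        stack, cfg.channels["dna"], nucleus, _surface_params(p.get("cc")),
        object_type="chromocenter",
    )
    bodies = seg.segment_bright_bodies(
        stack, cfg.channels["body"], nucleus, _surface_params(p.get("bodies")),
        object_type="speckle",
    )
    log.append(f"{cc.n_objects} CC, {bodies.n_objects} bodies")
    table = ObjectTable()
    body_name = stack.channel_names[stack.channel_index(cfg.channels["body"])]
    dna_name = stack.channel_names[stack.channel_index(cfg.channels["dna"])]
    for lv, name in ((cc, "chromocenter"), (bodies, "speckle")):
        regions = classify.object_stats(lv, stack)
        t = export_table(regions, stack.image_id)
        table._rows.extend(t._rows)
        if regions:
            d = spatial.signed_distance_to_boundary(regions, nucleus)
            _add_distance_rows(table, stack.image_id, name, regions, d, "distance_to_nucleus")
    body_regions = classify.object_stats(bodies, stack)
    if body_regions and cc.n_objects:
        ratios, flagged = classify.intensity_ratio(body_regions, body_name, dna_name)
        bins = classify.distance_bin_classify(
            body_regions, cc, p.get("distance_bins", (0.5, 1.0))
        )
        for r, ratio, b, fl in zip(body_regions, ratios, bins, flagged):
            table.add(
                stack.image_id, "speckle", r.label, "enrichment_ratio", float(ratio),
                "", channel=f"{body_name}:{dna_name}", distance_to_cc_class=b,
                flagged=bool(fl),
            )
        overlaps = spatial.pair_by_overlap(bodies, cc)
        for la, lb, ratio in overlaps:
            table.add(
                stack.image_id, "speckle", la, "overlap_ratio_cc", float(ratio), "",
                channel="", paired_cc=lb if lb is not None else -1,
            )
    table.to_dataframe()
    return WorkflowResult(
        "w4_bodies", table,
        labels={"nucleus": nucleus, "cc": cc, "bodies": bodies},
        metrics={"n_cc": cc.n_objects, "n_bodies": bodies.n_objects},
        config=cfg, log=log,
    )


def w5_chromosome(stack: ImageStack, cfg: WorkflowConfig) -> WorkflowResult:
    """Metaphase chromosome compaction: chromosome surface, masked FISH
    region surfaces, volumes and Mb/µm³ compaction densities."""
    _require(cfg, ("dna",), ("probes",))
    p = cfg.params
    log = []
    chrom = seg.segment_nucleus(stack, cfg.channels["dna"], _surface_params(p.get("chromosome")))
    masked = seg.mask_channel(stack, chrom)
    table = ObjectTable()
    densities = {}
    for probe_cfg in p["probes"]:
        probe = classify.ProbeAnnotation(
            probe_cfg["name"], float(probe_cfg["mb"]), probe_cfg["channel"]
        )
        region_lv = seg.segment_bright_bodies(
            masked, probe.channel, chrom, _surface_params(p.get("fish")),
            object_type="fish_region",
        )
        regions = classify.object_stats(region_lv, stack)
        if not regions:
            log.append(f"probe {probe.name}: no FISH region found")
            continue
        region = max(regions, key=lambda r: r.volume)
        density = classify.compaction_density(region, probe)
        densities[probe.name] = density
        table.add(stack.image_id, "fish_region", probe.name, "volume", region.volume, "µm³")
        table.add(stack.image_id, "fish_region", probe.name, "genomic_span", probe.mb, "Mb")
        table.add(
            stack.image_id, "fish_region", probe.name, "compaction_density", density, "Mb/µm³"
        )
        log.append(
            f"probe {probe.name}: V={region.volume:.3g} µm³, {density:.3g} Mb/µm³"
        )
    table.to_dataframe()
    return WorkflowResult(
        "w5_chromosome", table, labels={"chromosome": chrom},
        metrics={"densities": densities}, config=cfg, log=log,
    )


def w6_rabl(stack: ImageStack, cfg: WorkflowConfig) -> WorkflowResult:
    """Centromere/telomere positioning: CEN and TEL spots (~300 nm seed),
    nucleus surface, shortest CEN–TEL distance, distance to the surface,
    mean distance to the 5 nearest same-class neighbours, normalized by the
    nucleus equivalent diameter (and radius)."""
    _require(cfg, ("dna", "cen", "tel"))
    p = cfg.params
    log = []
    nucleus = seg.segment_nucleus(stack, cfg.channels["dna"], _surface_params(p.get("nucleus")))
    sp = _spot_params(p.get("spots", {"seed_diameter": 0.3, "max_diameter": 0.6}))
    cen = seg.detect_spots(stack, cfg.channels["cen"], sp, within=nucleus)
    tel = seg.detect_spots(stack, cfg.channels["tel"], sp, within=nucleus)
    log.append(f"{len(cen)} CEN spots, {len(tel)} TEL spots")

    vol = list(nucleus.volumes().values())[0]
    eq_diam = (6.0 * vol / np.pi) ** (1.0 / 3.0)
    eq_rad = eq_diam / 2.0
    k = int(p.get("k_neighbors", 5))
    table = ObjectTable()
    for spots, name, other in ((cen, "cen", tel), (tel, "tel", cen)):
        if not len(spots):
            continue
        t = export_table(spots, stack.image_id, object_type=name)
        table._rows.extend(t._rows)
        d_surf = spatial.signed_distance_to_boundary(spots, nucleus)
        _add_distance_rows(table, stack.image_id, name, spots.spots, d_surf, "distance_to_surface")
        _add_distance_rows(
            table, stack.image_id, name, spots.spots, np.abs(d_surf) / eq_rad,
            "distance_to_surface_norm_radius", unit="",
        )
        if len(other):
            d_cross = spatial.shortest_cross_distance(spots, other)
            _add_distance_rows(
                table, stack.image_id, name, spots.spots, d_cross, "shortest_cen_tel_distance"
            )
            _add_distance_rows(
                table, stack.image_id, name, spots.spots, d_cross / eq_diam,
                "shortest_cen_tel_distance_norm_diameter", unit="",
            )
        if len(spots) >= 2:
            means, flagged = spatial.knn_mean_distance(spots, k=k)
            _add_distance_rows(
                table, stack.image_id, name, spots.spots, means, f"mean_distance_{k}_neighbors"
            )
            _add_distance_rows(
                table, stack.image_id, name, spots.spots, means / eq_diam,
                f"mean_distance_{k}_neighbors_norm_diameter", unit="",
            )
    table.to_dataframe()
    return WorkflowResult(
        "w6_rabl", table, labels={"nucleus": nucleus}, spots={"cen": cen, "tel": tel},
        metrics={"n_cen": len(cen), "n_tel": len(tel), "nucleus_volume": vol},
        config=cfg, log=log,
    )


def w7_angle(stack: ImageStack, cfg: WorkflowConfig) -> WorkflowResult:
    """Division-angle measurement: optional ROI crop, cell-wall and
    chromosome-plate segmentation, automated or manual measurement axes and
    the 3D angle between the pulling and elongation axes."""
    _require(cfg, ("chromatin",))
    p = cfg.params
    log = []
    if "roi" in p:
        stack = seg.crop_roi(stack, p["roi"])
        log.append(f"cropped ROI to shape {stack.shape}")

    if "measurement_points" in p:
        mp = p["measurement_points"]
        axes = spatial.DivisionAxes(
            A=tuple(mp["A"]), A_prime=tuple(mp["A_prime"]),
            B=tuple(mp["B"]), C=tuple(mp["C"]),
        )
        labels = {}
        log.append("using manual measurement points")
    else:
        wall_p = _surface_params(p.get("wall", {"fill_holes": False, "closing": False,
                                                "keep": "largest"}))
        wall = seg.segment_nucleus(stack, cfg.channels["chromatin"], wall_p)
        from scipy import ndimage as ndi

        cell_mask = ndi.binary_fill_holes(wall.mask)
        cell = LabelVolume(
            cell_mask.astype(np.int32), stack.voxel_size, "cell", stack.origin
        )
        interior = cell_mask & ~ndi.binary_dilation(wall.mask, iterations=2)
        ch = stack.channel(cfg.channels["chromatin"])
        plate_p = _surface_params(
            p.get("plates", {"threshold_method": "quantile", "threshold_value": 0.9,
                             "min_volume": 0.2, "keep": "all", "fill_holes": False})
        )
        interior_lv = LabelVolume(
            interior.astype(np.int32), stack.voxel_size, "cell", stack.origin
        )
        plates = seg.segment_bright_bodies(
            stack, cfg.channels["chromatin"], interior_lv, plate_p,
            object_type="chromosome",
        )
        # retain the two largest plates (labels are volume-ordered)
        lab = np.where(plates.labels <= 2, plates.labels, 0).astype(np.int32)
        plates = LabelVolume(lab, stack.voxel_size, "chromosome", stack.origin)
        axes = spatial.estimate_division_axes(plates, cell)
        labels = {"cell": cell, "plates": plates}
        log.append("estimated axes from plate centroids and cell principal axis")

    pair = tuple(p.get("angle_pair", ("pulling", "elongation")))
    angle = spatial.division_angle(axes, pair)
    log.append(f"division angle ({pair[0]} vs {pair[1]}): {angle:.2f}°")
    table = ObjectTable()
    table.add(stack.image_id, "cell", 1, f"division_angle_{pair[0]}_{pair[1]}", angle, "deg")
    for name, pt in (("A", axes.A), ("A_prime", axes.A_prime), ("B", axes.B), ("C", axes.C)):
        for ax, v in zip("zyx", pt):
            table.add(stack.image_id, "cell", 1, f"point_{name}_{ax}", float(v), "µm")
    table.to_dataframe()
    return WorkflowResult(
        "w7_angle", table, labels=labels, metrics={"division_angle_deg": angle},
        config=cfg, log=log,
    )


_DISPATCH = {
    "w1_rnpii": w1_rnpii,
    "w2_ne": w2_ne,
    "w3_meiosis": w3_meiosis,
    "w4_bodies": w4_bodies,
    "w5_chromosome": w5_chromosome,
    "w6_rabl": w6_rabl,
    "w7_angle": w7_angle,
}


def run_workflow(
    name: str,
    config: WorkflowConfig | dict,
    inputs: ImageStack | str,
    outdir=None,
) -> WorkflowResult:
    """Run one named workflow on a stack (or a path to one).

    The config is validated against the workflow's required keys; all label
    volumes, spot classifications and the long-format table are produced and
    optionally written under ``outdir`` with a YAML config sidecar.
    """
    if name not in _DISPATCH:
        raise ValueError(f"unknown workflow {name!r}; choose from {WORKFLOW_NAMES}")
    if isinstance(config, dict):
        config = WorkflowConfig.from_dict({"workflow": name, **config})
    stack = inputs if isinstance(inputs, ImageStack) else load_stack(inputs)
    result = _DISPATCH[name](stack, config)
    if outdir is not None:
        result.write(outdir)
    return result
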