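# nucspat3d

Quantitative 3D image analysis of nuclear and chromosomal spatial
organization, for cell biologists working with multi-channel fluorescence
stacks (confocal, Airyscan, SIM, STED).

Studies of chromatin and nucleus organization routinely need numbers that
qualitative inspection cannot give: how bright and how large are
chromocenters, nuclear speckles or recombination foci; how deep inside the
nucleus do they sit; do centromeres and telomeres cluster at opposite poles
(the Rabl configuration); how compact is a FISH-painted chromosome region;
at what angle are anaphase chromosomes pulled relative to the cell's
elongation axis.  `nucspat3d` implements seven such analysis workflows as an
open library plus CLI, together with a synthetic 3D scene generator that
provides exact ground truth, so every operation is testable without any
microscope data.

## What it computes

Segmentation (threshold-based surfaces, Laplacian-of-Gaussian spot seeds,
adaptive "growing spots") produces label volumes and spot sets from which
the library measures:

- **signed distance to the nuclear periphery** `d(p)` — anisotropy-aware
  Euclidean distance to the mask boundary, negative inside, 0 at the
  boundary — and the normalized radial position
  `d_norm(p) = d(p) / |d(com)|`, so the centre of mass maps to −1 and the
  periphery to 0;
- **axial classes** (top / middle / bottom) relative to a reference frame at
  a surface's centre of mass, with the equatorial band `|z′| ≤ 2 µm`;
- **quantile intensity tiers** — ranking objects by intensity sum and
  cutting at cumulative fractions (default 2 % / 2 % / rest → T1, T2, T3);
- **shortest cross distances** (e.g. centromere→telomere), **mean distance
  to the k = 5 nearest same-class neighbours**, both optionally normalized
  by the nucleus equivalent diameter `(6V/π)^(1/3)`;
- **overlapped volume ratio** `|A∩B| / |A|` between nuclear bodies;
- **chromatin compaction density** `ρ = Mb / V` in Mb/µm³ from the genomic
  span of a FISH probe and the measured 3D volume of its painted domain;
- **3D division angle** between the chromosome pulling axis (through the
  two anaphase-plate centroids) and the cell elongation axis (principal
  axis of the cell mask), folded to [0°, 90°].

Everything is exported as a long-format CSV
(`image_id, object_type, object_id, variable, channel, value, unit, …`)
with a YAML sidecar recording every parameter of the run.

## Worked example

Segment a synthetic interphase nucleus and capture its polymerase signal
with the iterative growing-spot procedure:

```python
from nucspat3d import scenes, segmentation as seg
from nucspat3d.segmentation import SpotParams
from nucspat3d.workflows import run_workflow

stack, truth = scenes.make_interphase_scene(seed=1)      # 2 channels + ground truth
nucleus = seg.segment_nucleus(stack, "dna")
masked = seg.mask_channel(stack, nucleus)
spots = seg.iterative_spot_capture(
    masked, "rnpii", nucleus,
    SpotParams(seed_diameter=0.2, grow_fraction=0.5, capture_target=0.8),
)
meta = spots.metadata
print(f"nucleus volume: {list(nucleus.volumes().values())[0]:.1f} um3")
print(f"captured {100*meta['captured_fraction']:.1f}% of polymerase signal "
      f"in {len(spots)} spots ({meta['iterations']} iterations)")

stack7, t7 = scenes.make_anaphase_scene(angle=30.0, seed=3)
res = run_workflow("w7_angle", {"channels": {"chromatin": "chromatin_wall"}}, stack7)
print(f"division angle: {res.metrics['division_angle_deg']:.2f} deg (true {t7.division_angle_deg:.0f})")
```

prints

```
nucleus volume: 61.1 um3
captured 82.8% of polymerase signal in 1267 spots (3 iterations)
division angle: 29.97 deg (true 30)
```

The nucleus volume is the voxel count times the voxel volume (the true
ellipsoid is 62.8 µm³); the capture fraction is the share of in-nucleus
polymerase intensity that ends up inside grown spot regions; the division
angle is recovered from the rendered image alone, within a fraction of a
degree of the angle the scene was built with.

## Command line

```sh
nucspat3d fixtures --outdir fixtures/ --seed 1        # synthetic test gallery
nucspat3d w6_rabl --config cfg.yaml --input nucleus.ome.tif --outdir out/
```

One subcommand per workflow (`w1_rnpii`, `w2_ne`, `w3_meiosis`,
`w4_bodies`, `w5_chromosome`, `w6_rabl`, `w7_angle`); a directory as
`--input` runs batch mode.  Inputs are TIFF / OME-TIFF with voxel sizes in
µm; convert proprietary formats (.ims, .czi, .lif) to OME-TIFF first.

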