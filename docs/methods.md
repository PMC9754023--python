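# Methods

## Coordinate and distance conventions

Voxel grids are indexed `(z, y, x)`, channel first for multi-channel
stacks.  The physical coordinate of a voxel is its centre,
`(index + 0.5) · voxel_size + origin`, in µm.  Anisotropy is carried, never
resampled away: every distance weights axes by the voxel size, because
confocal stacks are almost always coarser axially than laterally.  ROI
cropping records an origin offset so absolute coordinates survive the crop.

The boundary of a mask is its set of foreground voxels 6-adjacent to
background (image edges count as background, so truncated objects have a
boundary there).  Signed distances are measured to boundary-voxel centres —
for point queries via a kd-tree over those centres, which is *exactly* the
brute-force minimum; for voxel maps via a sampled Euclidean distance
transform of the boundary set, so the two routes agree to machine
precision.  The sign convention is negative inside, 0 on boundary voxels,
positive outside: interior structures plot at negative
distance-to-periphery.  The normalized radial position divides by the
centre-of-mass depth, mapping the centre of mass to −1 and the boundary
to 0; values below −1 are possible in aspherical nuclei and are reported
as-is.  A surface whose centre of mass lies within one voxel of its own
boundary (a sheet, a torus) has no meaningful normalization and is
rejected.

## Surface segmentation

Surfaces (nucleus, nucleolus, chromocenters, bodies, chromosomes, cell
wall) are Gaussian pre-smooth (default sigma = one finest-axis voxel) →
threshold → optional hole filling → connected components, ordered by
decreasing volume with ties broken by scan order, so segmentation is fully
deterministic.  Thresholds are always computed *inside* the parent mask:

- `otsu` (default) — appropriate when foreground and background both occupy
  a substantial fraction of the region;
- `quantile` — for thin structures such as a nuclear-envelope shell, where
  the foreground fraction is small and a bright-cluster tail drags Otsu
  into the wrong mode;
- `absolute` — the user-supervised route: like any threshold-based
  pipeline, per-dataset tuning is expected, and the chosen value is
  recorded in the config sidecar.

The nucleolus is the largest low-intensity cavity strictly inside the
nucleus: components of the low mask touching the nucleus boundary are
excluded, so invaginations open to the outside never count.  Its default
threshold is a **two-stage Otsu** over in-nucleus intensities: the first
cut splits off bright heterochromatin, the second separates cavity from
nucleoplasm.  A plain Otsu fails here because the in-nucleus histogram is
trimodal.  An empty result is valid — not every nucleus resolves a
nucleolus.

Manual masks drawn elsewhere can be imported as label TIFFs and used
wherever a segmented surface is expected; the library itself is fully
automated because it cannot assume interactive contour drawing.

Touching bright bodies are *not* declumped (no watershed); they merge into
one label.  The chromocenter / nanochromocenter split is a pure volume
partition at a configurable cutoff (default 0.1 µm³), applied after
segmentation, so `|CC| + |nanoCC| = |bodies|` always.

## Spot detection and growing spots

Point-like signals are detected as local maxima of a scale-matched,
negated Laplacian-of-Gaussian response (sigma = seed radius / √3 per axis,
in voxels), with non-maximum suppression at one seed diameter and
lexicographic tie-breaking.  The seed diameter is the biological prior:
0.2 µm for recombination foci, 0.3 µm for FISH signals, 0.4–0.6 µm for
envelope clusters.

When no explicit quality threshold is given, the automatic threshold is a
robust noise floor (median + 5 MAD of the in-region response) with two
policies:

- **strict** (default, for punctum identification): the floor is raised to
  1.1× the magnitude of the strongest *negative* response excursion.  Under
  symmetric noise the negative tail estimates the null distribution of the
  response, so anything above it is a genuine blob; a noise-only channel
  yields at most a handful of stray maxima.  The factor 1.1 compensates the
  positive skew introduced by clipping intensities at zero.  A final
  refinement drops the dim candidate group when an Otsu split of candidate
  qualities shows strong bimodality (bright group ≥ 4× the dim group) —
  this removes structured-background ripple (e.g. on a bright envelope
  shell) without touching scenes where all spots are genuinely similar.
- **permissive** (used by iterative capture): MAD floor only, because the
  goal there is exhaustive signal coverage, not individual punctum calls.

"Growing spots" expand each seed by fraction-of-peak region growing: the
local peak is located within the seed sphere, voxels at or above
`grow_fraction × peak` (default 0.5, a FWHM analogue) are candidates,
contested voxels go to the nearest peak, and the spot keeps the connected
component containing its peak.  The recorded radius is the grown region's
equivalent-sphere radius, floored at the seed radius and capped at
`max_diameter / 2`.  The size filter for envelope clusters is applied on
this grown diameter, boundary inclusive (≤ 0.6 µm).  A reported cluster
volume near 1 µm³ for a 0.6 µm spot is geometrically impossible for a
sphere (0.113 µm³); the filter therefore acts on diameter only.

Iterative capture repeats (detect on the residual → grow → zero captured
voxels) until the captured fraction of in-mask channel intensity reaches
the target (default 0.8) or the iteration cap (default 10).  Because each
pass removes the cores of the brightest structures, later passes pick up
their flanks and the brighter parts of the diffuse background; the
achieved fraction and iteration count are returned as metadata and are the
pipeline's headline quantity.

## Classifications, normalization, compaction

Quantile tiers rank objects by intensity sum (mean available) in
descending stable order; class sizes are `ceil(fᵢ·n)` cumulatively, so the
top class is non-empty for any n ≥ 1 and sizes depend only on n and the
breaks, never on the values.  Quantiles are computed per image, not pooled
across images.  Inside/outside classification uses the spot's centre
voxel, consistent with the sign convention (boundary voxels count as
inside).  Distance-to-reference binning is left-inclusive, with distance 0
for objects touching or inside a reference region.

Intensity normalization divides by an explicit reference — image mean,
parent-surface mean, or channel maximum — recorded with the result; all
normalized quantities and ratios are invariant under a global gain change,
which the tests assert.  A zero denominator flags the row rather than
dropping it.

Compaction density is the probe's genomic span divided by the measured
domain volume, Mb/µm³; volumes are voxel counts times the voxel volume.

## Division axes

The pulling axis runs through the two anaphase-plate centroids; the
elongation axis is the principal axis of the cell mask (eigenvector of the
voxel-coordinate covariance).  A cell whose two leading eigenvalues differ
by less than 1.2× has no well-defined elongation axis and is rejected
rather than silently measured.  Angles are between undirected axes, folded
to [0°, 90°], invariant to endpoint swaps and global rotations.  Manual
measurement points (A, A′, B, C in µm) are accepted via the config as an
alternative route; because conventions for which pair defines the angle
vary, the axes are *named* (pulling, elongation, reference) and the pair is
configurable, defaulting to (pulling, elongation).

## The synthetic scene generator

Every workflow has a phantom scene with serialized ground truth.  The
imaging model is: Gaussian PSF blur (axial sigma ≥ lateral; defaults
0.15 / 0.06 µm), additive background (2 a.u.), Poisson shot noise on
signal + background, then Gaussian read noise (sd 2).  Default voxel size
0.1 × 0.05 × 0.05 µm.  All randomness comes from one seeded generator, so
identical (parameters, seed) give bit-identical stacks.

Scene contrasts were chosen to emulate stained nuclei at super-resolution
scale: nucleoplasm 40 a.u., chromocenters +160 (radius 0.35–0.45 µm),
nanochromocenters +120 (radius 0.16–0.19 µm), nucleolar cavity 8;
polymerase clusters (n = 150 by default) with amplitudes 100–300 and
lateral sigmas 0.08–0.2 µm over a reticulate background of 20 a.u.
covering ~40 % of the nucleoplasm, so clusters carry the dominant share of
the channel's intensity, as they do in stained material.  Objects are
placed by rejection sampling with separation constraints that prevent
distinct bodies from merging under the PSF; infeasible requests raise
rather than silently overlapping.  The meiotic scene uses seven smooth
axis stretches so that 240 foci fit along them at 0.2 µm spacing; foci
amplitudes come in well-separated tiers (600 / 300 / 100 a.u.).  The
envelope scene doubles spot amplitudes inside the |z′| ≤ 2 µm equatorial
band (factor 1 = null scene) and keeps spots 0.2 µm clear of the band edge
so their true class is unambiguous under blur.  The chromosome scene is a
cylinder with painted sub-intervals of *analytically* known volume; the
anaphase scene is a capsule-shaped cell with wall autofluorescence and two
plates at an exact requested angle.

What the phantoms deliberately do not model: a realistic optical PSF
(plain Gaussian instead), reconstruction artefacts of SIM/STED processing,
intensity calibration (all units are arbitrary), and the true generative
process of the polymerase reticulum — the band-pass-noise reticulum is a
stand-in with the right visual statistics, not a biophysical model.
Passing tests therefore demonstrate correctness of the measurement
operations and recoverability of known geometry under blur and shot noise;
they do not certify segmentation quality on any particular real dataset,
where thresholds must be tuned per the supervised route above.

## Problem sizes and numerical choices

Default scenes are 0.9–2.5 million voxels per channel — large enough that
every structure spans many voxels in all axes, small enough that the whole
suite runs in about a minute.  Recovery accuracies on these scenes: nucleus
volume within 5 % of the analytic ellipsoid, nucleolus within 10 %,
chromocenter / nanochromocenter counts exact, spot recall and precision
≥ 0.95 at peak SNR 5, envelope enrichment factor within 15 %, division
angles within 2° across 0–60°, compaction densities within 10 % with the
interstitial : subtelomeric contrast preserved.

Degenerate inputs fail loudly: empty masks after thresholding report the
threshold used; an all-background channel yields an empty spot set; a
singleton spot set has no neighbour statistics; zero-length measurement
lines, empty overlap numerators and non-positive normalization references
are errors, not NaNs.  Spots with fewer than k neighbours use all and are
flagged rather than dropped.

## Known limitations

- Thresholds ported to real images need per-dataset adjustment; the
  defaults are calibrated to the phantom contrasts.
- No declumping of touching bodies and no machine-learning segmentation.
- Deconvolution / SIM reconstruction are out of scope; inputs are assumed
  already reconstructed.
- Statistical comparison across conditions (rank tests, multiple-testing
  control) is left to downstream tools; the CSV export is designed for
  that hand-off.
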