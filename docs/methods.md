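# Methods

This note records the models, conventions and design choices behind
`stereobench`, in the order the pipeline runs.

## Coordinate and rounding conventions

Voxel indices are 0-based; the physical position of a voxel is
`index * spacing` in μm with no half-voxel offset, `spacing = (dx, dy, dz)`.
Arrays are indexed `[z, y, x]`, matching multi-page TIFF plane order.
Rates rendered in reports are rounded half away from zero (153/155 → 0.99,
1191/1344 → 0.89, 36/96 = 0.375 → 0.38); this convention is validated cell
by cell against the shipped benchmark count table.

## Synthetic stack generator

The generator's job is to emulate the statistical structure of thick-section
microscopy — not its optics.  Cells are axis-aligned ellipsoids with per-cell
radii drawn uniformly from stated ranges; the defaults (XY radius 2.0–2.5 μm,
Z radius 2.0–2.5 μm) correspond to nuclei with a 4–5 μm XY diameter, the
scale the matching tolerance is also anchored to.  Arbitrary orientations and
non-ellipsoidal shapes are out of scope; the size/shape/orientation argument
for stereologic counting is handled abstractly in the stereology module.

**Placement** is hard-core rejection sampling (uniform candidate centers,
rejected when closer than `min_separation` to an accepted center; 2000
attempts per cell before an explicit `PlacementError`).  Setting
`clustering = σ_c` switches to a Thomas process: ⌈n/5⌉ uniform parents, each
cell placed at a parent plus isotropic Normal(0, σ_c²) offset, still subject
to the hard core.  With `allow_boundary_cut = False` centers are constrained
so the rasterized support stays strictly off the stack faces (margin of one
radius plus 0.51 voxel per axis).

**Rendering**: the ellipsoid indicator (per-cell amplitude drawn from
`intensity_range`) is convolved with an anisotropic Gaussian
(`lateral_blur_sd` = 0.3 μm, `axial_blur_sd` = 1.0 μm by default) standing in
for the out-of-focus axial blur of widefield imaging; then background offset
(0.08), optional Poisson shot noise, and additive Gaussian noise (sd 0.02)
are applied and the stack is quantized to 8 bits (16 optional), rounding
half up.  Brightfield stacks blend a bright near-neutral background RGB
(0.90, 0.88, 0.86) toward a DAB-brown stain color (0.45, 0.28, 0.14) in
proportion to the blurred stain intensity: cells are darker than background
in the red channel but brighter in red chromaticity, so both preprocessing
paths are exercised.

**Ground truth**: one marker per placed cell at the voxel-mean centroid of
its true support; a property test verifies this lies within 0.5 voxel per
axis of the analytic ellipsoid center for interior cells.  The boundary flag
is defined as "the labeled support touches one of the six stack faces",
which is measurable from the delivered label volume and agrees with a
brute-force face scan by construction.  (An alternative definition — "the
analytic extent leaves the stack bounds" — differs only on the
measure-zero-in-practice case of a support that reaches a face voxel without
crossing it; the face-scan definition was chosen because it matches what an
annotator marking "cells that intersect the image boundary" can observe.)

**Seeding**: one master seed is split via `numpy.random.SeedSequence` into
four fixed streams (placement, cell geometry, pixel noise, brightfield
rendering), so `sample_population` can re-derive the analytic population
independently and identical inputs give bit-identical stacks.

What the generator does *not* emulate: stain spectra, vignetting,
flat-field error, tissue shrinkage, textured chromatin, irregular somata.
Passing tests therefore demonstrate correctness of the evaluation machinery
and qualitative detector behavior (merging under crowding, noise
sensitivity), not detector performance on real tissue.

## Preprocessing

Red chromaticity is `r = R/(R+G+B)` per voxel, with `r = 0` at
`R = G = B = 0` (black is background in a brightfield context); it is kept
real-valued in [0, 1] internally and scaled to the stack bit depth (round
half up) when exported for the detector.  Red inversion is
`(2^d − 1) − R`.  Smoothing is a separable Gaussian with per-axis sigmas in
*voxel* units (the benchmark used σ = (2, 2, 1) as a camera-noise filter,
deliberately independent of optical resolution), reflect boundary handling,
kernels truncated at 4σ — standard, mass-conserving choices.  The CLI
applies color conversion first and smoothing second, and records the order
in the output sidecar.

## Baseline detector

Foreground is `intensity ≥ threshold` (inclusive, the common ImageJ
convention).  Connected components default to 26-connectivity (blob-like
cells; 6 and 18 selectable), with labels compacted in raster-scan
first-voxel order for deterministic output.  The size filter removes regions
*strictly* smaller than `min_voxels` — "much smaller than a typical cell"
argues for keeping the boundary case.  The benchmark's voxel-count filters
translate to physical volumes as `min_voxels · dx · dy · dz`: 1000 voxels at
the 0.102134 × 0.101507 × 0.5 μm spacing is 5.2 μm³ and 25 voxels at
0.46056 × 0.46056 × 1.0 μm is 5.3 μm³, which ties each filter to the
spacing it belongs with.  No maximum-size filter and no split/merge
post-processing are provided: the baseline's under-segmentation of touching
cells is a finding, not a bug.

## Matching and rates

Matching is a single greedy pass over ground-truth markers in input order
(a canonical `sorted` order is available since greedy results can be
order-dependent).  A detection is eligible if its lateral distance is
≤ r_xy *and* its axial offset is ≤ r_z — a cylinder, reflecting the lower
axial precision of light microscopy.  "Nearest" among eligible detections is
the normalized elliptic distance √((Δxy/r_xy)² + (Δz/r_z)²) (plain Euclidean
selectable); ties break to the lowest detection id; matched detections are
consumed.  Greedy N_tp is bounded by the optimal assignment (verified
against a Hungarian-algorithm oracle) and equals it whenever lateral
ground-truth spacing exceeds 2·r_xy, because then no detection is eligible
for two cells.

Defaults: r_xy = 3 μm; r_z = 1.5 μm, except 2.0 μm for the coarse-spacing
low-NA condition ("3B").  The manual ground-truth z convention (median
in-focus plane) differs from the voxel-mean z of automated centroids by
less than the axial tolerance, which absorbs it.

Rates are exact rational divisions, `R_tp = N_tp/N_gt`, `R_fp = N_fp/N_s`;
zero denominators yield 0 with a warning.  Stratified rates split N_gt into
interior cells (R_tpi over N_gti) and boundary-touching cells (R_tpb over
N_gt − N_gti); boundary cells are matched like any others.

**Combination.**  Union: a ground-truth cell is a TP if either method found
it; pooled false positives are deduplicated by greedy nearest pairing within
the same cylinder tolerance (one combined FP per pair) — a no-dedup variant
is available, since the published combined rates cannot be reconstructed
exactly and merging is the conservative reading.  Intersection: TP iff TP in
both; FPs are mutually-close pairs, one per pair.  The combined N_s is
defined as N_tp + N_fp of the combined result, preserving the count
identity N_tp + N_fp = N_s that every result object enforces.

## Reference dataset

`stereobench.datasets` ships the published per-method benchmark counts
verbatim.  Auditing the table against its own arithmetic found three rows
whose printed cells are inconsistent with their printed counts (one R_tp off
by 0.01, one R_fp off by 0.01, and one N_tp that violates
N_tp + N_fn = N_gt); they are flagged as `PRINT_DISCREPANT_ROWS`, kept
verbatim, and excluded from the exact-reproduction checks, which cover the
remaining 21 complete rows.  Three detector-default rows with false-positive
rates of 0.89–0.98 are flagged as the complete segmentation failures the
original analysis disregarded; rate extrema are computed accordingly
(true-positive extrema over all complete best-method rows: 38–99 %;
false-positive minimum over non-failure rows: 3.6 %).

## Stereology

The counting frame uses the classic convention: exclusion lines are the left
edge (extended infinitely upward from the top-left corner) and the bottom
edge (with the downward extension at the bottom-right corner); top and right
edges are inclusion edges.  A profile is counted iff part of it lies inside
the frame and it touches no exclusion line; touching counts as exclusion.
Cells are circular footprints for the frame rule and carry an explicit
`top_z` (None when the top lies in the section above); the UVCS rule counts
a cell iff the frame rule accepts it *and* `z_top ≤ top_z ≤ z_bottom`.
Guard zones are configuration (defaults leave them above and below the
UVCS); which edges are exclusion edges is likewise configurable but fixed to
the conventional choice.

The fractionator estimate is the standard product
`N̂ = Q / (ssf · asf · hsf)`.  The unbiasedness simulation uses modular
arithmetic for section and grid sampling (a point is in a sampled frame iff
its coordinates fall in a half-open window of the random-offset tiling),
which makes inclusion probabilities exactly the design fractions; over 200
replicates of a 2000-point uniform population the mean estimate sits within
two standard errors of the truth.

The profile-count bias demonstration places equal numbers of spheres of
diameter d and 2d uniformly in a cube of side L and cuts a section of
thickness t: expected profile counts are n(d + t)/L, so doubling the
diameter inflates them by (2d + t)/(d + t) while UVCS counts (tops in a
fixed-height disector) are unchanged — the reason profile counting cannot
distinguish cell number from cell size.

## Problem sizes

The default test and acceptance runs use stacks scaled to 256 × 256 × 30
voxels on the fine-spacing geometry (26 × 26 × 15 μm) with 20 cells for
recovery checks, 200 × 200 × 30 with 25 cells for the crowding series, and
160 × 160 × 20 with 8 cells for the combination runs; marker-level
simulations use up to 100 markers and the stereology simulations 200
replicates of 2000 points.  These sizes exhibit every behavior of interest
(full recovery when well-separated, progressive merging when crowded) while
keeping a full run on a single core in minutes; the full-size preset
geometries (up to 1600 × 1200 × 45) are available unchanged through the same
API.

## Known limitations

* The generator's ellipsoid-plus-Gaussian-blur model has no texture, so
  thresholding is easier than on real stained tissue; absolute rates on
  synthetic stacks are optimistic by construction.
* Greedy matching is order-dependent in crowded configurations; the sorted
  order makes runs canonical but does not make greedy optimal.
* The published combined (union) rates use an unknown duplicate rule and are
  therefore shipped as context, not reproduced.
* Volumetric overlap metrics (IoU/Dice) are deliberately absent: the
  evaluation is centroid-based, and segmentation-extent errors appear only
  through displaced centroids.
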