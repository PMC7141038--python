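# Methods

## The measurement

A spheroid-outgrowth assay is read out from a single-channel f-actin
stack as four voxel classes — background, core, collective outgrowth,
single-cell outgrowth — and per-class radial distance histograms.
The defining rule is topological: outgrowth connected (under a declared
voxel connectivity) to the component that contains the spheroid center is
collective; disconnected foreground is single-cell. Everything else in
the pipeline exists to make that rule well-posed on real images:
segmentation chooses the foreground, core estimation chooses the center
and the core/outgrowth boundary, and the histogram turns per-voxel
distances into the familiar bar-plot readout.

## Segmentation

`segment_foreground` applies a global threshold — Otsu by default
(parameter-free), or a fixed value for controlled experiments and
synthetic data where the two intensity levels are known. The mask keeps
voxels *strictly above* the threshold. An optional Gaussian pre-smoothing
(`smooth_sigma`, voxels, default 0) exists for very noisy data but is off
by default because blurring systematically thins structures near the
sprout width (≈3 voxels).

Degenerate inputs raise: a constant image cannot be Otsu-thresholded
("degenerate histogram"), and an empty mask is "no foreground" rather
than a silent zero result.

## Center and core

The spheroid center is the voxel of maximal Euclidean distance transform
(EDT, computed with the physical voxel spacing) within the largest
foreground component; ties break to the lowest lexicographic index. This
is robust to asymmetric sprouts that would drag a centroid off-center.
The core radius estimate is the EDT maximum — the radius of the largest
inscribed ball — and the core mask is the connected foreground strictly
inside that ball around the center. The strict `<` comparison matters: a
one-voxel-wide arm whose first voxel sits exactly at the inscribed radius
is outgrowth, not core.

For the EDT only, the mask is regularized by a fill-only neighbor
majority vote (a background voxel becomes foreground when at least half
of its 3^ndim−1 neighbors are foreground) followed by binary hole
filling. Without this, a single unstained voxel inside or on the surface
of the spheroid (noise drop-out, lumen) collapses the EDT maximum and
with it the core/outgrowth split. The operation is purely additive, so
thin sprouts and single cells are never eroded, and the classification
mask itself is never altered: on a noise-free two-level image the whole
pipeline reproduces generator ground truth exactly, while at a
contrast-to-noise ratio of 5 the radius estimate stays within ~0.1 voxel
of its noise-free value.

One spheroid per field is the assay design; if several blobs are present
the largest is used and a warning is logged.

## Classification, distances, histogram

`classify_migration` labels the component of the mask containing the
center (scipy `ndimage.label` with the requested connectivity; default 26
in 3D / 8 in 2D, the most permissive standard choice so diagonally
touching sprout voxels stay collective). Distances default to the
*center* reference; `surface` mode subtracts the estimated core radius
(negative values are clipped into the first bin when histogramming, so
counts always conserve). Bins are uniform, half-open and lower-inclusive,
default width 10 px — coarse enough for stable bars, configurable.
`min_single_size` (default 1 = off) drops single-cell objects below a
voxel count; with noisy images a value of ~5 removes the isolated
speckle false positives expected from thresholding (at contrast/noise = 5
a background voxel crosses the midpoint threshold with p ≈ 0.006,
producing hundreds of size-1 objects in a 128×128×16 stack but
essentially no size-5 ones).

`quantify_stack` composes the stages and returns every intermediate
artifact. `mode="mip"` first collapses the stack by maximum-intensity
projection; both modes are supported because acquired z-stacks can
reasonably be analysed either way, and the mode is always logged.

## Synthetic data generator

`generate_spheroid_stack` emulates the assay's imaging: a bright ball
(the ≈750-cell microtissue core) at the image center, straight
cylindrical sprouts seeded at the core with isotropically sampled outward
directions, spherical single cells placed by rejection sampling in a
distance shell, a two-level intensity image (foreground 200, background
20 grey levels by default), additive Gaussian noise (default sd 10),
optional Gaussian PSF blur, and clipping/rounding to the integer dtype.

Choices worth knowing:

* **Default geometry** — 128×128×16 voxels, core radius 6, five sprouts
  of mean length 20 ± 4 voxels and width 3, ten single cells of radius 2
  at 30–50 voxels from the center. The thin axial extent mimics a
  confocal slab at low magnification; sprout directions are rejected
  until the whole sprout fits inside the volume, which keeps sprouts
  mostly in-plane exactly as a finite imaging volume does, and keeps the
  maximal collective distance a clean monotone function of sprout length.
* **`guarantee_isolation`** — single cells are placed with ≥ 2 voxels of
  clearance from the core+sprout network and from each other, so the
  ground-truth collective/single partition is unambiguous under any
  standard connectivity. Without it, overlapping objects are labeled
  with network priority and the disconnection guarantee lapses.
* **Core labeling convention** — the ground-truth core is defined by the
  same inscribed-ball rule the quantifier uses (shared helper), with the
  radius computed on the clean mask. The core/outgrowth boundary is a
  reporting convention, not a biological claim; defining it once and
  using it on both sides makes "exact recovery" a meaningful test of the
  segmentation and classification, which remain independently checked
  against a hand-written BFS flood-fill oracle.
* **Determinism** — output is a pure function of `SpheroidParams`
  including the seed; condition panels derive per-condition seeds from
  the base seed and the condition index.
* **2D** — a shape with a leading singleton axis runs the identical code
  path with planar geometry.

What the generator does *not* emulate: intensity falloff with depth,
anisotropic PSFs, autofluorescence texture, curved or branching sprouts,
cell-scale intensity variation, or any actual migration dynamics
(persistence, chemotaxis). Passing tests therefore demonstrate that the
*quantification* is correct and noise-tolerant, not that segmentation
will be trivial on arbitrary real acquisitions — on real data the
threshold choice remains the analyst's responsibility.

## Histomorphometry

`positive_pixel_fraction` counts pixels strictly above a user-supplied
threshold (optionally within an ROI); the threshold is deliberately
manual — the protocol it mirrors chooses it to exclude unspecific
staining — and an Otsu suggestion is printed but never silently applied.
`normalize_to_control` divides each sample's value by the control-group
mean, so the control normalizes to exactly 1 and the operation is
invariant to any global intensity rescaling. Fractions (not absolute
counts) are normalized, so sections of different sizes compare fairly.

## Problem sizes and numerical notes

The test suite and `scripts/acceptance.py` use the default 128×128×16
stacks (20 images for recovery and noise checks, 5 seeds × 4 sprout
lengths for the monotonicity check) and a few hundred random masks up to
64² / 32³ for oracle comparisons; these sizes were chosen so the whole
suite runs in well under a minute per check on one CPU while every voxel
count stated is computed, not assumed. Distances and EDT values are
float64 throughout; count fields are integers end to end (CSV writers
never reformat them as floats), which is what makes the round-trip
checks bit-exact. Ball membership uses `d² ≤ r²` on exact integer/float
arithmetic; the inscribed-core rule uses strict `<` against the EDT
maximum as described above.
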