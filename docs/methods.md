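# Methods

This note documents the models, conventions and numerical choices behind
`embolocate`, and what the synthetic fixtures do and do not establish about
real data.

## Physical model and conventions

Serial coronal block-face images are taken of the tissue block before each
vibratome section is cut. Defaults follow the acquisition this workflow
was built around: 6.5 µm/px in-plane, 100 µm section thickness, 8-bit RGB
images with bead fluorescence in the green channel, and a black background
guaranteed by the tissue preparation (ink-darkened embedding). Section
index 0 is the most anterior face; the z-resolution of every localization
equals the section thickness.

Atlas volumes are integer label arrays with isotropic voxel size, axes
ordered (anterior–posterior, dorsal–ventral, medial–lateral); label 0 is
outside the brain. Continuous atlas coordinates use the voxel-centre
convention: voxel `v` spans physical `[v·s, (v+1)·s)` µm and has
coordinate `v` at its centre, so structure lookup is nearest-voxel
(`rint`). Pixel-to-atlas charts use the pixel-corner convention
(`x ∈ [0, W)`), switchable to pixel centres.

## Stack normalization and rigid alignment

Midline rotation computes one angle from two user-drawn points and applies
it to every section; the canvas is expanded with black fill so nothing is
clipped. Consequence: anchors and midlines must be specified on the
*rotated* images. Masks are warped with nearest-neighbour interpolation
(they must stay binary), intensity images bilinearly.

Stack alignment registers each section to its predecessor and chains the
pairwise transforms to a reference section — the middle one by default,
halving worst-case drift accumulation relative to chaining from one end.
Pairwise registration is intensity-similarity maximization restricted to
rotation + translation: sub-pixel phase correlation (upsampling factor 20)
provides the translation for a candidate angle, and a bounded scalar
optimization (±10° by default, tolerance 0.02°) minimizes the normalized
RMS residual over the angle. Both images are first smoothed with a
Gaussian (σ = 1 px). This smoothing matters: warping at a small trial
angle low-passes the image, which on unsmoothed noisy data *reduces* the
residual for spurious rotations; pre-smoothing removes the bias, and a
nonzero angle is only accepted if it beats angle 0. An all-black section
yields an identity transform with a warning rather than a failure.

Whole-brain volume is Σ (foreground pixels × px² × thickness), with
foreground defined as max-over-channels intensity > 15/255 — the
preparation guarantees a black background but no published threshold
exists, so a low conservative value is used. We align before measuring
area; for rigid transforms the difference is interpolation-level (≤ 1%).

## Detection and z-plane resolution

Bead segmentation thresholds the green channel at ≥ 140 of 255. The
published band places 140 in both the background and signal classes; we
classify 140 as signal (flag `--threshold-low`). Non-8-bit input is an
error, never silently rescaled, because the threshold is defined on the
0–255 scale.

Serial subtraction assigns each bead to the last section it is detected
in. The default implementation matches connected components between
adjacent masks by centroid distance (radius = one bead diameter), which
tolerates residual alignment error; `pixel` mode performs literal mask
subtraction. Chains longer than ⌈visibility depth / thickness⌉ sections
(4 at the defaults) are split with a warning — a bead cannot be seen
deeper than its visibility depth, so longer same-place chains must be two
beads. Component area limits default to 0.25×–4× the nominal bead disk
area at the given calibration (no published size filter exists; the filter
is configurable and can be disabled); oversized components are treated as
merged beads and split by a distance-transform watershed seeded at local
maxima.

## Atlas registration

Anchors follow the origin + two in-plane vectors convention used by
serial-section anchoring tools, so third-party anchoring files can be
imported directly. Between consecutive anchors all three vectors (o, u, v)
are interpolated linearly by section index — interpolating position *and*
cutting angles; `--propagate ap-only` restricts interpolation to the
origin and holds angles at the nearest anchor. Outside the anchored range
the nearest segment's slope is extrapolated. A single anchor advances the
origin by one section thickness (in voxels) per section along the
anterior–posterior axis. A detection exactly on the midline ties to the
right hemisphere (deterministic output); sections without their own
midline inherit the nearest delineated one.

## Ontology aggregation and reporting

Level numbering starts at 1 at the root; level 2 splits into gray matter,
fiber tracts and ventricular systems. Branches end at different depths, so
a structure may simply not exist at a deep level (`not_at_this_level`).
Terminal-branch selection applies the ≥ 5-bead criterion to the node being
expanded (not to each child — that reading matches "to consider moving to
the next anatomic subdivision"); a flag switches the semantics. Direct
detections on an expanded internal node that no child inherits are
reported in an "(other)" bucket row so every bead lands in exactly one
row. Proportions are taken over *all* detections including unaccounted
ones; region volumes count both hemispheres' voxels and all descendant
voxels. The totals row sums counts and proportions and takes the mean of
region densities.

In the agreement table, a bead whose reference structure ends above the
queried level counts as "not at this level" *only if it was correctly
allocated at its own terminal level*; otherwise it remains a disagreement.
This implements "correctly allocated up to the specific hierarchal level"
and makes sum-of-agreement monotonically non-increasing with depth, which
a purely level-based rule would violate. Percentages round half-up to one
decimal, matching printed tables. Levels 11–12 are computed but flagged
sparse. The independent-samples t test uses pooled variance (Student's)
by default since the published analysis names no correction; Welch is
available via a flag.

## Synthetic data: what it emulates

The generator provides seeded, fully ground-truthed fixtures.

- **Toy atlas**: a box-shaped brain inset in label 0, with each internal
  node partitioned exactly among its children (axis-aligned slabs), so
  sibling volumes tile their parent and region volumes are known. One
  branch always terminates early (plus a seeded fraction of others), so
  `not_at_this_level` cases always exist. Defaults: depth 5, branching 2,
  64³ voxels at 50 µm. Pipeline fixtures use 32³ voxels at 100 µm — voxel
  size equal to section thickness, which makes a section's mid-plane land
  exactly on a voxel index and keeps the ground-truth (section, region)
  pair well-defined at the workflow's z-resolution.
- **Scenes**: beads are placed uniformly over brain voxels (or weighted by
  region), jittered within the voxel but kept 0.1 voxel clear of voxel
  boundaries — a bead centred within a few µm of a structure boundary has
  no unique assignment at bead scale. Beads whose anterior–posterior
  separation is within the visibility depth plus one section (500 µm)
  keep ≥ 50 µm in-plane separation, emulating beads lodging in distinct
  arterioles (real bead loads are sparse: hundreds of beads in a
  ~450 mm³ brain) and keeping co-visible beads resolvable as distinct
  components.
- **Rendering**: a bead surfaces in its own section's image at full
  intensity (255) and appears in up to three preceding images with
  linearly attenuated intensity reaching exactly the detection threshold
  (140) at the visibility depth (400 µm); an exponential curve is
  available — only the visibility range is published, not the curve
  shape. Sub-surface appearances get a small depth-proportional Gaussian
  blur (renormalized so the core keeps its attenuated intensity), a
  fixture-realism choice. Brain tissue renders at green level 40 (well
  below threshold); optional per-section rigid jitter and Gaussian noise
  are applied after rendering. Mask-stack fixtures for the z-resolution
  oracle keep per-section centroid drift at or below the disk radius so
  chains stay 26-connected, and distinct chains far enough apart that
  neither centroid matching nor 3D connectivity can merge them.

What passing these tests shows: the geometry, the subtraction rule, the
anchoring math, the aggregation arithmetic and the statistics are correct,
and the pipeline is robust to moderate noise (σ = 10 on 8-bit) and jitter
(±1 px). What they do not show: performance on real tissue — autofluorescence
texture, uneven illumination, non-rigid deformation, beads dimmer than the
calibrated threshold, and anchoring error from human judgement are all
outside the simulation.

## Problem sizes and determinism

The test suite and the acceptance script use 32-section stacks of
~493×493 px with 60–500 beads, 200 random mask stacks for the oracle
comparison, and depth-7 toy atlases — sizes chosen so a full run completes
in minutes on one core while exercising every code path at realistic
calibration. All randomness flows from explicit seeds; the same seed
reproduces scenes, atlases and renders byte-for-byte.

## Known limitations

- The linear anchoring model cannot express non-rigid tissue deformation;
  it is the price of keeping user input to a handful of anchors.
- Serial subtraction can mis-assign two beads that overlap in-plane with
  anterior–posterior separation just beyond the visibility depth (the
  chain-split cap bounds, but cannot eliminate, this).
- Region volumes come from the annotation volume's voxel counts, so
  densities inherit its discretization error.
- Beads dimmer than the threshold at depth (e.g., under blood or dense
  white matter) are only detected once they surface — or not at all; the
  simulator's attenuation model is calibrated to the threshold contract,
  not to measured intensity histograms.
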