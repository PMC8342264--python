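# embolocate

Brain-wide localization of fluorescent microemboli from serial block-face
images.

Injecting ~20-µm fluorescent microspheres into the carotid circulation is a
standard rodent model of cerebral microinfarction: each bead lodges in a
penetrating arteriole and marks one occlusion site. The hard part is not
making the occlusions but *finding* them — mapping every bead in a brain to
an anatomical structure. `embolocate` implements a semi-automated workflow
that does this from **block-face images**: photographs of the cut tissue
surface taken before each vibratome section, which preserve the native
tissue geometry that slide-mounted histology distorts.

It is a library for neuroscientists quantifying microembolic load: the
importable API is the main interface, `examples/` holds one narrative
script per capability, and a thin `embolocate` command-line tool wraps the
common simulate/detect/report paths.

## The method

1. **Stack handling** — read an ordered image series with physical
   calibration (µm/px, section thickness), rotate all sections so a
   user-drawn midline is vertical, and rigidly align the stack
   (rotation + translation only; phase-correlation translation seed with a
   bounded search over the angle).
2. **Detection with depth disambiguation** — beads are segmented in the
   green channel of the 8-bit image (intensity ≥ 140 is bead signal). A
   bead shines through up to ~400 µm of tissue, so it appears in several
   consecutive images; adjacent binary masks are subtracted so each bead is
   attributed to the **last** image it appears in — the section that
   actually contains it. The z-resolution therefore equals the section
   thickness. Manual point annotations are dilated to bead size
   (20 µm) and flow through the same subtraction path.
3. **Atlas registration** — a few sections are *anchored* to a 3D reference
   atlas with a linear chart (origin `o` plus in-plane vectors `u`, `v` in
   atlas voxel coordinates); charts for the remaining sections are linearly
   interpolated, and a pixel maps to `p = o + (x/W)·u + (y/H)·v`.
   Hemispheres come from per-section midline delineations.
4. **Ontology reporting** — each mapped bead is looked up in the annotation
   label volume, counts are rolled up the hierarchical structure tree
   (level 1 = root, deepest branches ≈ level 12, branches end at different
   depths), and reporting regions are the terminal branches selected by the
   *≥ 5 beads to expand* criterion. Per region: count, proportion of all
   beads (unaccounted included), structure volume, and density (beads/mm³).
5. **Validation statistics** — level-wise agreement tables between two
   allocations of the same beads (agreement / not-at-this-level /
   sum-of-agreement / disagreement), percent agreement, Pearson
   correlation, paired and pooled-variance independent t tests, and the
   sectioning-loss percentage.

A seeded synthetic-data module (`embolocate.synthetic_data`) generates a
nested toy atlas, ground-truthed bead scenes, and rendered block-face
stacks with depth-attenuated bead intensity, noise and rigid jitter, so the
whole pipeline is testable end to end without reference-atlas downloads.

## Worked example

`python examples/03_region_report.py` simulates a brain with 300 beads,
runs the full workflow and prints the region report (excerpt):

```
   region  level  count  proportion_pct  volume_mm3  density_per_mm3
 region 6    6.0      8            2.67        0.69            11.66
 region 7    6.0     10            3.33        0.69            14.58
region 15    5.0     21            7.00        1.37            15.31
region 16    3.0     83           27.67        5.49            15.12
...
total detections: 300; unaccounted: 0
```

Each row is one terminal branch of the ontology: `count` beads landed in
that structure (or its descendants), `proportion_pct` is the share of all
300 beads, `volume_mm3` the structure volume from the annotation volume,
and `density_per_mm3 = count / volume`. Region 16 sits at level 3 because
it held too few beads to justify expanding into its subregions, while
well-populated branches are reported deeper — that is the ≥ 5-bead
criterion at work. The totals row sums counts and proportions (to 100%)
and averages densities.

The other examples cover detection against ground truth
(`01_simulate_and_detect.py`), anchor-based registration
(`02_atlas_registration.py`) and the validation statistics
(`04_validation_stats.py`).

## CLI

```sh
embolocate simulate --n-spheres 2000 --seed 7 --out-dir sim/
embolocate detect --stack sim/blockface.tiff --threshold-low 140 \
    --match-radius-um 20 --subtract-mode component --out detections.csv
embolocate report --stack sim/blockface.tiff --anchors sim/anchors.json \
    --ontology sim/ontology.json --annotation sim/annotation.nii.gz \
    --out-dir report/
```
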