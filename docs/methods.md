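# Methods

This document describes what `livernav` computes and why, module by module,
with all parameters, units, and defaults. The README covers installation and
usage; this file covers the underlying method and its numerical choices.

## Problem setting

On CT, the liver's attenuation (~40–80 HU) overlaps with the heart, spleen,
stomach wall, and kidneys. Intensity alone therefore cannot delimit the liver;
what distinguishes it is *where* it sits inside the body. `livernav` encodes
that position explicitly: it localizes robustly segmentable reference
structures (body surface, spine, symmetry planes, diaphragm), converts them
into four signed-distance fields (SDFs), and feeds those fields to a U-Net as
extra input channels alongside the intensity.

Axis convention throughout: arrays are indexed `(z, y, x)` with `z` the
craniocaudal axis (slice 0 most caudal), `+y` posterior, `+x` patient-left.
World coordinates are `mm = origin + index * spacing`.

## Volume primitives (`livernav.volume`)

`Volume` and `Mask` wrap a voxel array with its spacing and origin (mm).
I/O goes through SimpleITK and supports MetaImage (`.mhd/.mha`), NIfTI
(`.nii/.nii.gz`), and DICOM series directories. Numerical primitives:

- `minmax_normalize` — affine rescale of intensities to [0, 1] per volume.
- `resample` — linear interpolation onto an isotropic grid (nearest for
  masks); `resample_to_grid` maps a field from one grid onto another.
- `gaussian_smooth` — Gaussian filter with sigma given in mm, converted to
  voxels per axis, so smoothing is anisotropy-aware.
- `threshold` — boolean mask at a HU cutoff.

## Body-navigation features (`livernav.bodynav`)

All steps run at a coarse working resolution (`working_spacing_mm`, default
4 mm) for speed; the final SDF channels are evaluated on the native grid.
Parameters (`BodyNavParams`), with defaults:

| name | meaning | default |
|------|---------|---------|
| `SB` | body-surface smoothing sigma | 3 mm |
| `TB` | body threshold | −300 HU |
| `SS` | spine smoothing sigma (craniocaudal, in-plane) | (100, 15) mm |
| `TS` | bone threshold | 320 HU |
| `TLA` | internal-cavity threshold | −200 HU |
| `DSA` | cavity exclusion distance from the sagittal plane | 30 mm |
| `DBA` | cavity exclusion distance from the body surface | 1 mm |
| `working_spacing_mm` | working resolution | 4 mm |
| `diaphragm_area_fraction` | cavity-band cutoff | 0.05 |

Stages:

1. **Body surface** — smooth (`SB`), threshold (`TB`), keep the largest
   connected component, fill enclosed cavities (so lungs count as inside).
2. **Spine** — threshold at `TS`, then smooth the bone map with a strongly
   anisotropic Gaussian (long along the craniocaudal axis, short in-plane).
   This reinforces the one bony column that spans the scan and suppresses
   ribs; the per-slice argmax gives the spine centre, and a bone-mass
   weighted average gives the centroid.
3. **Sagittal plane** — initialized from the body-centre→spine-centre
   vector, then refined by minimizing the squared mismatch between the axial
   bone projection and its mirrored copy over a rotation angle and a lateral
   offset. The optimizer is a deterministic coordinate descent (coarse grid
   scan + golden-section per line); if refinement cannot improve on the
   initial estimate the plane is returned flagged `low_confidence`.
4. **Coronal plane** — through the spine centroid, perpendicular to the
   sagittal plane, normal oriented anteriorly.
5. **Diaphragm level** — per-slice area of the internal cavity (below `TLA`,
   inside the body, excluding voxels within `DSA` of the sagittal plane and
   within `DBA` of the surface). The lungs produce a high-area band; the
   level is that band's caudal edge: scanning caudally from the area peak,
   the last slice whose area exceeds `diaphragm_area_fraction` of the
   maximum. The crossing is refined by linear interpolation between slices,
   which removes whole-slice jumps under small parameter perturbations.

The four output channels are the signed distances (mm, native grid) to the
sagittal plane, the coronal plane, the axial plane at the diaphragm level,
and the body surface. Plane SDFs are evaluated analytically (exact affine
fields); the surface SDF uses an anisotropy-aware Euclidean distance
transform at working resolution (negative inside), linearly resampled to the
native grid. Feature extraction is deterministic: identical volume and
parameters give bit-identical channels. Failures raise
`FeatureExtractionError` carrying the failing stage's name.

## Phantom generator (`livernav.phantom`)

Real abdominal CT with ground truth cannot ship with the package, so tests
and experiments run on a synthetic phantom: an elliptical torso (fat shell,
soft tissue, two lungs, spine with a posterior process, ribs) containing six
soft organs — liver, heart, spleen, stomach, and two kidneys — *all at the
same attenuation* (60 HU over 30 HU tissue, Gaussian noise sd 15 HU). The
shared attenuation is the point: intensity separates organ from background
but cannot tell the organs apart, so any segmentation advantage must come
from positional information, which mirrors the clinical problem. The pose
(in-plane rotation `yaw_deg`, lateral `lateral_shift_mm`) is applied to all
structures coherently, and the generator returns exact ground truth: all
structure masks, the true sagittal/coronal planes, and the true diaphragm
level.

Realism limits to keep in mind:

- Organs are ellipsoids; there are no vessels, no organ boundaries with
  partial-volume gradients, and no bed, metal, or contrast agent.
- At coarse grids the anatomically proportioned organs would be only a few
  voxels, so `organ_scale` (default 1.0; experiments use 1.8) enlarges the
  soft organs. This raises the liver's voxel share to a trainable level and
  is a deliberate departure from proportion.
- The spine is exactly straight and the symmetry is exact up to noise, which
  makes spine localization more robust than on clinical data; consequently
  the bone threshold `TS` is less fragile here than on real scans.

`generate_probability_fixture` produces a synthetic "network output"
(~0.9 on the liver, ~0.1 elsewhere, ±0.05 uniform noise) with an optional
spurious high-probability blob, used to demonstrate the postprocessing.

## Tiling (`livernav.tiling`)

Networks train on fixed-size tiles: per-axial-slice 2D tiles
(`mode="slices2d"`) or 3D cubes (default 32³). Training in cube mode cuts
tiles from the offset-0 grid plus grids shifted by each `train_offsets` value
(default 8, 16, 24 voxels in every direction), roughly quadrupling the
training data; voxels outside the volume are padded with 0 (background for
labels). Inference always uses the unshifted disjoint grid, so
`assemble(make_inference_tiles(x))` is a bit-exact identity.

## Network and training (`livernav.nn`, `livernav.model`)

The U-Net engine is implemented directly on numpy (no deep-learning
framework is required at run time): stride-1 same-padding convolutions
(evaluated as a z-chunked shift-and-accumulate over stacked GEMMs, which is
substantially faster than im2col at small channel counts), ReLU, factor-2
max pooling, nearest-neighbour upsampling, inverted dropout on the two
deepest encoder levels, skip connections by channel concatenation, and a
1×1(×1) output head. Backpropagation is manual and gradient-checked.

Two numerical choices matter for stable training at small step budgets:

- **Class-weighted BCE** — weights inversely proportional to class frequency,
  normalized to sum to 2, so the minority liver class is not drowned out.
  Under these weights the best *constant* prediction is exactly p = 0.5.
- **Zero-initialized head** — the final 1×1 convolution starts at zero, so
  training begins at that maximum-entropy optimum. Without this, Adam's
  large effective step (≈ learning-rate per parameter per step) drives the
  randomly initialized network through a transient that collapses it onto a
  constant output before any feature–label correlation can form.

Training uses Adam (lr 0.01, β = (0.9, 0.999)), batch size 4 for cubes and
32 for slices, 5 epochs by default, all seeded and deterministic.
`UNetSegmenter` is the sklearn-style wrapper: `fit(X, y)` on volumes (or
`(volume, features)` pairs when `use_position_features=True`),
`predict_proba` returns per-voxel probability volumes, `predict` thresholds
at 0.5, and `save`/`load` round-trip the configuration and weights through a
single `.npz` file.

## Postprocessing (`livernav.postprocess`)

`postprocess = binarize → keep_largest_component → erode`: threshold at 0.5,
keep the largest 26-connected component, then four binary erosions with the
6-neighbour cross. Dropping all but the largest component removes spurious
detections far from the organ — which is what improves the maximum surface
distance most — and the erosions strip high-frequency boundary noise.

## Metrics (`livernav.metrics`)

- **Accuracy** — voxelwise (TP+TN)/total.
- **Dice** — 2|X∩Y|/(|X|+|Y|); two empty masks give 1 by convention.
- **MaxD** — symmetric Hausdorff distance in mm between mask surfaces.
  Surface voxels are foreground voxels with a 6-neighbour background voxel
  (the volume border counts as background); distances are between voxel
  centres, anisotropy-aware, computed with a KD-tree (identical to the
  brute-force double loop). Empty masks give NaN (undefined, not zero).

`aggregate` renders a per-case table with `Avg. value` and `St. dev.` rows.

## Sensitivity experiment (`livernav.sensitivity`)

One body-navigation parameter at a time is multiplied by
k ∈ {0.25, …, 1.75} while the others stay at their defaults; the reported
quantity is the displacement (mm) of the navigation origin — the
intersection of the sagittal, coronal, and diaphragm planes — relative to
the default-parameter origin. Runs where a stage fails are flagged with the
stage name and excluded from summaries rather than silently dropped. On the
phantom, the scan reproduces the qualitative picture expected from the
method: zero displacement at k = 1, flat DBA/DSA rows, fragility of the
body threshold `TB` at low k (the body mask vanishes), and a blow-up of the
cavity threshold `TLA` at low k (fat gets counted as cavity). `TS` is more
robust here than on clinical data (see phantom limits above).

## Paired experiment (`livernav.experiment`)

`run_experiment(ExperimentConfig(...))` runs the package's headline
comparison end to end: generate (or load) volumes, split by whole volume
into train/validation/test (default 8/2/2), optionally extract
body-navigation features, train one `UNetSegmenter`, and report per-case
Accuracy/MaxD/Dice tables before and after postprocessing. Running it twice
with `use_bodynav` True/False and the same `data_seed` gives a paired
with/without-position-features comparison on identical data.

Experiment defaults are sized for a single CPU: phantoms on a
(32, 64, 96) grid at 4 mm (which tiles into exactly six 32³ cubes with no
padding — padded, mostly-empty tiles measurably destabilize training at
this scale), `organ_scale` 1.8, network depth `levels=2`, `base_filters=8`,
no training offsets, 5 epochs. All randomness is controlled by exactly two
seeds (`data_seed`, `model_seed`), and the CLI refuses to run an experiment
without explicit seeds.

## Limitations

- The numpy engine targets small networks (levels ≤ 3, base_filters ≤ 16 on
  one CPU); it is not a general-purpose training framework.
- The phantom's simplifications (see above) mean quantitative results do not
  transfer to clinical CT; the package demonstrates the *mechanism* — that
  positional SDF channels let a network reject intensity-identical confuser
  organs — not clinical performance.
- With 5 epochs on a handful of volumes, training outcomes vary noticeably
  across model seeds; the experiment therefore reports medians across seeds
  rather than single runs.
- The sagittal-plane search assumes the patient is roughly supine (rotation
  within ±20°) and the diaphragm detection assumes the lungs are at least
  partly in the field of view.
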