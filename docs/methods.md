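# Methods

`gtvnet` implements a fully automatic gross-tumor-volume (GTV) contouring
pipeline for head-and-neck cancer on coregistered PET-CT: a synthetic
dual-center phantom generator, slice preprocessing, a two-phase
encoder-decoder convolutional network trained progressively in three stages,
patient-level leave-one-out cross-validation (LOOCV), and an evaluation
suite (DSC, MSD, sensitivity, precision, volume statistics). This note
documents the model, its assumptions, and the design choices made where the
design was genuinely open.

## The segmentation model

### Inputs

The network consumes two-channel 2-D samples: one axial CT slice and the
coregistered PET slice resampled onto the CT grid. Hybrid PET-CT scanners
acquire both modalities in a common hardware frame, so coregistration is
implemented as trilinear grid resampling only — no deformable or statistical
registration. Each patient volume is min-max normalised to [0, 1] per
modality over the whole volume before slicing; per-volume (rather than
per-slice) scope makes the normalisation robust to slices without anatomy.

### Architecture

Two phases. The *feature representation* phase: each modality passes its own
5×5 convolution + ReLU (low-level features per modality), the two feature
maps are concatenated (the fusion point), and five downsampling blocks
(conv + ReLU + 2×2/stride-2 max pooling) reduce an S×S input to S/32×S/32,
with one extra 3×3 conv + ReLU interleaved after blocks 2–5. A convolution
whose kernel spans the entire remaining map ("fully-connected-like") yields
a 1×1 scores vector, refined by two 1×1 convolutions. The *scores-map
reconstruction* phase: five upsampling blocks — a transposed convolution
(the first maps 1×1 → S/16×S/16 with kernel = stride = S/16; the rest
double resolution with kernel = stride = 2), concatenation with the last
encoder feature map of matching resolution (U-style skip), and a 1×1 conv +
ReLU — followed by a final 1×1 conv + ReLU emitting the single-channel
non-negative scores map at full resolution.

Open details resolved as package design choices:

- **Kernel sizes.** Only the first convolution is fixed at 5×5 by the
  design; the remaining encoder convs use 3×3 (the standard small-kernel
  choice; materially cheaper on CPU). Post-concatenation decoder convs are
  1×1 by design.
- **Channel counts** are unspecified in the source design; the default is
  the standard doubling schedule 32-64-128-256-512 scaled by a
  `width_multiplier`, with a 512-channel bottleneck (also scaled).
- **Fusion** of the two modality branches is by concatenation (summation
  was the alternative reading).
- **Skip sources**: the last encoder map at the matching resolution.
- **Padding** is "same" everywhere, the only choice consistent with the
  clean 512→16→1→512 spatial schedule.
- **Pooling** is max pooling (the pooling type is not pinned by the design).
- **Extra encoder convs**: one after each of blocks 2–5.

### Loss

Training minimises the Euclidean loss `sum((score - gold)^2) / (2·batch)`.
The division by 2·batch is a normalisation convention chosen so toy
examples are simple (a single pixel off by 1 in a batch of one gives 0.5)
and learning-rate advice transfers across batch sizes. Gold masks are
average-pooled and re-binarized (≥ 0.5) to the stage's output size for
stages 1–2; average pooling preserves small-structure topology better than
nearest-neighbour subsampling.

### Three-stage progressive training

Stage 1 attaches an output head after the third upsampling block (output
S/4), stage 2 after the fourth (S/2), stage 3 trains the whole network
(output S). Every layer exists from construction, built from one seeded
generator, so stage transitions carry shared weights over bit-exactly and
only the next head/decoder block is "new".

Short-budget optimisation of this architecture has two failure modes that
the training procedure addresses directly; both stem from the network
having no normalisation layers and a rectified output regressing {0, 1}
targets:

1. **Uncontrolled scale at stage transitions.** Internal activation scales
   drift freely during earlier stages, so a freshly attached head's initial
   output can be arbitrarily large (its error then swamps the pretrained
   trunk; initial stage losses above 500 were observed) or arbitrarily
   small (its gradient then crawls under Adam's per-step cap). The remedy
   is *data-dependent head initialisation*: at the start of each stage the
   fresh head's weights are rescaled so its pre-activation has a fixed
   small standard deviation (0.05) on a probe batch, and its bias starts
   positive (+0.1) so the rectified output begins active.
2. **The dead-output absorbing state.** Because ~98% of target pixels are
   background, the loss pushes the whole scores map down; if the head's
   pre-activation goes negative at every pixel, the final ReLU outputs
   identically zero *and the gradient is identically zero* — training
   freezes permanently in the "predict nothing" state. Training therefore
   watches for a run of all-zero output batches (25 consecutive) and
   *resurrects* the head by re-running the calibration: this only rescales
   the learned weight direction and restores the positive bias, so trunk
   learning is preserved and nothing useful is lost (the dead head's
   gradient was exactly zero).

Two further standard safeguards: global gradient-norm clipping (at 1e3,
inactive during healthy training) prevents the occasional exploding step
from overflowing float32 Adam moments, and a *restart-on-failed-convergence*
rule retrains a fold from a fresh seeded initialisation when its final
100-iteration training loss stays above 0.35× the all-zero-prediction
baseline loss (half the mean tumor area per sample), keeping the attempt
with the lower final loss. Only training-set quantities enter these
decisions; the cross-validation driver caps total retraining work at two
restarts per run. Weight initialisation is otherwise He-uniform
(±sqrt(6/fan_in)) from the seeded generator.

### Optimisation

Adam with fixed learning rate. The full-scale configuration reported for
GPU training is 200,000 iterations at 1e-5 (split across the three stages
unstated; we document (50k, 50k, 100k) as the full-scale default). The desk
default, used in tests and the acceptance run, is ~2,000 iterations per
LOOCV fold split (400, 400, 1200) at learning rate 1e-3 (stage 3 carries
the most freshly initialised layers and the final full-resolution
objective, so it receives the largest share) — the standard Adam
rate, appropriate for a run three orders of magnitude shorter — with batch
size 8. Training is single-threaded and deterministic given the seed.

## Preprocessing rules

- **0.5 cm² slice filter.** Slices whose gold tumor cross-section is
  positive but below 0.5 cm² (count × pixel area, 2-D) are discarded
  entirely — the partial-volume effect makes such lesions unreliable on
  PET. Tumor-free slices are kept as negatives. At the clinical 0.49 mm
  pixel pitch the threshold falls between 208 pixels (49.94 mm²) and 209
  pixels (50.18 mm²).
- **Balancing.** All positive slices are kept; negatives are uniformly
  subsampled without replacement to the positive count (all kept, with a
  warning, if already fewer).
- **Augmentation.** Each training sample emits `factor` random variants
  composing rotation (±15°), horizontal mirror (p = 0.5), gamma contrast
  (γ ∈ [0.8, 1.25], image channels only), and isotropic scaling
  ([0.9, 1.1]); geometric transforms are applied identically to CT, PET and
  mask, the mask re-binarized at 0.5 after interpolation. The magnitudes
  are unstated in the source design and chosen conservatively; whether the
  contrast change was gamma, linear windowing or histogram-based is also
  unstated — gamma was chosen. Balancing and augmentation are re-drawn per
  LOOCV fold with the fold index folded into the seed.

## The phantom generator

Because the clinical data are private, every stage is exercised on a
synthetic dual-center phantom. Each patient is a head-like axial ellipse —
bright skull rim, textured soft tissue (Gaussian-filtered noise, ~4 mm
correlation length) — carrying 1–2 tumor lesions and 1–2 inflammation
confounders:

- **Tumors** are unions of 1–3 overlapping ellipsoids (shape matters for
  MSD; single spheres would be too easy), placed well inside the soft
  tissue (normalised ellipse radius < 0.55). On CT they appear as a subtle
  sharp-edged contrast step (+0.18 on a 0.35 soft-tissue level); on PET as
  high uptake (4× soft tissue).
- **Inflammation confounders** draw from the *same* PET uptake distribution
  as tumors but have *no CT correlate* and sit adjacent to the skull rim
  (normalised radius 0.70–0.84). The tumor/confounder discrimination is
  therefore solvable only from CT and PET jointly — exactly the behaviour
  the clinical network exhibits — and unsolvable from PET alone.
- **PET physics** is emulated, not simulated: uptake is synthesised on the
  CT grid, blurred with a Gaussian point-spread function (FWHM 5 mm desk /
  6 mm full scale, the partial-volume effect), trilinearly downsampled to
  the coarser PET grid, and degraded with additive Gaussian noise.
  Attenuation, scatter, reconstruction artefacts and motion are *not*
  modelled; consequently, passing tests demonstrate that the pipeline
  learns joint PET-CT evidence on data with realistic geometry and
  blur/noise structure, not that it reaches clinical accuracy on real
  scans.
- **Intensities are abstract units** in [0, ~1]; no HU or SUV calibration
  (everything is min-max normalised downstream anyway).

Two full-scale parameter sets mirror the two scanners (CT 0.49×0.49×2.5 mm
/ PET 1.56×1.56×3.27 mm on 512×512×63; CT 0.59×0.59×3.27 mm / PET
1.17×1.17×3.27 mm on 512×512×47). The desk presets used by the tests are
64×64 in-plane grids: center A at 2×2×4 mm CT / 4 mm PET, center B at
2.5×2.5×5 mm CT / 5 mm PET.

**Lesion size at desk scale.** The clinical volume range (3.5–147.5 cm³ on
a 512 grid at ~0.5 mm pixels) corresponds to in-plane lesion radii of
roughly 4–13% of the matrix width. Desk tumor radius ranges are chosen to
occupy the same fraction of the 64-pixel matrix (A: 5–17 mm on 2 mm
pixels; B: 6–21 mm on 2.5 mm pixels), with radii drawn log-uniformly so
cohort volumes span a wide range. Early experiments with proportionally
smaller lesions produced a degenerate task: after average-pooling to the
stage-1 output (S/4), the targets vanished and training collapsed to
"predict nothing". Matching the clinical lesion-to-matrix proportion keeps
the desk task a faithful scale model.

The analytic tumor volume stored with each case is computed by fine-grid
(0.5 mm) integration of the generative ellipsoid unions within their
bounding box, independent of the CT voxelisation.

## Evaluation mathematics

All overlap metrics are computed from voxel counts pooled over a patient's
evaluated slices (volume-level pooling, one row per patient):

- DSC = 2TP / (FP + 2TP + FN); sensitivity = TP/(TP+FN); precision =
  TP/(TP+FP). Pooled counts make DSC exactly the harmonic mean of
  sensitivity and precision — an identity the test suite checks on random
  counts. Degenerate cases: two empty masks give DSC 1.0 with a warning;
  undefined sensitivity/precision (empty gold/prediction) are reported as
  missing and excluded from aggregation with a warning.
- MSD is the symmetric mean of nearest-neighbour Euclidean distances
  between the two boundaries, in mm. Boundary pixels are mask-positive
  pixels with at least one face-adjacent in-plane background neighbour
  (4-neighbourhood); coordinates are voxel-centre positions scaled by
  spacing, and distances are measured in 3-D across the patient's slices
  with slice thickness as the z-spacing (2-D vs 3-D was open; 3-D chosen).
- Volume difference (%) = |GTVa − GTVm| / GTVm × 100 — the
  manual-volume-denominated absolute form (this variant, and only this
  variant, reproduces the published cohort mean from the published
  volumes).
- The "95% interval" of a metric is mean ± 1.96·SD of its distribution
  (sample SD, n−1), the only reading consistent with the published
  intervals; medians for even n are midpoints of the central order
  statistics; Pearson's R is the standard product-moment correlation.
- Known inconsistency in the published per-patient table: one patient's
  printed DSC (0.683) deviates slightly from the harmonic-mean identity of
  its printed sensitivity/precision (0.672); we do not replicate the
  deviation.

Prediction masks are scores ≥ 0.5 — the binarization rule is not stated in
the source design; 0.5 is defensible because targets are {0, 1}, and the
threshold is exposed as a flag. No post-processing is applied by default
(an optional largest-connected-component cleanup exists behind a flag but
is excluded from acceptance runs). GTV volumes are voxel counts × voxel
volume, in cm³.

LOOCV holds out one patient per fold; the held-out patient's slices never
enter training (asserted in tests). At test time every slice is predicted;
evaluation pools slices whose gold cross-section is zero or ≥ 0.5 cm²
(mirroring the training-side filter).

## Problem sizes used by the test and acceptance runs

The published experiment (512×512 inputs, 200k iterations, ~24 h on a GPU)
is configurable but not exercised. The desk-scale experiment used
throughout — 6 phantom patients across both pseudo-centers, S = 64,
width_multiplier 0.25, ~2,000 Adam iterations per fold, batch 8,
augmentation factor 4 — was sized to run the full 6-fold LOOCV in roughly
twelve minutes on one CPU core. At this scale the substituted acceptance
property is: LOOCV mean DSC ≥ 0.70, exceeding an untrained network by
≥ 0.40, with < 20% of inflammation-confounder area predicted positive.

## Known limitations

- The phantom's CT tumor contrast is deliberately learnable; real
  head-and-neck lesions can be nearly isodense with surrounding soft
  tissue. Phantom DSC is therefore not a clinical performance estimate.
- The NumPy network trains single-threaded; full-scale (512×512) training
  is supported by configuration but impractical without GPU hardware.
- Slices are processed independently (2-D); volumetric context is used
  only at evaluation time.
- Oblique acquisition geometries are rejected; only axis-aligned grids are
  supported.
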