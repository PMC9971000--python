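# Methods

## The measurement problem

Tear meniscus height (TMH) — the vertical extent of the tear-fluid strip
along the lower lid margin — is a standard biomarker for dry eye disease.
On a Keratograph-style ocular-surface photograph the measurement is anchored
to the central ring of the corneal projection ring (CCPR): a clinician reads
the meniscus height directly below the ring centre. `tmhkit` automates this
in two stages: semantic segmentation of the meniscus and the CCPR by two
independently trained networks that share one architecture, followed by a
deterministic geometric read-out.

## Geometric read-out

Given binary masks, the pipeline is:

1. **CCPR centre.** Keep the largest 8-connected component of the ring
   mask, fill interior cavities, and fit a circle to the filled component's
   pixels by algebraic (Kåsa) least squares. The axis-aligned bounding
   square of the fitted disk is reported alongside; its centre reproduces
   the fit centre to within a pixel, which is the invariant the centre
   localisation is tested on.
2. **Edge extraction.** In the half-open window of 200 columns
   `[x_c − 100, x_c + 100)` around the (rounded) centre column, record the
   topmost and bottommost meniscus rows per column on the largest meniscus
   component — 400 edge coordinates for a full window. The window is
   half-open deliberately: a closed ±100 px window would contain 201
   columns and 402 coordinates, and the method is specified by its total
   coordinate count of 400.
3. **Measurement columns.** Seven columns spaced 30 px apart, symmetric
   about the centre column (offsets −90 … +90). The 180 px span is ≈2.1 mm
   at the instrument scale; the measurement region directly below the ring
   centre is known to be insensitive to the exact sampling phase, which is
   why the symmetric anchoring is an acceptable choice.
4. **Height and conversion.** The height at a column is the filled-row
   count `lower − upper + 1`; the seven heights are averaged into PTMH
   (px) and converted as `TMH = PTMH / 86` mm. The `+1` convention makes a
   band occupying 86 raster rows measure exactly 1.00 mm, which we treat
   as the anchor identity of the conversion; a strict coordinate-difference
   mode (`strict_difference=True`, one pixel less per column) is provided
   for comparison.

Coordinates are 0-based, `x` = column, `y` = row increasing downwards.
Degenerate inputs raise typed errors: empty ring mask (`NoTargetError`),
ring component thinner than 3 px (`DegenerateFitError`), a measurement
column with no meniscus pixels (`MissingEdgeError`, naming the column).
Non-measurement window columns without pixels are dropped with a warning.

## Segmentation architecture

A DeepLabv3-style encoder at output stride 8: a ResNet50-layout backbone
(7×7/stride-2 stem, 3×3/stride-2 max pool, bottleneck blocks of depth
3/4/6/3) in which the last two blocks keep stride 1 and use dilations 2 and
4·multi-grid (default multi-grid `(1, 1, 1)`); ASPP with five branches
(1×1 conv, three 3×3 atrous convs at rates 12/24/36, global-average pooling
restored bilinearly), concatenated and fused 1×1; a 1×1 classifier; and
bilinear restoration of the scores to the input size. Training mode adds an
FCN-style auxiliary head (3×3 conv → dropout 0.1 → 1×1 classifier) on the
third block's output, weighted 0.4 in the loss.

The per-layer dilation pattern follows the standard output-stride-8
DeepLabv3 convention (dilations 2 and 4, ASPP rates 12/24/36); all of these
are exposed in `NetworkConfig`. `base_channels` scales all widths together
(64 = the standard ResNet50 widths). Argmax ties break to the lower class
index, so an all-zero score map predicts no target.

### Initialisation and parameterisation

Weights use He fan-out initialisation, seed-controlled, with no
pretraining. Three conditioning choices matter at small learning rates:

* the final per-class projections (main and auxiliary) start at zero, so an
  untrained model emits the maximum-entropy tie and the first gradient
  steps move in a useful direction;
* the last batch-norm scale of every bottleneck starts at zero (the
  familiar zero-init-residual trick), so each residual unit begins as (a
  projection of) the identity and low-level image contrast survives to the
  encoder output at initialisation;
* `logit_scale` multiplies the class projections by a fixed constant
  (default 1, the standard parameterisation). Width-reduced models need it:
  the optimiser recipe's learning rate is appropriate for the full-width
  model, and when the width shrinks the output multiplier must grow
  correspondingly for feature-to-logit learning to proceed at the same
  rate — the standard scale-aware-parameterisation argument. The
  desk-scale experiments use `64 / base_channels`. Diagnostics behind this
  choice: at initialisation a converged linear readout of the encoder
  features already solves the phantom task (cross-entropy ≈ 0.006, IoU
  ≈ 0.99), but the solution requires a head-weight norm of ≈ 6, which SGD
  at learning rate 1e-4 cannot reach within a desk-scale step budget under
  the unit parameterisation; the multiplier restores the balance without
  touching any optimiser hyperparameter.

### The NumPy engine

The network runs on a small CPU engine written for this package
(`tmhkit.nn`): NCHW float32 tensors, convolution as one GEMM per kernel tap
against a strided view (stride and dilation come out of the slicing, with no
im2col buffer), batch normalisation, 3×3/stride-2 max pooling, dropout,
global average pooling and separable bilinear resizing, each with a
hand-derived backward pass. Backward passes are verified against central
finite differences in float64 in the test suite at the layer level.

## Training recipe

SGD with momentum 0.9 and weight decay 1e-4 (applied to convolution kernels
only, not to normalisation parameters or biases — the usual convention);
peak learning rate 1e-4 annealed to 0 by a cosine schedule evaluated at
every optimisation step over `max_epochs × steps_per_epoch` total steps;
batch size 4; 480×480 random crops at instrument resolution; augmentation
by horizontal flip (p = 0.5), rotation ±10°, translation ±5% and HSV jitter
(hue ±0.02, saturation/value ×[0.8, 1.2]) — ranges chosen as mild,
label-preserving defaults. Cropping precedes the photometric jitter.
Geometric transforms use nearest-neighbour resampling for masks so labels
stay binary. The loss is per-pixel cross-entropy on the main output plus
0.4× the auxiliary head's cross-entropy. The retained "optimal" model is
the snapshot of the epoch with the lowest mean training loss; there is no
validation split, matching a train/test-only protocol.

## Synthetic phantoms

No clinical images ship with the package, so every stage is exercised on
synthetic phantoms with exact ground truth: a bright annulus (the CCPR) over
a concentric iris-like ripple, optional fainter distractor rings, a bright
meniscus band whose per-column thickness follows a constant / linear /
sinusoidal profile rasterised to whole rows, a vertical illumination
gradient, and clipped additive Gaussian noise. Default geometry mirrors the
instrument format: 1360×1024 px, 86 px/mm, ring radius 100 px, band ~30 px
(≈0.35 mm, a plausible clinical height). Because `true_tmh_mm` is defined
from the rasterised per-column row counts at the seven measurement columns,
the geometric read-out on the true masks recovers it exactly; the closure
property is tested over broad random spec families (image sizes 160–320 px,
all three profile shapes, scaled `px_per_mm`).

What the phantoms do **not** emulate: eyelashes, blinks, specular glints,
full placido ring patterns, vignetting, anisotropic sensor noise, or
ambiguous meniscus boundaries. Passing phantom tests therefore demonstrates
that the architecture, optimiser and read-out are implemented correctly and
compose end-to-end — not that the trained weights would transfer to
clinical images, which would require the original instrument data.

The phantom brightness contrast (meniscus 0.75, ring 0.90 over background
0.15) is a free parameter of the generator; real contrast is
instrument-dependent and unspecified.

## Desk-scale problem sizes

The full instrument-scale recipe (hundreds of images, 500 epochs at
480×480, standard widths) is a GPU-days workload. The package's benchmark
experiment (`tmhkit.experiments.overfit_phantoms`) keeps every element of
the topology and the optimiser settings but scales the problem: 8 phantoms
at 128×128, a width-reduced backbone (`base_channels=6`) with ASPP at 384
channels, atrous rates 3/6/9 matched to the 16×16 encoder grid, the
width-matched output multiplier described above, no augmentation, and 1200
optimisation steps (600 epochs of 2 steps). On one CPU core this runs in
roughly ten minutes and memorises the training set (final-epoch loss
≈ 0.05, target-class IoU ≈ 0.95) — the qualitative behaviour expected of a
healthy implementation of this architecture and recipe. The phantom band
occupies ≈ 0.11 of the image height at this scale (a thicker fraction than
clinical images) because at output stride 8 a 128-px image must give the
band ≈ 2 encoder cells to be resolvable at all. Evaluation sweeps
(geometry closure, metric properties) use 100 random phantoms at reduced
resolution for the same reason.

## Metrics

Overlap: IoU, Dice and sensitivity (= recall, TP/(TP+FN)) from exact pixel
confusion counts, reported per class and as unweighted class means
("mIoU"-style). Precision is reported alongside because the two quantities
are easy to conflate; the implemented sensitivity is the recall formula.
Conventions: IoU/Dice of two empty masks are 1.0; sensitivity/precision are
NaN in per-class tables (error for the scalar functions) when undefined.

Agreement between automated and manual TMH: ordinary least squares with the
true value as ordinate and the predicted value as abscissa, and ICC(2,1) —
two-way random effects, absolute agreement, single measures — computed from
explicit two-way ANOVA mean squares. The variant is fixed to ICC(2,1)
because model-vs-clinician agreement treats both raters as random and
penalises systematic offsets; the implementation is cross-checked against
pingouin in the test suite.

## Known limitations

* The trained-at-desk-scale networks are demonstrations of the training
  machinery, not clinically usable weights.
* The CPU engine is single-device and eager; it is fast enough for the
  desk-scale experiments it exists for, not for instrument-scale training.
* The circle fit on a cavity-filled disk estimates the centre robustly but
  the fitted radius of a solid disk is smaller than the outer radius (the
  algebraic fit balances interior pixels); only the centre feeds the
  measurement, so this does not affect TMH.
* Rounding the ring centre to a column before windowing can shift the
  measurement grid by one pixel; with slowly varying thickness profiles the
  induced TMH error is below half a pixel, inside the tested closure bound.
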