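# Methods

## Problem and scope

The mandibular canal (MC) carries the inferior alveolar nerve through the
lower jaw; segmenting it in cone-beam CT (CBCT) is a prerequisite for implant
and third-molar surgery planning. CBCT contrast is low, and along parts of
the canal the cortical-bone rim that outlines it becomes ambiguous or
invisible, so purely per-slice models lose the canal and produce
discontinuous segmentations. This package implements a continuity-aware
segmentation network for such tubular structures — a 3D U-Net-style
encoder–decoder with a bidirectional convolutional LSTM (ConvLSTM) decoder
and a multi-planar projection (MPL) multi-task loss — together with the full
evaluation protocol (seven metrics, per-slice profiles, paired statistics,
cross-validation, loss-weight ablation) and a synthetic phantom generator so
that every component is exercisable without clinical data.

Clinical CBCT volumes are not distributed with the package; all experiments
here run on phantoms, and the numeric results in tests and in
`scripts/acceptance.py` characterise behaviour on those phantoms, not on
patient data.

## Phantom generator

A phantom is a curved tube in a noisy background:

* **Centerline** — a natural cubic spline through ≥ 2 control points,
  parameterised by the slice coordinate (so the curve is single-valued per
  slice) and resampled at ≤ 1-voxel arc-length steps.
* **Geometry** — lumen of radius `tube_radius_vox` (default 2.0) and a
  cortical rim ring of thickness `rim_thickness_vox` (default 1.5). The
  ground-truth mask is the full tube *including the rim*, matching the
  annotation convention under which canals are traced together with their
  cortical wall.
* **Intensities** — abstract floats, not Hounsfield units: background 0.35,
  lumen 0.15, rim 0.75, additive Gaussian noise (σ = 0.05 by default) over
  the whole volume. Defaults give a CBCT-like bright-rim/dark-lumen
  appearance with moderate contrast-to-noise.
* **Low-visibility gaps** — each `(start, end, attenuation)` segment of the
  arc length fades the *entire tube cross-section* (rim and lumen) linearly
  toward the background; attenuation 1 makes the canal locally invisible.
  Fading only the rim would leave the dark lumen as an unambiguous cue and
  the "low visibility" stretch would not actually be hard to segment.
  The truth mask is unaffected by gaps.
* **Streaks** — optional additive bright lines with a Gaussian cross-profile
  (σ = 1 voxel, amplitude 1.5 × rim-background contrast), a minimal metal
  artifact analog.

Everything is reproducible from `PhantomSpec.seed`. `generate_dataset`
mirrors "right-side" phantoms along axis 2 so the horizontal-flip
preprocessing step has something to act on.

What the phantom does **not** model: anatomy around the canal (teeth,
trabecular texture, bone boundaries), beam hardening, scatter, partial-volume
blur at tissue interfaces, or the 16-bit CBCT intensity range. Passing tests
on phantoms therefore demonstrates the correctness and the qualitative
behaviour of the method, not clinical-grade accuracy.

## Network

Feature maps are `(T, C, H, W)` with axis 0 the slice axis. The default
configuration has 4 resolution levels; the miniature test configuration has
3 levels with channels (8, 16, 32) or (4, 8, 16).

* **Encoder** — per level, two (convolution, batch-norm, ReLU) modules and a
  2×2×2 max-pool. Convolutions are *time-distributed*: 3×3 kernels applied
  independently per slice, which is the defining property of the encoder in
  this design; a `volumetric_kernels` switch restores literal 3×3×3 kernels.
  With `multiscale_inputs`, an average-pooled image pyramid is concatenated
  (1 extra channel) at each level below the first, mitigating the
  information loss of pooling.
* **Decoder** — per level, nearest-neighbour 2×2×2 up-sampling, skip
  concatenation from the matching encoder level, and a bidirectional
  ConvLSTM: independent forward and backward recurrences along the slice
  axis with 3×3 convolutional gates, hidden sequences concatenated on the
  channel axis, then batch-norm/ReLU and a 3×3 convolution. The plain
  variants replace the ConvLSTM with two convolution modules.
* **Output head** — with `side_outputs`, each decoder level (and the
  bottleneck) contributes a 1×1-projected, up-sampled, sigmoid side map;
  the maps are averaged and passed through a final bidirectional ConvLSTM
  and a 1×1 sigmoid projection. Averaging after the sigmoid keeps all maps
  on the probability scale. Without side outputs the last decoder level
  feeds the head directly.

Nearest-neighbour up-sampling (rather than transposed convolution) avoids
checkerboard artifacts and has an exactly invertible gradient, which keeps
the layer oracle-testable. Weights use He-style uniform fan-in
initialisation from the config seed; ConvLSTM forget-gate biases start at 1
(standard LSTM practice) so gradients propagate along the slice axis from
the first epochs.

The four comparison variants are flag presets of one config: `canal_net`
(recurrent decoder + side outputs + multi-scale inputs, trained with the
multi-task loss), `convlstm_only` (recurrent decoder only, volume loss
only), `mpl_only` (plain decoder, multi-task loss), `plain` (plain decoder,
volume loss).

### The numpy backend

No deep-learning framework is a dependency: `canalnet.nn` is a small
reverse-mode autodiff engine (float64, im2col convolutions, iterative
topological-order backprop) with exactly the layers the network needs, plus
Adam. Finite-difference tests pin every primitive's gradient. The engine is
single-threaded NumPy/BLAS and comfortably handles the miniature problem
sizes used throughout (a full forward+backward pass of the miniature
network is ~0.1–0.5 s).

## Loss

`L = α·DL_vol + β·(DL_ap + DL_cp + DL_sp)` where `DL_vol` is the soft Dice
loss `1 − (2Σpt + s)/(Σp + Σt + s)` on the volume and the three planar terms
are soft Dice losses between **maximum** projections of prediction and truth
along axes 0/1/2 (axial/coronal/sagittal silhouettes). Max-projection is the
natural silhouette operator for a probability map — it preserves [0, 1] and
is differentiable except on ties (the subgradient routes to the first
argmax); a mean-projection mode is available. Defaults: (α, β) = (0.7, 0.3),
smoothing constant s = 1e−6 (small, so identity cases stay sharp). The loss
is applied to the final output only; side outputs contribute through the
averaging head rather than as separate supervised terms.

## Metrics

With TP/FP/FN voxel counts: DSC = 2TP/(2TP+FP+FN), JI = TP/(TP+FP+FN),
PR = TP/(TP+FP), RC = TP/(TP+FN); VOE = 1 − |∩|/|∪| and
RVD = |V_gt − V_pred|/V_gt on voxel counts. When both masks are empty the
overlap metrics are 1 and VOE is 0 (identity of empties); RVD is undefined
for an empty ground truth and raises.

MCD (mean curve distance) extracts centerlines of both masks by 3D
morphological thinning and averages, over ground-truth centerline voxels,
the Euclidean distance in mm to the nearest predicted centerline voxel. The
distance is Euclidean, not squared — MCD carries millimetre units; a
`squared=True` flag provides the squared-kernel variant for completeness.
MCD is deliberately asymmetric (truth → prediction). An empty prediction
yields an infinite MCD, which the harness replaces by a large finite penalty
when averaging.

Per-slice profiles report, for every truth-occupied slice along axis 0, the
2D DSC and the mean distance from truth-skeleton voxels in that slice to the
full predicted skeleton — the along-canal accuracy profile from one foramen
to the other. Probability maps are binarised at 0.5 before all metrics.

## Statistics

* Paired two-tailed t-test (df = n − 1) for model comparisons on the same
  cases; identical samples return (t = 0, p = 1), constant non-zero
  differences raise as degenerate. Pairwise p-values are reported
  uncorrected.
* Bland–Altman agreement between true and predicted voxel counts: bias =
  mean difference, limits of agreement = bias ± 1.96 sd (large-sample
  multiplier).
* A-priori sample size: the smallest equal per-group n whose exact
  noncentral-t power for a two-sample two-tailed test reaches the target,
  returned as 2n. Only the two-sample reading reproduces the canonical
  N = 128 at d = 0.5, α = 0.05, power 0.80, so that design is the default.

## Training protocol

Adam (β₁ = 0.9, β₂ = 0.999), batch size 1, learning rate 0.00025 at full
scale. "Reduce on plateau" is implemented as plateau *detection*: the
learning rate is halved when the validation loss (train loss if no
validation set) has not improved for 25 consecutive epochs; a fixed-step
decay mode is available as `schedule="step"`. Training is fully seeded and
deterministic; two runs with the same seed produce identical histories.

Cross-validation partitions subjects (not volumes) into five cells; fold k
tests on cell k, validates on cell k+1, trains on the rest, giving the
30/10/10 subject split at n = 50 and keeping both sides of one subject in
the same block.

## Scaled-down experiments

CPU-scale problem sizes, chosen once as the package's test conditions:

* **Overfit capacity check** — one noiseless 16×32×32 phantom, 3 levels,
  channels (8, 16, 32), lr 5e-3, 150 epochs: final training loss < 0.1 and
  training DSC > 0.9.
* **Loss-weight ablation** — the 9-row grid α ∈ {0.1, …, 0.9}, β = 1 − α,
  one model per row on a shared split/seed, reporting 3D DSC and the three
  projected 2D DSCs.
* **Continuity experiment** — per seed, 12 phantoms (16×24×24) each with a
  stretch of 25–40% of the canal at attenuation 1.0 (tube locally
  invisible), 9 train / 3 test, both `canal_net` and `plain` trained for 100
  epochs at lr 1e-2 (enough for both variants to saturate their training
  loss). The full model should achieve mean test MCD at most that of the
  plain baseline in most seeded replicates — the scaled-down analog of the
  claim that recurrence plus projection losses preserve continuity where
  visibility fails. Gap severity matters here: with mild gaps both variants
  segment the phantom nearly perfectly and the comparison degenerates to
  optimisation noise.

## Numerical and degenerate-input choices

* Float64 throughout the network; gradient identities tested at 1e−4
  relative tolerance (projection subgradients checked away from ties).
* Pooling requires all three axes even at every level; the config validates
  divisibility by 2^(levels−1) up front and `crop_and_pad` zero-pads the
  slice axis (end-padding when short, center-crop when long).
* Skeletonization tolerance: thinning of a discrete cylinder may wobble by
  one voxel around the true axis; property tests assert within-1-voxel
  bounds rather than exact coordinates.
* Tie-breaking: max-projection and max-pooling route gradients to the first
  maximum.

## Known limitations

* The phantom background is featureless noise; real CBCT surroundings
  (teeth, cortical plates) produce distractors the phantom cannot represent.
* At miniature scale the capacity gap between variants is small, and the
  plain baseline is nearly as accurate outside low-visibility regions;
  variant differences here are only meaningful on gap-bearing phantoms.
* The numpy backend is CPU-only and single-threaded; full-resolution
  (200×128×128) training is configurable but not practical with it.
* Side outputs are supervised only through the averaging head; classic
  deep-supervision (a loss per side map) is not implemented.
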