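# Methods

## Model

The package trains a 2D segmentation student under the mean-teacher
assumption: predictions for the same input under different perturbations
should agree, and a teacher whose weights average the student's past states
is a better supervision target than the student itself.  Two teachers guide
the student simultaneously.  Teacher 1 shares the student's architecture
exactly and is updated only by the exponential moving average
θ_T ← η·θ_T + (1−η)·θ_S after every student step (η = 0.99; teacher 1 starts
as a parameter copy of the student, so its weights are always a convex
combination of past student weights).  Teacher 2 additionally consumes a
pseudo-3D stack — the slice plus its `context_radius` neighbours on each
side (default radius 1, i.e. three planes; volume ends replicate-padded) —
through a 3D convolution stem whose plane-axis extent equals the stack depth
with valid padding there.  Because that stem collapses the plane axis
completely, it is arithmetically a 2D convolution treating planes as input
channels, and is implemented as such.  Its output is concatenated with the
2D features of the centre plane and reduced by a 1×1 fusion convolution,
after which the network is the same U-Net as the student.

All three networks emit a final sigmoid map plus two auxiliary sigmoid heads
(a second 1×1 convolution on the last decoder features; the half-resolution
penultimate decoder features upsampled and passed through a 1×1
convolution).  Only the student's auxiliary heads enter any loss; the
teachers contribute their final maps alone.

## Discrepancy extraction and losses

Per batch, the confidence anchor A is the ratio of sums
Σᵢ Sum(f_s(xᵢ)·yᵢ) / Σᵢ Sum(yᵢ) over the labelled half — the average
probability the student assigns to true target pixels.  It partitions
teacher 1's map on the unlabeled half into high (f_t1 ≥ A) and low
confidence; the anchor enters only through this partition (an optional
`binarize_teacher1_at_anchor` flag hardens teacher 1's map at A instead,
preserving an alternative reading of "optimising" the teacher prediction).
The maps D1 (partition-weighted), D2 (un-partitioned, against teacher 2) and
D = m·D1 + n·D2 are built from elementwise absolute differences so that they
are nonnegative uncertainty surrogates; they keep per-pixel, per-sample
resolution because the consistency gate needs pixel-level decisions.  The
batch-level sums in the defining equations are realised inside the loss
reductions.

Losses: supervised Dice (smooth constant 1e-5) summed over the labelled
samples of the batch; the discrepancy loss mean(D²) (MSE against the
all-zero image); and gated consistency losses between the student's final
map and each teacher's final map, a masked MSE with weight α on {D > TH} and
β on {D ≤ TH}.  Each masked MSE is normalised by its own pixel count so that
α and β are not confounded with region size; an empty region contributes
zero.  Teachers are constants in every loss — gradients reach the student
only.

Unstated constants default to neutral choices, all exposed in
`DiscrepancyConfig`/`LossWeights`: a = b = c = 1/3, High = Low = 1,
m = n = 1/2, TH = 0.1 on the combined-D scale, α = 0.6 / β = 0.4 (more
weight on high-uncertainty regions), w = v = 1/2, X = Y = Z = 1.  The
unsupervised terms are scaled by a Gaussian warm-up exp(−5(1 − t/L)²) for
the first L = 100 iterations (`ramp_length`): freshly initialised teachers
produce noise targets, and without the ramp they can swamp the supervised
signal early.

## Training protocol

SGD with learning rate 0.02, momentum 0.9 and weight decay 1e-4 updates the
student only; batches hold 4 labelled and 4 unlabeled slices (each unlabeled
slice accompanied by its stack), sampled without replacement within an epoch
of the respective pool and reshuffled between epochs.  Student and teacher
streams see the same images under independent additive Gaussian input noise
(sd 0.1, clipped to [0, 1]) — the standard mean-teacher perturbation; all
noise, sampling and initialisation streams derive from three named seeds in
the config, and the labelled-stream draws are independent of whether the
unsupervised machinery runs, which is what makes the supervised-only
reduction step-equivalent.

Teacher 2 has no EMA partner for its stem and fusion layers, and an EMA
across different architectures is undefined.  Its update rule is therefore
two-part, a deliberate design choice in the face of an open gap: every
parameter whose name and shape mirror the student's receives the same EMA
update with the same η, while the stem and fusion parameters are trained by
gradient descent on the supervised Dice loss over the labelled samples'
stacks (same optimizer settings).  This preserves "the teacher aggregates
the student" wherever shapes permit while giving the 3D pathway a learning
signal; it is the package's single largest judgement call.

The per-iteration mean pixel value of D (discrepancy rate Dr) is averaged
over unlabeled-pool epochs for the Dr-vs-training diagnostic; its smoothed
series (window-3 moving average) is summarised by the Spearman correlation
with the epoch index.

## Architecture and numerics

The U-Net uses one 3×3 convolution + instance normalisation + ReLU per
resolution level (depth levels double the channel count; 2×2 max pooling
down, nearest-neighbour upsampling and skip concatenation up).  Instance
normalisation (per-sample, per-channel, learned affine) was chosen over
batch statistics because it is stateless: teacher copies and EMA updates
stay exact, and evaluation is deterministic.  Without normalisation the
prescribed learning rate saturates the sigmoid heads and training collapses
to all-background.  He-normal initialisation, float32 arithmetic throughout;
the autodiff engine's operators are verified against central finite
differences in float64.  Max-pool gradient ties resolve to the first
argmax.  Default geometry is 128×128 inputs with a depth-4, base-16 U-Net;
the desk-scale studies use 64×64 inputs with depth 3 to fit a single-CPU
budget (problem sizes below).

Preprocessing per slice: min-max normalisation to [0, 1] (constant slices
map to zero), gamma brightening with γ = 0.8 (γ < 1 lifts the mid-range;
the exponent is configurable), bilinear resize of intensities and
nearest-neighbour resize of labels to the input size (preserving binarity).
Training slices with an empty label plane are dropped; inference keeps every
slice so the predicted volume reassembles completely.  Pseudo-3D stacks are
assembled before the empty-slice filter so kept slices retain their true
neighbours.

Evaluation binarises reassembled probability volumes at 0.5 (≥ convention)
and reports Dice, Jaccard, ASD and HD95.  Boundaries are foreground voxels
with at least one background 6-neighbour (outside the array counts as
background); distances use the exact Euclidean distance transform with
physical spacing.  HD95 defaults to the 95th percentile of the pooled
symmetric nearest-boundary distances — the convention of the comparative
segmentation literature; a `scaled_max` flag preserves the literal
0.95·max[d(X,Y), d(Y,X)] reading, which is recorded but nonstandard.
Both-empty masks score Dice = Jaccard = 1; surface metrics on an empty
boundary raise a defined error, which volume-level evaluation records as
NaN rather than a silent infinity.

## Synthetic phantoms

`generate_phantom` emulates the structure the slicer sees in contrast MRI of
the atrium: one large bright quasi-spherical blob with a few small satellite
blobs attached to its surface (vessel stumps), on a darker background,
Gaussian-blurred (σ = 1 voxel) to soften boundaries and corrupted with
i.i.d. Gaussian noise (sd 0.05).  Foreground/background intensities 0.8/0.3
give roughly the contrast of a gadolinium-enhanced blood pool.  The label is
the exact rasterised blob union.  Defaults (64×64×32 grid, main radius 9–13
voxels, two satellites of radius 2–4) make most Z planes carry a target
whose cross-section varies, with empty end planes exercising the slice
filter.  The phantoms deliberately lack several properties of real scans —
anatomical shape variability, bias fields, anisotropic spacing, neighbouring
bright structures, ambiguous boundaries — so passing desk-scale studies
demonstrates that the training machinery and losses behave as specified, not
that the method reaches clinical accuracy; real-data performance must be
established on real data.

## Desk-scale problem sizes

The bundled studies use 20 phantoms (two held out), 10% of training volumes
labelled, a base-16 depth-3 U-Net on 64×64 slices, batches of 4+4, and 400
iterations (about 3 unlabeled-pool epochs) — sizes chosen so a full study
runs in a few minutes on one CPU while still showing the qualitative
behaviour of interest: test Dice above 0.95, the full framework matching or
exceeding its supervised-only baseline, and a falling epoch-mean
discrepancy rate.

## Known limitations

* The teacher-2 update rule is a constructed design (see above), not a
  documented prescription; alternatives (pure gradient training, frozen
  stem) are plausible.
* Perturbations are input-noise only; augmentation-style transforms are out
  of scope.
* The consistency losses compare final maps only; auxiliary heads influence
  training solely through the discrepancy maps.
* Binary segmentation only; one foreground class.
* The autodiff engine implements exactly the operator set these networks
  need; it is not a general deep-learning framework (no GPU, no mixed
  precision, no distributed training).
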