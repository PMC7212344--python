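# Methods

## Problem and approach

Automatic contouring models for radiotherapy planning emit, per CT slice,
a probability map `p(i,j) ∈ [0,1]` that each pixel belongs to the target
structure. Clinically the generated contours still have to be reviewed
slice by slice. `segqa` implements an automatic quality-assurance (QA)
step that predicts, for each slice and *without access to the ground
truth*, how good the auto-segmentation is. Quality is defined through the
Dice similarity coefficient

    DSC(A, B) = 2 |A ∩ B| / (|A| + |B|)

between the ground-truth mask A and the predicted mask B (the probability
map thresholded at 0.5). Two output formulations are supported:

- **3-level head** — good: DSC ∈ [0.95, 1]; medium: [0.8, 0.95); bad:
  [0, 0.8). Boundary values belong to the better bin.
- **101-class head** — DSC discretized to `round(100·DSC)` (half-up);
  the prediction is mapped back as `class / 100`.

The QA classifier consumes up to three co-registered channels: the CT
slice, the probability map, and the uncertainty map
`u = min(p, 1 − p)`, which peaks (0.5) exactly on the segmentation
model's decision boundary.

### Empty-contour convention

Slices where both A and B are empty score DSC = 1 ("the segmentation is
perfect — there was nothing to contour"). When exactly one of the two is
empty the Dice formula itself yields 0 and we keep that value: a missed
contour or a hallucinated contour is a failure, not a success. A
`paper_literal` mode is available in `slice_dsc` that instead returns 1
whenever *either* mask is empty — the looser clinical reading — but it is
not the default because it would label clear segmentation failures as
"good".

## Synthetic cohort

No public dataset with per-slice probability maps and ground truth
exists for this task, so the package ships a generator that emulates the
statistical structure the QA method consumes.

**Phantom.** Each patient is a stack of 512×512 slices: an elliptical
soft-tissue body (≈30 HU) containing a lung-like void (≈−750 HU) and a
breast-like half-ellipse target (≈120 HU) on an air background
(−1000 HU), plus Gaussian texture noise (SD 20 HU). The target's
semi-axes follow a per-slice profile that is zero at both stack ends and
a sine arc rescaled to [0.35, 1] in between, so the contour appears,
grows, shrinks and disappears along the stack and every nonempty contour
area stays within 440–12,440 px — the per-slice size range of clinical
breast CTV contours. Per-patient geometry is mildly jittered (semi-axes
±15%/+5%, center ±8 px), with jitter bounds chosen so the target always
remains strictly inside the body.

**Perturbation engine.** The "auto-segmentation" is derived from the
ground truth through its signed Euclidean distance field d (negative
inside). The predicted contour is the zero level-set of

    d'(x) = d(x − shift) + deform_amplitude · sin(f·θ(x) + φ) − dilation

and the probability map is `p = σ(−d'/τ)`, a logistic profile of width τ
across the boundary, so thresholding at 0.5 recovers the perturbed mask
exactly for any τ. Two discrete failure modes are superimposed: dropout
(the map is all zeros — the model missed the structure) and spurious
blobs (a high-probability disk disjoint from the target — a hallucinated
contour). Default τ = 3 px at 512² resolution, a typical soft-boundary
width for CNN segmentation outputs; it survives downsampling to the QA
input size so the uncertainty band remains informative.

**DSC calibration.** Because the perturbation acts on a continuous
distance field, the DSC is monotone non-increasing in the magnitude of
each single perturbation parameter, and a bisection (≤60 iterations,
tolerance 0.02, with bracket expansion) can solve for the magnitude that
realizes any requested DSC. Dilation changes area in integer steps and
can be too coarse near DSC = 1 on small masks; the generator therefore
falls back through shift and deformation (sub-pixel smooth) when a
parameter cannot reach the target.

**Mix control.** Requested good/medium/bad proportions are converted to
slice quotas (largest remainder) and filled explicitly. Stack-end slices
(empty ground truth) consume the good quota first (both-empty → DSC 1);
overflow empties absorb the bad quota via spurious blobs (DSC 0). Within
the bad quota a 10% share is realized as dropout. Nonempty slices draw a
target DSC uniformly inside their bin, kept ≥0.025 away from the
0.8/0.95 bin edges so the calibration tolerance cannot flip the realized
level. Splits are assigned per patient (never per slice) in a
65:10:10 train/validation/test ratio by default.

**What the generator does not emulate.** Real anatomy (organ texture,
neighboring structures, inter-patient shape variability beyond ellipse
jitter), scanner physics, and — most importantly — the error *structure*
of a real segmentation CNN, whose probability maps correlate with image
content in ways a geometric perturbation cannot. Passing benchmarks here
demonstrates that the QA method recovers quality signal from
probability/uncertainty/CT channels under controlled conditions; it does
not certify performance on clinical data.

## Preprocessing

Slices are resampled to 1.00 mm isotropic spacing (bilinear; masks
nearest-neighbor), center-cropped/zero-padded to 512×512 (odd remainders
to bottom/right), CLAHE contrast-enhanced (intensity channel only;
clip limit 0.01, 8×8 tiles — library-conventional values, configurable),
and downsampled to the QA input size with bilinear interpolation
(anti-aliased when shrinking), clipping probability and uncertainty
channels back to [0,1] and [0,0.5]. DSC labels are always computed at
full 512² resolution, before QA downsampling: the label should reflect
the segmentation, not resizing loss.

## Classifier

The default backbone is a small CNN trainable on one CPU in minutes:
three 3×3 conv+ReLU blocks (8, 16, 32 channels) with max pooling
(4, 2, 2), global average pooling and a linear softmax head (3 or 101
classes, zero-initialized so the initial loss is exactly ln K). It is
implemented directly on numpy (im2col convolutions, hand-written
backward pass). Training is plain softmax cross-entropy under SGD with
momentum 0.9, weight decay 5·10⁻⁴, batch size 16, and the poly schedule
`lr = base_lr · (1 − iter/max_iter)^0.9`. These optimizer constants are
the published fine-tuning schedule of the original ResNet-101 QA
network; its base rate 2.5·10⁻⁴ presumes ImageNet-pretrained weights,
so the from-scratch small CNN uses base_lr = 0.05 on the benchmark. A
`resnet101` backbone name is reserved for the faithful architecture but
is not trainable in this package (no GPU-scale autodiff stack); the
contribution under test is the QA framework, not the backbone.

Augmentation: random left-right flips, random crop-to-fraction 0.9 with
resize ("cutting"), and rotations uniform in ±5°, all applied jointly to
every channel so labels are preserved. Minority-class oversampling
(replication with replacement up to the majority count, originals always
retained) runs before on-the-fly augmentation; for the 101-class head
the balancing still groups by the 3 quality levels, since individual DSC
classes are too sparse to balance. The best-on-validation checkpoint is
returned (mean one-vs-rest balanced accuracy for the 3-level head, MAE
for the 101-class head). Prediction ties break to the lower class index.

## Evaluation

One-vs-rest per class g: TP/FP/TN/FN, balanced accuracy
`(sens + spec)/2`, F score `2TP/(2TP+FN+FP)`, and ROC AUC by the
Mann-Whitney rank statistic (ties count ½; classes without both
positives and negatives report NaN rather than a fabricated value). The
ROC score for class g is the softmax probability of g. DSC-value runs
report MAE over all pooled test slices, the SD of absolute errors, the
mean signed error, Pearson correlation, and fractions of predictions
within 0.03/0.05/0.10. Misclassification histograms bin the true DSC of
wrongly classified slices per predicted class (half-open bins, width
0.05).

## Benchmark scale and numerical choices

The reference benchmark is 40 patients × 20 slices (800 slices, even
three-way mix, seeded), generated at 512² and classified at 96² — chosen
as the smallest input size at which the good/medium distinction (a
boundary-band difference of ~1–3 px at 512²) survives downsampling;
at 64² the signal is largely lost to resizing. Schedules: 1500
iterations for the headline 3-level model, 2000 for the 101-class model,
800 for the uniform six-way channel ablation. Random crop is disabled on
the benchmark: at 96² the crop-resize cycle destroys the sub-pixel
boundary signal the task depends on.

Degenerate inputs: constant images pass through CLAHE unchanged;
empty masks have no signed distance field and map to all-zero
probability; calibration on an empty mask, unreachable DSC targets, and
metric computation without positive/negative support all raise
descriptive errors instead of returning silently clamped values.

Known limitations: phantom realism (above); the numpy CNN is desk-scale,
not a replication of the published ResNet-101 results, and the published
Table-1-level numbers (BA 0.89–0.97) are specific to the private
680-patient cohort; on the synthetic benchmark the same qualitative
ordering holds (all-channel best, CT-only worst) at somewhat lower
absolute values for the harder classes.
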