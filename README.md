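# segqa — per-slice quality assurance for automatic contour segmentation

Deep-learning contouring tools for radiotherapy emit a segmentation
probability map per CT slice, but clinicians still review every generated
contour slice by slice. `segqa` implements an automatic QA step that
predicts per-slice contour quality *without ground truth at inference
time*, from three co-registered channels: the CT slice, the segmentation
probability map `p(i,j)`, and the uncertainty map `u(i,j) = min(p, 1−p)`
(maximal on the segmentation model's decision boundary).

Quality is defined through the per-slice Dice similarity coefficient
between the ground-truth mask A and the thresholded prediction B,

    DSC(A, B) = 2 |A ∩ B| / (|A| + |B|),

with DSC = 1 when both masks are empty. A CNN classifier predicts either

- a **3-level quality class** — good `[0.95, 1]`, medium `[0.8, 0.95)`,
  bad `[0, 0.8)`; evaluated per class (one-vs-rest) with balanced
  accuracy, F score, and ROC AUC; or
- a **discretized DSC value** — 101 classes (0…100, mapped back as
  class/100); evaluated with mean absolute error and correlation.

Because no public cohort with per-slice probability maps exists, the
package ships a synthetic generator: CT-like phantoms with a breast-like
target whose auto-segmentation is emulated by perturbing the ground-truth
contour through its signed distance field (shift, dilation, smooth
deformation, dropout, spurious blobs). The perturbation magnitude can be
*calibrated by bisection to any requested DSC*, giving exact control of
the quality distribution. See `docs/methods.md` for the full model.

Intended users: researchers in medical image analysis / radiotherapy
workflow automation who want a reproducible, desk-scale testbed for
segmentation-QA methods.

## Worked example

```python
import numpy as np
from segqa import phantom, qa

params = phantom.PhantomParams(seed=0)
ct, gt = phantom.make_phantom(params, slice_index=10)

# degrade the contour to a target Dice of 0.85 by translating it
cfg = phantom.calibrate_to_dsc(gt, target_dsc=0.85, free_parameter="shift")
prob = phantom.perturb_segmentation(gt, cfg)
unc = qa.uncertainty_map(prob)

dsc = qa.slice_dsc(gt, qa.threshold_probability(prob))
print(f"contour area:     {int(gt.sum())} px")
print(f"calibrated shift: {cfg.shift:.2f} px")
print(f"achieved DSC:     {dsc:.4f}")
print(f"quality level:    {qa.QUALITY_NAMES[qa.bin_quality(dsc)]} "
      f"(class {qa.discretize_dsc(dsc)})")
print(f"uncertainty max:  {unc.max():.2f}")
```

prints

```
contour area:     7788 px
calibrated shift: 13.00 px
achieved DSC:     0.8498
quality level:    medium (class 85)
uncertainty max:  0.34
```

The mid-stack phantom contour covers 7,788 px (clinical breast contours
span 440–12,440 px per slice). A 13 px translation of the predicted
contour realizes a Dice of 0.8498 — within the 0.02 calibration
tolerance of the requested 0.85 — which falls in the "medium" bin
(moderate edits needed) and DSC class 85. The uncertainty map peaks near
the displaced boundary.

## Command-line workflow

```bash
segqa generate --out data --seed 7              # synthetic cohort (NIfTI + manifest CSV)
segqa label    --data data --out labels         # per-slice DSC / level / class + uncertainty volumes
segqa train    --data data --out run            # QA classifier, best-on-validation checkpoint
segqa evaluate --data data --checkpoint run/checkpoint_model.npz --out eval
segqa ablate   --data data --out ablation       # all six input-channel combinations
segqa report   --metrics-json eval/metrics.json --out figs
```

Every command echoes its fully resolved YAML config into the output
directory; a single global seed makes the whole chain reproducible.

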