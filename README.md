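# kbfmgmt

Identification of MGMT promoter methylation — a favorable chemotherapy-
response biomarker in glioblastoma — from routine brain MRI, without tumor
segmentation masks.  The package implements a three-stage pipeline for
radiologists' and radiogenomics researchers' use on paired FLAIR / T1-w
series:

1. **Preparation** — DICOM series → 3-D volumes (ordered by Slice
   Location), 1 mm isotropic resampling, reorientation to a standard
   sagittal frame, rigid inter-modality registration (Mattes mutual
   information), skull stripping via an external or fallback brain mask.
2. **Knowledge-Based Filtering (KBF)** — unsupervised tumor-ROI
   preselection fusing two radiological priors: glioma is the brightest
   tissue on FLAIR and sits between CSF and parenchyma on T1-w.  Each
   sequence is split at its in-brain intensity mode; the top 25 % of
   supra-mode FLAIR voxels is intersected with the bottom 25 % of sub-mode
   T1-w voxels:

   `ROI = top_f(FLAIR > mode(FLAIR)) ∩ bottom_f(T1 < mode(T1))`, f = 0.25.

   The mask multiplies the FLAIR volume; the product is cropped to a
   192³ cube around the brain and min-max scaled to [0, 1] per patient.
3. **Classification** — `MGMTClassifier`: seven depthwise-separable
   convolutional blocks (depthwise 3×3(×3), stride 2, padding 1 →
   pointwise 1×1(×1) → batch norm → ReLU; channels 8, 16, …, 512) and two
   fully connected layers producing one binary logit; 2D (per-slice) and 3D
   (per-volume) variants share the schema.  Training: Adam, lr 5·10⁻⁴,
   batch 8, ≤150 epochs, flip/rotation augmentation, stratified 5-fold
   cross-validation; metrics ACC / SPE / SEN / PRE / F1 / AUC (positive
   class = methylation present).  Integrated-gradients and occlusion
   attribution maps explain individual predictions.

The CNN arithmetic (depthwise/pointwise convolutions, batch normalization,
dense layers, Adam, BCE) is implemented in NumPy with hand-derived backward
passes, verified against numerical differentiation in the test suite.

A seeded phantom generator (`kbfmgmt.synthdata`) produces paired
FLAIR/T1-w brain phantoms with ground-truth tumor masks and a
methylation-conditional tumor-texture signal, so the entire pipeline is
testable end to end without any data download.  See `docs/methods.md` for
the model, the generator's assumptions and every numerical convention.

## Worked example

```python
import numpy as np
from kbfmgmt import (PhantomParams, make_phantom, kbf_mask, KBFParams,
                     prepare_input)

ph = make_phantom(PhantomParams.small(), seed=13, label=1)   # 48 mm cube
roi = kbf_mask(ph.flair, ph.t1, ph.brain_mask, KBFParams(crop_side=48))
t, r = ph.tumor_mask, roi.grid
dice = 2 * (t & r).sum() / (t.sum() + r.sum())
print(f"tumor voxels: {t.sum()}   ROI voxels: {roi.n_voxels}   Dice: {dice:.3f}")

cube = prepare_input(ph.flair, ph.t1, ph.brain_mask, KBFParams(crop_side=48))
print(f"classifier input: {cube.shape}, range [{cube.min():.1f}, {cube.max():.1f}]")
```

prints

```
tumor voxels: 535   ROI voxels: 839   Dice: 0.735
classifier input: (48, 48, 48), range [0.0, 1.0]
```

The unsupervised filter found the tumor (Dice 0.74 against ground truth —
it aims to *localize*, not to segment pixel-perfectly; the extra ROI voxels
are the expected sparse outliers) and produced the fixed-size, normalised
cube the classifier trains on.

The same stages are scriptable from the shell:

```bash
kbfmgmt simulate --n 40 --prevalence 0.5 --seed 1 --preset small --out-dir cohort/
kbfmgmt train --data-dir cohort/ --dims 3 --crop-side 48 --folds 5 --seed 42
kbfmgmt model describe --dims 3            # layer table + parameter count
```

`kbfmgmt model describe --dims 3` ends with

```
Flatten          (4096,)                        0
Dense            (64,)                     262208
ReLU             (64,)                          0
Dense            (1,)                          65
total                                      452668
```

— 452,668 trainable parameters for the 3D variant (312,506 for 2D), two
orders of magnitude below the 14 M-parameter residual networks typically
fine-tuned for this task.

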