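# ctcforge

Detection of circulating tumor cells (CTCs) in microscopy images, for
settings where box-annotated training data are scarce. CTCs shed from a
tumor into the bloodstream are a key biomarker for early cancer diagnosis,
but they are rare (a handful per mL of blood), heterogeneous in size and
shape, and most public cell datasets carry only class labels — not the
bounding boxes a detector needs. `ctcforge` addresses this with three
pieces:

1. **Copy–paste image synthesis** — segment cells into masks *M*, extract
   transparent cutouts *C = I · M*, augment them
   (`RandomScale(Rotate(ColorJitter(C)))`), alpha-composite them onto
   unoccupied background regions, derive the bounding box from the paste
   location, and add Gaussian noise. Classification-only patch banks
   thereby become detection datasets.
2. **A transformer detection framework** — a hierarchical windowed-attention
   backbone with a *scale adapter* (feature-pyramid top-down fusion,
   `F_scale = FPN(F_stage1..4)`) and a *shape adapter* (per-level 3×3
   deformable convolution with learned sampling offsets,
   `F_shape = DeformConv(F_input, O_offset)`), feeding a dense head of
   stacked convolutions with per-location class and box projections.
3. **A mixed-source loss and evaluation suite** — single-source loss
   `L = L_c + L_b` (cross-entropy + smooth-L1); with synthetic data,
   `L = w_r·L_r + w_s·L_s + λ·R` where `w_r = N_r/(N_r+N_s)`,
   `w_s = N_s/(N_r+N_s)` follow the source sample sizes and
   `R = (1/N) Σ_j ‖ŷ_aug,j − ŷ_j‖²` enforces consistent outputs under
   photometric augmentation. Evaluation reports mAP@IoU 0.5, recall,
   precision, specificity and accuracy, with bootstrap resampling (1000
   resampled test sets by default) for stability intervals.

Everything runs on numpy — the network, its deformable convolution, and
AdamW training are built on a small reverse-mode autodiff engine included
in the package — so the full pipeline is testable on one CPU core with no
GPU and no downloads: a built-in fixture generator produces seeded
synthetic microscopy images (light-field or fluorescence) with pixel-exact
masks and boxes.

## Worked example

Train the CPU-sized detector on synthetic microscopy fixtures and evaluate
with bootstrap intervals:

```python
from ctcforge import CTCDetector, FixtureConfig, make_detection_dataset

train_ds = make_detection_dataset(FixtureConfig(n_images=200, image_size=128,
                                                n_classes=1, seed=1))
test_ds = make_detection_dataset(FixtureConfig(n_images=50, image_size=128,
                                               n_classes=1, seed=2))

det = CTCDetector(epochs=15, batch_size=8, score_threshold=0.8, seed=0)
det.fit(train_ds)
report = det.report(test_ds, n_boot=1000)
print(f"mAP@0.5     {report.map50:.4f}")
print(f"recall      {report.recall:.4f}")
print(f"precision   {report.precision:.4f}")
print(f"specificity {report.specificity:.4f}")
print(f"accuracy    {report.accuracy:.4f}")
```

Output (a few minutes on one CPU core):

```
mAP@0.5     0.9993
recall      1.0000
precision   0.8904
specificity 0.9843
accuracy    0.9860
```

`mAP@0.5` is the mean average precision at IoU threshold 0.5: the model
ranks every candidate box by confidence, and mAP integrates precision over
recall, so it summarizes both "did we find every cell" and "are the found
boxes right" independent of any operating point. The other four metrics
*do* depend on the operating point: `score_threshold=0.8` keeps only
confident detections (the default, 0.3, admits many low-confidence boxes
and trades precision for candidate coverage). Specificity and accuracy
additionally count seeded background candidate boxes as the negative class
(see `docs/methods.md` for the exact convention). `det.report(...)` also
carries `report.bootstrap`, the per-metric mean/SD/quartiles over 1000
resampled test sets.

To build a synthetic detection dataset from a classification-only patch
bank (the copy–paste engine):

```python
from ctcforge import (FixtureConfig, make_patch_bank, make_background,
                      synthesize_dataset, SynthesisConfig)
import numpy as np

cfg = FixtureConfig(seed=7)
bank = make_patch_bank(cfg, n_patches=40)          # labeled RGBA cutouts
rng = np.random.default_rng(7)
backgrounds = [make_background(cfg, rng) for _ in range(4)]
synthetic = synthesize_dataset(bank, backgrounds, SynthesisConfig(n_images=10))
det.fit(train_ds, synthetic=synthetic)             # mixed real+synthetic loss
```

A command-line interface mirrors the library:

```bash
ctcforge fixtures --out data/fx --n-images 20 --seed 1
ctcforge segment  --backend classical --in data/fx/images --out data/masks
ctcforge synth    --bank data/bank --backgrounds data/fx/images --out data/syn
ctcforge train    --real data/fx/annotations.json --real-images data/fx/images --out runs/r1
ctcforge eval     --gt data/fx/annotations.json --pred preds.json --n-boot 1000
ctcforge model-info --variant paper-base
ctcforge run      --out runs/full --seed 3
```

## Model variants

- `tiny-test` (default): embed dim 32, depths [1,1,1,1], window 4,
  32-channel pyramid — sized for CPU experiments and the test suite.
- `paper-base`: the published "base" windowed-attention backbone
  (embed 128, depths [2,2,18,2], heads [4,8,16,32], window 7) with a
  256-channel pyramid scale adapter, per-level deformable shape adapters
  and a 4-convolution head; 92.97 M trainable parameters.
  `ctcforge model-info --variant paper-base` prints the parameter and
  analytic multiply-accumulate totals.

## Layout

```
src/ctcforge/
  _tensor.py      reverse-mode autodiff engine (numpy)
  nn.py           layers + AdamW
  fixtures.py     seeded synthetic microscopy generator (exact ground truth)
  segmentation.py classical + promptable mask backends
  synthesis.py    copy–paste engine (cutout, augment, paste, noise)
  model.py        backbone, scale/shape adapters, dense head, complexity
  loss.py         losses, mixture weights, consistency regularizer
  training.py     AdamW recipe, cosine schedule, mixed batches
  evaluation.py   matching, AP/mAP, confusion metrics, bootstrap
  detector.py     scikit-learn style CTCDetector estimator
  pipeline.py     seeded end-to-end orchestration with manifests
  cli.py          `ctcforge` command-line interface
```
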