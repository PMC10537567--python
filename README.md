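# appleseg

Pixel-wise segmentation of surface defects on apples from
multi-spectral (RGB + near-infrared) or plain RGB images, aimed at
automated visual inspection lines where defects must be localized — not
just detected — to grade fruit correctly.

The package implements, end to end:

* a **lightweight U-shaped encoder–decoder network** built from
  inverted-residual bottlenecks (point-wise expand ×t → depth-wise 3×3 →
  point-wise reduce), with a noise-reduction block after the stem and a
  single encoder→decoder skip from that block by default (~7.7 GFLOPs
  at 4×430×560, full-resolution inference with no resizing);
* **copy-paste defect synthesis**: training-time transplantation of
  annotated defect regions from defective apples onto the ROI of
  healthy apples (1–3 defects, random rotation, optional elastic
  warping, six ablation setups, applied with probability P = 0.8);
* the **Focal Tversky Loss**
  `FTL = (1 − TI)^(1/γ)` with
  `TI = (Σpg + ε)/(Σpg + αΣ(1−p)g + (1−α)Σp(1−g) + ε)`,
  α = 0.5, γ = 0.75, which handles the extreme imbalance between defect
  pixels and apple surface;
* the evaluation protocol: pixel precision / recall / f-score and the
  **Class-Specific Recognition Error**
  `CSRE = (FN/(TP+FN) + FP/(TN+FP))/2` (one minus balanced accuracy),
  with per-macro-class and per-sub-class tables over a 4/10-way defect
  taxonomy;
* a **phantom generator** producing fully annotated synthetic
  multi-spectral apple images (textured ellipse on dark background,
  class-dependent defect contrast, one class invisible in NIR), so the
  whole pipeline runs and is tested without any external dataset.

The network trains and predicts on the package's own numpy autodiff
engine (`appleseg.nn`) — no deep-learning framework dependency.

## Worked example

```python
import numpy as np
from appleseg import (PhantomConfig, generate_samples, phantom_train_config,
                      train, evaluate)

def make(n_healthy, n_defective, seed):
    h, d = generate_samples(PhantomConfig(n_healthy=n_healthy,
                                          n_defective=n_defective, seed=seed))
    return h + d

train_set = make(48, 48, 11)   # 96 training phantoms at 128x128
val_set   = make(8, 8, 12)
test_set  = make(16, 16, 13)

cfg = phantom_train_config(max_epochs=30, seed=3)   # setup-5 synthesis, FTL
net, history = train(train_set, val_set, cfg=cfg)
report = evaluate(net, test_set)
print(report.overall)
```

Output from this exact run:

```
      aggregation      csre   f_score  precision    recall
0  mean_per_image  0.009619  0.900336   0.827394  0.990672
1   pooled_counts  0.009811  0.901858   0.827949  0.990256
```

Read: averaged over the 16 defective test phantoms, 99.1% of defect
pixels are recovered (recall) at 82.7% precision, f-score 0.90, and the
mean of the false-negative and false-positive rates (CSRE) is under 1% —
the high-contrast phantom task is segmented nearly perfectly after 30
epochs (~2 minutes on one CPU core). `report.macro` / `report.sub`
break the same metrics down by defect class.

The same pipeline is scriptable from the shell:

```bash
appleseg phantom --n-healthy 48 --n-defective 48 --size 128x128 --seed 7 --out data/
appleseg split   --data data/ --fractions 0.5,0.17,0.33 --seed 7
appleseg train   --data data/ --epochs 30 --setup 5 --seed 7 --out run/
appleseg eval    --weights run/weights.npz --data data/ --report run/report/
appleseg ablate  --setups 1,5 --data data/ --out ablation.csv
appleseg flops   --shape 4x430x560
```

## Layout

| module | contents |
|---|---|
| `appleseg.core_data` | `Sample` / annotations / manifest, TIFF+PNG I/O, stratified splits |
| `appleseg.phantom` | synthetic apple generator with exact ground truth |
| `appleseg.synthesis` | ROI extraction, defect patches, rotate/warp, placement, classic augmentation |
| `appleseg.network` | network config/builder, padding, prediction, FLOPs estimator |
| `appleseg.nn` | numpy autodiff engine (conv, BN, ReLU6, bilinear upsampling, …) |
| `appleseg.metrics` | Focal Tversky Loss, confusion, CSRE, f-score, per-class reports |
| `appleseg.training` | Adam + LR schedule + early stopping, evaluation driver, ablation/α sweeps |
| `appleseg.cli` | `appleseg` command-line interface |

See `docs/methods.md` for the model, the conventions chosen where the
method leaves them open, and what phantom results do and do not show.
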