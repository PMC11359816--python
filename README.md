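# raftseg

Mapping offshore **floating raft aquaculture (FRA)** — seaweed and
shellfish grown on anchored raft-and-rope grids — from 10-band
Sentinel-2 surface-reflectance imagery. Rafts appear as regular dark
strip grids over brighter seawater; separating them from sediment
plumes, cloud and tidal flats needs both *spectral* context (the 10-band
signature) and *multiscale spatial* context (raft blocks span a few
pixels to whole bays). `raftseg` is a library plus CLI that implements:

- **MSSFNet**, an encoder–decoder segmentation network whose encoder
  replaces the residual blocks of a ResNet18-shaped backbone with
  **spatial–spectral feature extraction blocks (SSFEB)** and whose
  bottleneck applies a **multiscale spatial attention block (MSAB)**
  built on softmax-free ReLU linear attention,
- the dataset-construction pipeline (band resampling to 10 m, DN/10⁴
  normalization, 512-px sliding-window tiling with step 256, background
  filtering, mirror augmentation, 7:2:1 splitting),
- the training recipe (Adam, batch 8, equally weighted BCE + Dice,
  per-step cosine annealing) and confusion-matrix metric suite
  (precision, recall, F1, IoU, OA, expected agreement, Cohen's kappa),
- a seeded synthetic raft-scene generator so every stage is testable at
  desk scale without satellite downloads.

The network stack (reverse-mode autodiff, convolutions, batch
normalization, Adam) is implemented on numpy inside the package
(`raftseg.nn`) and is validated by finite-difference gradient checks and
independent scipy forward oracles.

## The model

Each SSFEB fuses three terms residually,

```
F_G(x) = K_spa(x) + K_spe(x) + x
```

where the spatial branch is a 1×1 / depthwise-3×3 / 1×1 bottleneck
(`K_spa(x) = Conv1x1(DW3x3(Conv1x1(x)))`) and the spectral branch
permutes the map so the width axis becomes the grouping axis, splits it
into three groups convolved depthwise with 3×3, 1×11 and 11×1 kernels
over the (height × channel) plane, then applies BatchNorm and a
two-layer 1×1 MLP before inverting the permutation. The MSAB projects
Q, K, V with a 1×1 convolution, aggregates them with depthwise
convolutions at scales {3, 5}, and computes per scale

```
A_i = q'_i (K'ᵀ V) / (q'_i (K'ᵀ 1) + ε),   q' = ReLU(q), k' = ReLU(k)
```

in the O(N·d²) association order, followed by a 1×1 output projection
with residual and a BatchNorm + GeLU MLP with a second residual.

Losses: `L = ½·BCE + ½·(1 − Dice)`. Metrics derive from pooled pixel
confusion counts; F1 and IoU obey `F1 = 2·IoU/(1+IoU)` exactly, and
`kappa = (OA − EA)/(1 − EA)`.

## Worked example

```python
import numpy as np
import raftseg as rs

tiles = rs.generate_training_tiles(64, size=64, seed=101)   # 10-band synthetic tiles
val   = rs.generate_training_tiles(16, size=64, seed=901)

model = rs.build_model(rs.NetworkConfig(tile_size=64, width_multiplier=0.125), seed=1)
cfg = rs.TrainConfig(lr=2e-2, epochs=20, batch_size=8, seed=1,
                     scale_range=(1.0, 1.0), shear_deg=0.0)
result = rs.train(model, tiles, None, cfg)
report = rs.evaluate(model, val)
print(f"loss {result['log'][-1]['train_loss']:.3f}  "
      f"IoU {report.metrics.iou:.3f}  F1 {report.metrics.f1:.3f}")
```

prints (one CPU, ~35 s)

```
loss 0.182  IoU 0.710  F1 0.831
```

i.e. after 20 epochs the tiny (132k-parameter) model recovers 71% of
the raft/background overlap on held-out synthetic scenes — far above
the ~7% a chance classifier at the raft pixel rate would reach. The same
pipeline is exposed on the shell:

```bash
raftseg synth scenes/ --n-scenes 12 --seed 3
raftseg split scenes/ --seed 1
raftseg train scenes/ ckpt/ --epochs 20 --seed 1
raftseg eval scenes/ ckpt/best.npz
raftseg predict scene.tif ckpt/best.npz prob.tif mask.png
```

Full-scale training (512-px tiles, widths 64–512, 50 epochs, lr 1e-4,
full augmentation — the configuration the defaults encode) requires the
real Sentinel-2 dataset and accelerator hardware; everything in this
repository runs the same code paths at desk scale.

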