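# Methods

## Problem and model

Floating raft aquaculture (FRA) shows up in 10 m multispectral imagery
as blocks of regularly spaced dark strips over brighter water: raft
reflectance is below that of the surrounding sea in every band, while
the main confusers (suspended sediment, cloud, tidal flats/land) are
*brighter* in some or all bands. `raftseg` frames extraction as binary
semantic segmentation of 10-band tiles (B2, B3, B4, B5, B6, B7, B8,
B8A, B11, B12, all at 10 m, reflectance in [0, 1]).

The network is a UNet-shaped encoder–decoder:

- **Stem** (ResNet18-style): 7×7 stride-2 convolution to the first
  stage width, BatchNorm, ReLU, 3×3 stride-2 max pool.
- **Encoder**: four stages of two SSFEBs each, joined by stride-2 1×1
  projection convolutions. SSFEBs preserve shape, so the explicit
  projections carry all downsampling and channel growth; this keeps
  every stage transition testable in isolation.
- **Bottleneck**: one MSAB on the 1/32-resolution map, where global
  attention over all tokens is cheapest.
- **Decoder**: four levels of (2× bilinear upsample → concatenate skip
  → two 3×3 conv + BatchNorm + ReLU). Skips come from stages 3, 2, 1
  and the stem convolution map, so the last learned level works at 1/2
  resolution; a parameter-free 2× bilinear upsample then a 1×1
  convolution and sigmoid produce the full-resolution raft-probability
  map. Bilinear upsampling was chosen over transposed convolution to
  avoid checkerboard artifacts.

### SSFEB

`F_G(x) = K_spa(x) + K_spe(x) + x`, all three terms with identical
extents. The spectral branch interprets the permutation H×W×C → H×C×W
as: the original **width** becomes the grouping axis and depthwise
kernels slide over the (height × original-channels) plane — the only
reading under which the 1×11 kernel actually spans 11 spectral
channels, matching its purpose of long-range spectral correlation. The
permuted map splits into three equal groups along the grouping axis
(zero-padded up to a multiple of three when needed; the pad is recorded
and cropped again before the inverse permutation, so padded columns
never reach the fusion sum). Group kernels are 3×3, 1×k and k×1 with
k = 11, in that order. BatchNorm and the two-layer 1×1 MLP (GeLU
between, expansion 4) act on the permuted layout, directly after the
concatenation they normalize. A consequence of the permutation
semantics is that the branch's depthwise filter count equals the map
width at that stage: the network is therefore built for one fixed tile
size and rejects other input extents with an explicit error.

The spatial branch is a 1×1 reduction to C/r channels (r = 4, a
conventional bottleneck ratio; configurable), a depthwise 3×3, and a
1×1 restoration. All convolutions in the block use stride 1, zero
same-padding and biases, which the element-wise residual sum requires.

### MSAB

1×1 projection to stacked Q/K/V (3C channels); per scale s ∈ {3, 5} a
depthwise s×s convolution of the stack; tokens flattened to (H·W, C)
per map; ReLU rectification of Q and K; linear attention computed as
`q'(K'ᵀV)` with row normalizer `q'(K'ᵀ1) + ε`, ε = 1e-6. The printed
form of the mechanism has no denominator, but the rectified-attention
family it belongs to is row-normalized and the bare product is
scale-divergent in training, so normalization is the default and
`unnormalized_attention=True` reproduces the literal product. One head
per scale branch; per-scale outputs are concatenated and a 1×1
convolution maps 2C → C before the residual with the input; BatchNorm +
GeLU MLP (expansion 4) adds the second residual. Attention runs in at
least 32-bit precision.

## Numerical substrate

All network computation runs on a small reverse-mode autodiff engine
(`raftseg.nn`) written on numpy: tape-based `Tensor`, im2col grouped
convolution, -inf-padded max pooling, half-pixel-centre bilinear
upsampling, BatchNorm composed from differentiable primitives, and an
Adam optimizer whose moments serialize into checkpoints. Every
primitive's gradient is checked against central finite differences, and
convolution forwards are cross-checked against `scipy.signal.correlate2d`.
Pure numpy makes runs bit-reproducible for a fixed seed. Probabilities
are clamped to [1e-7, 1 − 1e-7] inside the BCE; the Dice smooth term
defaults to 1.0 (a config field; hand-worked examples set it to 0).
Threshold ties (p = 0.5) classify as raft.

## Dataset pipeline

- 20 m bands are upsampled bilinearly with half-pixel-centre alignment
  (`scipy.ndimage.zoom`, `grid_mode=True`); nodata is NaN and
  propagates.
- Normalization is DN/10000 clipped to [0, 1], the standard L2A
  surface-reflectance scaling.
- Sliding windows: 512 px, step 256, offsets {0, step, 2·step, …} plus
  one edge-snapped window per axis when the last regular window falls
  short, so coverage is total (required for whole-raster inference).
  Coordinates are 0-based (row, col), windows half-open.
- Background filtering drops tiles with zero raft pixels unless they
  intersect a supplied keep-region raster (land/tidal flats) or survive
  one seeded Bernoulli draw (`keep_p`), drawn per candidate in tile
  order so decisions replay exactly from the seed.
- Mirror augmentation emits original + horizontal flip + vertical flip
  + transpose ("diagonal mirroring" read as the main-diagonal flip; an
  anti-diagonal variant sits behind a flag), a ×4 expansion applied
  before splitting — variants of one scene can therefore straddle
  splits, which is inherited from the published construction and
  documented rather than silently fixed.
- The 7:2:1 split floors the two smaller partitions and gives the
  remainder to training — the only rounding that yields 7051/2014/1007
  from 10 072 — with assignment by one seeded shuffle.
- Stitching averages overlapping tile probabilities per pixel and
  errors on any uncovered pixel.

Raster I/O writes multiband TIFFs with GeoTIFF georeferencing tags
(ModelPixelScale, ModelTiepoint, GDAL_NODATA) plus CRS and band order
in the image description; masks are PNGs. This keeps files standard
enough for GIS tools while depending only on `tifffile`/`imageio`.

## Synthetic scenes

The generator emulates the FRA phenomenology, not radiative transfer:

- Water baseline per band (winter coastal values, B2 0.060 → B12
  0.006) plus zero-mean Gaussian noise whose sd scales with the band
  baseline (0.5% of B2 by default) and whose variance is 80% shared
  across bands — reflectance between bands is strongly correlated in
  real water.
- Raft blocks: grids of parallel strips (width 1–4 px, spacing 2–6 px,
  common orientation per block), rendered by exact half-open
  point-in-rectangle rasterization with no anti-aliasing, so an
  axis-aligned L×W strip covers exactly L·W pixels and metric targets
  are crisp. Raft pixels multiply the water reflectance by a per-band
  contrast factor (default 0.5, necessarily < 1: rafts are darker than
  water in every band).
- Distractors, never labelled raft: sediment plumes (Gaussian bumps,
  visible-band weighted), cloud patches (alpha-blended toward 0.40 in
  all bands) and a land margin along one edge (bright in NIR/SWIR,
  overriding any strip that strayed into it).

What this does *not* emulate — wakes, sun glint, mixed pixels at strip
edges, tide-dependent contrast, real atmospheric residuals — bounds
what the desk-scale results show: passing tests demonstrate that the
architecture, losses, pipeline and training loop are correct and that
the model can learn the raft/water spectral-spatial contrast, not that
the published full-dataset accuracy transfers.

## Training

Defaults encode the full-scale recipe: Adam (β = 0.9/0.999, no weight
decay — only the optimizer name and initial rate are prescribed
upstream, so the conventional defaults apply), lr 1e-4, batch 8, 50
epochs, per-step cosine annealing to 0 without restarts, equally
weighted BCE + Dice, online augmentation (scaling 0.75–1.25, shear ≤
5°, flips p = 0.5, uniform contrast gain 0.8–1.2) on top of the offline
×4 mirror expansion. Checkpoints store parameters, BatchNorm running
statistics, Adam moments and counters; per-epoch seeding
(`default_rng([seed, epoch])`) makes an interrupted run resume into
bit-identical logs. The best checkpoint is selected by validation IoU.

**Desk-scale configuration** (used by the worked example, the overfit
probe and the end-to-end run): tile 64, width multiplier 0.125 (132k
parameters), 64 training / 16 validation / 16 test synthetic tiles, 20
epochs, lr 2e-2 selected by a pilot sweep over
{1e-3, 3e-3, 1e-2, 2e-2, 3e-2} on this setup, and online augmentation
restricted to its lossless members (flips, contrast): random scaling
and shear resample 1–4 px strip masks through nearest-neighbour
interpolation and corrupt a substantial fraction of thin-strip labels
at 64 px, which a 160-step schedule cannot absorb. Full-scale training
keeps the complete augmentation set. Under this configuration the
held-out IoU of the best-validation checkpoint reaches ≥ 0.70 for two
of three fixed seeds (≈ 0.79/0.80/0.67); the third seed converges more
slowly, and the 2-of-3 margin is the honest desk-scale outcome rather
than a guaranteed property of every seed.

## Degenerate inputs and conventions

- Metrics: a ratio with zero denominator is 0 and flagged
  (`*_undefined`); EA = 1 gives kappa = 0, flagged. Metrics pool
  confusion counts over the whole evaluation set (micro-averaging).
- `split_groups` without padding raises on non-divisible extents,
  naming the axis and extents.
- Nodata (NaN) raster pixels are zero-filled for the forward pass and
  forced to background in stitched outputs.
- Channel counts not divisible by the spatial-reduction ratio, even
  attention scales, non-divisible-by-32 tile sizes and collapsed scaled
  widths are all rejected at configuration time with the offending
  field named.

## Known limitations

- The spectral branch fixes the tile width at build time; a model must
  be rebuilt (not just re-run) for a different tile size.
- Only a CPU numpy backend exists; full-scale (512-px, 50-epoch)
  training is impractical here and the published-scale accuracy is
  deliberately out of desk scope.
- Single-channel sigmoid head: binary raft/background only.
- The synthetic generator's distractor spectra are stylized; models
  trained on it should not be applied to real imagery without
  retraining.
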