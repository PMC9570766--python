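# Methods

`pestseg` segments bark-beetle (BB) and aspen-leaf-miner (ALM) canopy
damage in multispectral satellite imagery of the Sentinel-2 kind.  This
note records the model, the numerical choices, and what the synthetic
benchmark does and does not demonstrate.

## Feature engineering

Input scenes carry the 11 surface-reflectance bands that survive
atmospheric correction (B2, B3, B4, B5, B6, B7, B8, B8A, B9, B11, B12) as
12-bit digital numbers on a common 10 m grid; 20 m and 60 m bands are
resampled by integer factors (nearest or bilinear).  From the raw bands the
package derives 21 registered vegetation indices — 13 broadly used ones
(NDWI, DWSI, NGRDI, RDI, GLI, NDRE2, PBI, NDVI, GNDVI, CIG, CVI, NDRE3,
DRS) plus 8 red-edge indices (ND790/670, NDVI690-710, NDRE, NDVI65,
GNDVIhyper, RENDVI1, RENDVI2, RI).  Index formulas are arithmetic
expressions over band names evaluated by a small AST interpreter; a
denominator magnitude below 1e-8 marks the pixel nodata rather than
emitting an infinity that would corrupt the percentile stretch.  DRS is the
Euclidean distance sqrt(B4^2 + B12^2).

Channels are stored 8-bit: raw bands are scaled directly from the 12-bit
range (v -> round(v/4095*255)); index bands are linearly stretched so their
2.5th percentile maps to 0 and their 97.5th to 255, computed per band per
scene over valid pixels only, with clipping outside.  Rounding (not
truncation) is used; the network consumes channels rescaled to [0, 1].
Six channel selections are predefined: RGB (3 = B4, B3, B2, conventional
true-colour order), the 11 bands, RGB + 13 indices (16), 11 bands + 13
indices (24, the default), a red-edge-free reduction (18 = the 11 bands
minus B5/B6/B7 plus the 13 indices minus NDRE2/NDRE3/CVI), and the full 11
bands + 21 indices (32).

## Dataset construction

Feature stacks and label rasters (0 background, 1 BB, 2 ALM) are cut on a
regular non-overlapping grid into tiles (default 256 x 256, desk-scale runs
use 64 x 64).  Edge remainders are zero-padded in the features and padded
with an ignore value (255) in the labels; ignore pixels enter neither the
loss nor any metric.  Tiles whose labels are entirely ignore are dropped.
The split is a seeded uniform shuffle into 64/16/20 percent
train/validation/test (val and test counts are round(f*n), remainder to
train); an optional contiguous "spatial" split is provided to limit
spatial-autocorrelation leakage between partitions.  Tiles persist in an
HDF5 store (uint8 cubes, labels, origins, channel names, seed).

## Architecture

The network is a UNet++-style nested encoder-decoder.  Encoder stages
X^{i,0} (i = 0..4) sit at strides 2..32.  Two encoder flavours exist:

* **slim-split-attn** (default): a 3x3 stride-2 stem followed by four
  split-attention residual blocks, emitting the decoder widths (default
  16, 32, 64, 128, 256) directly.  Default because it is trainable from
  scratch at desk scale and realises the stated stage widths literally.
* **resnest-projected**: a ResNeSt-style bottleneck trunk (deep stem,
  stage widths 256..2048, radix 2, configurable depths defaulting to the
  101-layer (3, 4, 23, 3)) with per-stage 1x1 lateral projections down to
  the decoder widths.  `adapt_pretrained_stem` converts published
  3-channel stem kernels to C input channels by tiling the RGB-mean kernel
  rescaled by 3/C, which preserves the pre-activation response to constant
  input exactly.

The split-attention block splits its grouped 3x3 transform into `radix`
branches (default 2), pools the branch sum globally, passes it through a
two-layer bottleneck gate, weights branches by an r-softmax over the radix
axis (plain sigmoid at radix 1), fuses, and adds a shortcut of the block
input before the final rectification.  Channels must divide by
radix x cardinality.

Decoder node X^{i,j} concatenates X^{i,0..j-1} with the bilinearly
2x-upsampled X^{i+1,j-1}, applies 3x3 conv + batch norm + ReLU to width_i,
then an scSE attention block: channel squeeze-excitation (global pool ->
bottleneck, reduction 2 -> sigmoid channel weights) and spatial
squeeze-excitation (1x1 -> sigmoid spatial map) combined by elementwise
maximum (addition available); `cse`, `sse` and `none` variants support
ablations, and a probe flag forces all gates to 1, under which every
variant reduces to the same plain UNet++ node — attention is purely
multiplicative.

Deep supervision: a 1x1 convolution to K = 3 classes at each X^{0,j}
(j = 1..4), bilinearly upsampled 2x to input resolution (the stem places
X^{0,0} at half resolution).  Head activation is sigmoid with per-pixel
renormalisation across the K channels so the maps are probabilities
(softmax available).  The final map is the unweighted mean of the four
heads (or the last head only); training averages the composite loss over
the heads.  The prediction is the per-pixel argmax, ties toward the lower
class index.  Batch normalisation uses momentum 0.1; weights use He
initialisation from a seeded generator, so model construction is
reproducible.

All tensor computation runs on a compact numpy autograd core
(`pestseg.nn`): conv2d (im2col with stride/padding/groups), batch norm,
bilinear/nearest upsampling, softmax, elementwise max, AdamW.  Every
primitive's gradient is verified against central finite differences in the
test suite.

## Objective

L = 0.5 L_dice + 0.5 L_sce (weights configurable).

* Dice: per class c, 1 - (2|X_c.Y_c| + eps)/(|X_c| + |Y_c| + eps) with
  X the one-hot target plane, Y the predicted probabilities, eps = 1e-7;
  macro-averaged over the 3 classes and accumulated over the whole batch,
  which stabilises gradients of the rare damage classes.  The eps in the
  numerator makes a class absent from both target and prediction score 0
  loss rather than a spurious 1.
* Label-smoothed cross-entropy: the target distribution puts
  (1 - alpha) + alpha/K on the true class and alpha/K elsewhere
  (alpha = 0.1, K = 3); the loss is the full per-class sum
  -(1/n) sum_pixels sum_c p_c log(q_c + eps).  By Gibbs' inequality this
  term is bounded below by the entropy of the smoothed target (~0.29 nats
  at alpha = 0.1), so the one-batch capacity check in the tests disables
  smoothing: with alpha = 0.1 a near-zero loss is unreachable by
  construction, not for lack of capacity.

## Optimisation

AdamW (betas 0.9/0.999, eps 1e-8, decoupled weight decay 1e-3), batch
size 6, 300 epochs at full scale.  The learning rate follows cosine
annealing with warm restarts in continuous epochs: within a cycle of
length T_i, lr = lr_min + (lr_init - lr_min)/2 (1 + cos(pi t/T_i)), with
lr_init = 1e-4, lr_min = 1e-5, first cycle T_0 = 2 epochs and each cycle
twice as long (restarts at cumulative epochs 2, 6, 14, 30, 62, 126, 254).
The schedule is stepped per batch at fractional epoch progress.  After
every epoch the validation mIoU is computed and the best checkpoint kept;
there is no early stopping.  Non-finite or exploding (> 1e4) loss aborts
with the last finite state.  Ablation grids (attention variant, decoder
widths, band selection) run one seeded train/test cycle per cell and
tabulate the reports, surviving individual cell failures.

## Evaluation

All metrics derive from a K x K confusion matrix aggregated over the whole
evaluation set (micro aggregation; per-tile averaging is not used).  Per
class, one-vs-rest: precision, recall, F1 (harmonic mean; identically
2 IoU/(1 + IoU)), IoU = TP/(TP + FN + FP).  Global: overall accuracy
(trace/total), mIoU (unweighted class mean), FWIoU (IoU weighted by each
class's ground-truth pixel frequency and summed; the weights sum to 1).
0/0 ratios are reported as 0 with an explicit undefined flag.

Full-scene inference tiles the scene on the training grid, predicts each
cube, and stitches patches back at their origins; padding is cropped, so
output dimensions always equal input dimensions and, for multiples of the
tile size, stitching is exact by construction.  Georeferencing metadata is
copied through.  No overlap blending is used by default.

## Synthetic benchmark

The generator emulates the spectral structure of the mapped damage: a
healthy-forest background and non-overlapping elliptical BB/ALM patches,
each class with an 11-band mean spectrum on the 12-bit DN scale.  Damage
shifts concentrate in red-edge/NIR (down) and SWIR (up); visible-band
shifts are small.  Pixel variation is a shared multiplicative brightness
field (sd 0.18) plus additive per-band noise (sd 35 DN), both spatially
smoothed (Gaussian, scale 4 px).  Because the brightness term cancels in
band ratios, raw-band class separation stays below one within-class
standard deviation (e.g. B4) while normalised-difference indices separate
damage from background by more than three — the qualitative pattern that
motivates feeding index channels to the network.  Default scenes are
256 x 256 with 10 BB patches (semi-axes 6-18 px) and 8 ALM patches
(5-14 px), roughly 7% and 3.5% of the scene, mirroring BB damage being the
more extensive class.  Generation is bit-reproducible from the seed.

What the benchmark does not emulate: real canopy texture, mixed or
boundary pixels, cloud/shadow, topographic illumination, seasonal change,
and label noise from aerial sketch mapping.  Passing the synthetic
end-to-end checks therefore demonstrates that the pipeline is wired
correctly and can learn spectrally separable classes — not that the
full-scale accuracies reported for real surveys transfer to real
Sentinel-2 scenes, which
would require the original labelled imagery and GPU-scale training.

## Desk-scale problem sizes

The test suite and the acceptance script run the method end to end at
reduced size, chosen as the package's standard desk-scale configuration:
six 256 x 256 scenes, 64 x 64 tiles (~96 tiles), the slim encoder at
widths 8-128, ~300 optimiser steps for the main run and 150 for the
RGB-vs-full contrast, seeds fixed by the caller.  The one-batch capacity
check uses 10 tiles, >= 200 steps, smoothing off and a capacity-check
learning rate of 5e-3 with monotone cosine decay: the production rate of
1e-4 with warm restarts is tuned for stable generalisation, and restarts —
which deliberately kick the optimiser out of minima — are counterproductive
for pure interpolation.

## Known limitations

* CPU-only numpy execution: full-scale (4984 tiles, 300 epochs, widths
  16-256) training is out of reach; the recipe is validated at desk scale.
* The resnest-projected encoder is structurally complete but ships without
  published ImageNet weights; `adapt_pretrained_stem` accepts user-supplied
  kernels.
* Scenes are assumed atmospherically corrected and co-registered; no CRS
  reprojection or cloud masking.
* Mixed-damage pixels are out of scope; patches are single-class.
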