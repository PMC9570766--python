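# pestseg

Semantic segmentation of forest-pest damage — bark beetle (BB) and aspen
leaf miner (ALM) — in multispectral satellite imagery of the Sentinel-2
kind.  Insect damage alters leaf chemistry and water content long before it
is obvious in true colour, so the red-edge, NIR and SWIR bands and
vegetation indices derived from them carry most of the usable signal.
`pestseg` turns multi-band reflectance rasters into 8-bit feature stacks
(11 bands + up to 21 vegetation indices), trains an attention-augmented
nested encoder–decoder to label every pixel {background, BB, ALM}, and
stitches tile predictions back into full-scene damage maps.

The core pieces:

* **Feature stacks** — vegetation indices (NDVI = (B8A−B4)/(B8A+B4), NDWI,
  NDRE2, DWSI, DRS = √(B4²+B12²), …, 21 registered formulas) computed from
  raw digital numbers, percentile-stretched to 8 bit (2.5th→0,
  97.5th→255); raw 12-bit bands scaled directly.  Six standard channel
  selections from RGB (3) up to all bands + indices (32).
* **Model** — a UNet++-style nested decoder over a split-attention
  (ResNeSt-flavoured) encoder; scSE attention (channel + spatial
  squeeze-excitation, fused by elementwise max) at every decoder node;
  deep supervision through four 1×1-conv sigmoid heads whose mean is the
  output probability map.  Decoder widths default to 16/32/64/128/256.
* **Objective** — L = 0.5·L_dice + 0.5·L_sce: macro-averaged soft Dice
  plus cross-entropy against label-smoothed targets
  (p = (1−α)·one-hot + α/K, α = 0.1, K = 3).
* **Training** — AdamW (weight decay 1e-3, batch 6), cosine-annealed
  learning rate 1e-4→1e-5 with warm restarts (cycles 2, 4, 8, … epochs),
  best-validation-mIoU checkpoint selection.
* **Evaluation** — per-class precision/recall/F1/IoU and global accuracy,
  mIoU, FWIoU from a micro-aggregated confusion matrix.
* **Synthetic scenes** — a seeded generator producing labelled 11-band
  scenes whose damage classes separate weakly in raw bands but strongly in
  index channels, so the whole pipeline is testable without satellite data.

Everything runs on a self-contained numpy autograd/NN core (`pestseg.nn`)
— no deep-learning framework required.

## Worked example

```python
import numpy as np
from pestseg import (ModelConfig, TrainConfig, build_feature_stack,
                     drop_empty_tiles, evaluate_model, generate_scenes,
                     grid_crop, split_dataset, train)

tiles = []
for i, (scene, labels) in enumerate(generate_scenes(6, seed=11)):
    stack = build_feature_stack(scene, "bands11+indices13")   # 24 channels
    tiles += grid_crop(stack, labels, 64, scene_id=f"s{i}")
tiles = drop_empty_tiles(tiles)
split = split_dataset(tiles, seed=1)                          # 64/16/20

cfg = TrainConfig(model=ModelConfig(in_channels=24,
                                    decoder_widths=(8, 16, 32, 64, 128)),
                  epochs=30, seed=0)
model, log = train(cfg, tiles, split, max_steps=300)
report = evaluate_model(model, tiles, split.test_ids)
print(round(report.miou, 3), round(report.accuracy, 3))
```

prints (a few minutes on one CPU core):

```
0.662 0.94
```

meaning: after ~300 optimiser steps the slim model reaches held-out mean
IoU 0.662 over the three classes at 94% pixel accuracy — versus ~0.29 mIoU
for always predicting background.  The same scenes with RGB-only stacks
train to distinctly lower mIoU, the motivation for the index channels.
`examples/` holds narrative scripts for spectral profiling, training, and
full-scene prediction, and the `pestseg` CLI chains the pipeline
(`synth → prepare → tile → split → train → evaluate → predict → profile`).

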