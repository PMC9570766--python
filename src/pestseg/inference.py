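"""Full-scene prediction: tile, predict per cube, stitch back (pad-then-crop).

Scenes are cut on the same non-overlapping grid used for training; each
cube is predicted independently and the per-tile label patches are placed
back at their origins, so for scene dimensions that are multiples of the
tile size stitching is exact by construction.  Edge tiles are zero-padded
for the forward pass and the padding is cropped away afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import LabelRaster, grid_crop
from .metrics import MetricsReport, evaluate_labels
from .model import RsprUnetPP, load_checkpoint
from .nn import no_grad
from .spectral import SceneStack


@dataclass
class PredictionRaster:
    labels: np.ndarray                  # (H, W) uint8 class ids
    probabilities: np.ndarray | None    # (K, H, W) float32, optional
    geo_meta: dict | None = None

    @property
    def shape(self):
        return self.labels.shape


def _as_model(model_or_checkpoint):
    if isinstance(model_or_checkpoint, RsprUnetPP):
        return model_or_checkpoint
    model, _ = load_checkpoint(model_or_checkpoint)
    return model


def predict_scene(stack: SceneStack, model, tile_size: int = 256,
                  batch_size: int = 6, return_probs: bool = False
                  ) -> PredictionRaster:
    """Predict class labels for a whole feature stack.

    The stack must already be the 8-bit feature stack the checkpoint was
    trained on (same channels, same order).
    """
    model = _as_model(model)
    c = len(stack.bands)
    if c != model.cfg.in_channels:
        raise ValueError(
            f"scene has {c} channels but checkpoint expects "
            f"{model.cfg.in_channels} (config: {model.cfg})"
        )
    h, w = stack.height, stack.width
    dummy = LabelRaster(np.zeros((h, w), dtype=np.uint8))
    tiles = grid_crop(stack, dummy, tile_size=tile_size)
    ts = tile_size
    nh = -(-h // ts)
    nw = -(-w // ts)
    out_labels = np.zeros((nh * ts, nw * ts), dtype=np.uint8)
    out_probs = (np.zeros((model.cfg.n_classes, nh * ts, nw * ts),
                          dtype=np.float32) if return_probs else None)
    model.eval()
    for s in range(0, len(tiles), batch_size):
        chunk = tiles[s: s + batch_size]
        x = np.stack([t.cube for t in chunk]).astype(np.float32) / 255.0
        x = x.transpose(0, 3, 1, 2)
        with no_grad():
            out = model(x)
        pred = np.argmax(out["probs"].data, axis=1).astype(np.uint8)
        for t, p, k in zip(chunk, pred, range(len(chunk))):
            r0, c0 = t.origin
            out_labels[r0: r0 + ts, c0: c0 + ts] = p
            if return_probs:
                out_probs[:, r0: r0 + ts, c0: c0 + ts] = \
                    out["probs"].data[k].astype(np.float32)
    labels = out_labels[:h, :w]
    probs = out_probs[:, :h, :w] if return_probs else None
    return PredictionRaster(labels, probs, geo_meta=stack.geo_meta)


def evaluate_scene(pred: PredictionRaster, truth: LabelRaster) -> MetricsReport:
    """Whole-scene metrics of a prediction against a truth label raster."""
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth shapes differ")
    return evaluate_labels(pred.labels, truth.values, ignore=truth.nodata)
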