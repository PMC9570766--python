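"""Composite segmentation objective: soft Dice + label-smoothed cross-entropy.

Both terms operate on K-channel per-pixel probability maps against integer
label rasters.  Dice is computed per class over the whole batch and
macro-averaged, which stabilises gradients for the rare damage classes; the
cross-entropy term smooths the one-hot target to (1 - alpha) + alpha/K on
the true class and alpha/K elsewhere (alpha = 0.1, K = 3 by default).  The
training loss is the equal-weight mix L = 0.5 * L_dice + 0.5 * L_sce.
Pixels carrying the ignore label contribute to neither term.
"""

from __future__ import annotations

import numpy as np

from .dataset import IGNORE_LABEL
from .nn import Tensor, as_tensor

EPS = 1e-7


def _prep(pred, target, ignore):
    pred = as_tensor(pred)
    target = np.asarray(target)
    if pred.ndim != 4:
        raise ValueError("pred must be (N, K, H, W)")
    if target.shape != (pred.shape[0],) + pred.shape[2:]:
        raise ValueError(
            f"target shape {target.shape} does not match pred {pred.shape}"
        )
    k = pred.shape[1]
    valid = target != ignore
    if not valid.any():
        raise ValueError("all pixels are ignored; loss undefined")
    if target[valid].min() < 0 or target[valid].max() >= k:
        raise ValueError(f"target labels outside 0..{k - 1}")
    return pred, target, valid, k


def _one_hot(target, k, valid):
    """(N, K, H, W) float one-hot, zero on ignored pixels."""
    oh = np.zeros((target.shape[0], k) + target.shape[1:], dtype=np.float32)
    for c in range(k):
        oh[:, c] = (target == c) & valid
    return oh


def dice_loss(pred, target, ignore: int = IGNORE_LABEL, eps: float = EPS):
    """Mean over classes of 1 - 2|X.Y| / (|X| + |Y| + eps).

    X is the one-hot target plane, Y the predicted probability plane;
    |X.Y| sums the elementwise products, |X| and |Y| sum the planes.
    """
    pred, target, valid, k = _prep(pred, target, ignore)
    oh = _one_hot(target, k, valid)
    mask = valid[:, None].astype(np.float32)
    y = pred * mask
    total = None
    for c in range(k):
        xc = Tensor(oh[:, c: c + 1])
        # select the class plane via a one-channel selector product
        sel = np.zeros((1, k, 1, 1), dtype=np.float32)
        sel[0, c, 0, 0] = 1.0
        yc = (y * sel).sum(axis=1, keepdims=True)
        inter = (xc * yc).sum()
        card = xc.sum() + yc.sum()
        # eps in the numerator too: a class absent from both target and
        # prediction scores a perfect overlap instead of a spurious 1
        lc = 1.0 - (inter * 2.0 + eps) / (card + eps)
        total = lc if total is None else total + lc
    return total * (1.0 / k)


def soft_cross_entropy(pred, target, alpha: float = 0.1,
                       ignore: int = IGNORE_LABEL, eps: float = EPS):
    """Cross-entropy against label-smoothed targets.

    The smoothed target distribution puts (1 - alpha) + alpha/K mass on the
    true class and alpha/K on each other class; the loss averages
    -sum_c p_c log(q_c + eps) over non-ignored pixels.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    pred, target, valid, k = _prep(pred, target, ignore)
    oh = _one_hot(target, k, valid)
    p = oh * (1.0 - alpha) + (alpha / k) * valid[:, None]
    n = float(valid.sum())
    logq = (pred + eps).log()
    return -(Tensor(p.astype(np.float32)) * logq).sum() * (1.0 / n)


def smoothed_target(cls: int, alpha: float = 0.1, k: int = 3) -> np.ndarray:
    """The smoothed target vector for a true class (closed form)."""
    p = np.full(k, alpha / k)
    p[cls] += 1.0 - alpha
    return p


def combined_loss(pred, target, w_dice: float = 0.5, w_sce: float = 0.5,
                  alpha: float = 0.1, ignore: int = IGNORE_LABEL):
    """L = w_dice * L_dice + w_sce * L_sce (default equal weights)."""
    return (dice_loss(pred, target, ignore) * w_dice
            + soft_cross_entropy(pred, target, alpha, ignore) * w_sce)


def deep_supervision_loss(head_preds, target, **kwargs):
    """Unweighted mean of the combined loss over the supervision heads."""
    total = None
    for p in head_preds:
        l = combined_loss(p, target, **kwargs)
        total = l if total is None else total + l
    return total * (1.0 / len(head_preds))
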