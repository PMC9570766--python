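"""Optimisation loop: AdamW + cosine warm restarts + best-val-mIoU selection.

The recipe: AdamW (weight decay 1e-3), batch size 6, 300 epochs,
cosine-annealed learning rate from 1e-4 down to 1e-5 with warm restarts
(first cycle 2 epochs, each subsequent cycle twice as long, so restarts at
cumulative epochs 2, 6, 14, 30, 62, 126, 254), deep-supervised composite
loss, and the checkpoint with the best validation mIoU kept as the final
model.  Desk-scale experiments shrink tiles/epochs but keep the recipe.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .dataset import DatasetSplit
from .losses import deep_supervision_loss
from .metrics import ConfusionMatrix, compute_report
from .model import ModelConfig, RsprUnetPP
from .nn import AdamW


@dataclass
class TrainConfig:
    model: ModelConfig = field(default_factory=ModelConfig)
    batch_size: int = 6
    epochs: int = 300
    weight_decay: float = 1e-3
    lr_init: float = 1e-4
    lr_min: float = 1e-5
    t0: float = 2.0
    t_mult: float = 2.0
    alpha: float = 0.1
    loss_weights: tuple = (0.5, 0.5)
    seed: int = 0
    band_selection: str = "bands11+indices13"
    selection_metric: str = "val_miou"
    max_loss: float = 1e4  # divergence guard

    def __post_init__(self):
        if self.lr_min > self.lr_init:
            raise ValueError("lr_min must not exceed lr_init")
        if self.t0 < 1 or self.t_mult < 1:
            raise ValueError("t0 and t_mult must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["model"] = asdict(self.model)
        return d

    @classmethod
    def from_dict(cls, d) -> "TrainConfig":
        d = dict(d)
        m = d.get("model", {})
        if isinstance(m, dict):
            for k in ("decoder_widths", "trunk_depths"):
                if k in m:
                    m[k] = tuple(m[k])
            d["model"] = ModelConfig(**m)
        if "loss_weights" in d:
            d["loss_weights"] = tuple(d["loss_weights"])
        return cls(**d)


@dataclass
class TrainLog:
    iter_loss: list = field(default_factory=list)
    epoch: list = field(default_factory=list)
    lr: list = field(default_factory=list)
    train_loss: list = field(default_factory=list)
    val_miou: list = field(default_factory=list)

    @property
    def best_epoch(self) -> int:
        return int(np.argmax(self.val_miou))

    @property
    def best_val_miou(self) -> float:
        return float(max(self.val_miou))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"epoch": self.epoch, "lr": self.lr,
                             "train_loss": self.train_loss,
                             "val_miou": self.val_miou})


def lr_schedule(epoch_progress: float, lr_init: float = 1e-4,
                lr_min: float = 1e-5, t0: float = 2.0,
                t_mult: float = 2.0) -> float:
    """Cosine annealing with warm restarts, in continuous epochs.

    Within a cycle of length T_i the rate follows
    lr_min + (lr_init - lr_min)/2 * (1 + cos(pi * t / T_i)); cycle lengths
    grow geometrically (T_0, T_0*T_mult, ...), and the rate snaps back to
    lr_init at every restart.
    """
    if epoch_progress < 0:
        raise ValueError("epoch progress must be >= 0")
    start, length = 0.0, float(t0)
    while epoch_progress >= start + length:
        start += length
        length *= t_mult
    frac = (epoch_progress - start) / length
    return lr_min + 0.5 * (lr_init - lr_min) * (1.0 + math.cos(math.pi * frac))


def restart_epochs(t0: float = 2.0, t_mult: float = 2.0, horizon: float = 300):
    """Cumulative epochs at which warm restarts occur, up to `horizon`."""
    out, start, length = [], 0.0, float(t0)
    while start + length <= horizon:
        start += length
        out.append(start)
        length *= t_mult
        if t_mult == 1.0 and length == 0:
            break
    return out


def _batch_arrays(tiles, ids):
    x = np.stack([tiles[i].cube for i in ids]).astype(np.float32) / 255.0
    x = x.transpose(0, 3, 1, 2)
    y = np.stack([tiles[i].label for i in ids])
    return x, y


def evaluate_model(model: RsprUnetPP, tiles, ids, batch_size: int = 6):
    """Confusion-matrix metrics of a model over the given tile ids."""
    model.eval()
    cm = ConfusionMatrix(model.cfg.n_classes)
    for s in range(0, len(ids), batch_size):
        x, y = _batch_arrays(tiles, ids[s: s + batch_size])
        pred = model.predict(x)
        cm.accumulate(pred, y)
    return compute_report(cm)


class DivergenceError(RuntimeError):
    pass


def train(cfg: TrainConfig, tiles, split: DatasetSplit,
          checkpoint_path=None, max_steps: int | None = None,
          verbose: bool = False):
    """Run the optimisation loop; returns (model-at-best-val-mIoU, TrainLog).

    The model is re-seeded from cfg.seed, batches are drawn in a seeded
    shuffled order, the learning rate follows the warm-restart schedule in
    fractional epochs, and after each epoch the validation mIoU decides
    whether the in-memory best checkpoint (and optional on-disk copy) is
    overwritten.  `max_steps` truncates training for desk-scale runs.
    """
    c0 = tiles[0].cube.shape[2]
    if c0 != cfg.model.in_channels:
        raise ValueError(
            f"tiles have {c0} channels but model expects {cfg.model.in_channels}"
        )
    model = RsprUnetPP(cfg.model, seed=cfg.seed)
    opt = AdamW(model.parameters(), lr=cfg.lr_init,
                weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    log = TrainLog()
    best_state, best_miou = None, -1.0
    w_dice, w_sce = cfg.loss_weights
    steps_done = 0
    n_batches = max(len(split.train_ids) // cfg.batch_size, 1)
    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(split.train_ids)
        losses = []
        for b in range(n_batches):
            ids = order[b * cfg.batch_size: (b + 1) * cfg.batch_size]
            if len(ids) == 0:
                break
            lr = lr_schedule(epoch + b / n_batches, cfg.lr_init, cfg.lr_min,
                             cfg.t0, cfg.t_mult)
            opt.lr = lr
            x, y = _batch_arrays(tiles, ids)
            out = model(x)
            loss = deep_supervision_loss(out["heads"], y, w_dice=w_dice,
                                         w_sce=w_sce, alpha=cfg.alpha)
            lv = loss.item()
            if not np.isfinite(lv) or lv > cfg.max_loss:
                raise DivergenceError(
                    f"loss diverged ({lv}) at epoch {epoch}, batch {b}"
                )
            model.zero_grad()
            loss.backward()
            opt.step()
            losses.append(lv)
            log.iter_loss.append(lv)
            steps_done += 1
            if max_steps is not None and steps_done >= max_steps:
                break
        report = evaluate_model(model, tiles, split.val_ids, cfg.batch_size)
        log.epoch.append(epoch)
        log.lr.append(lr_schedule(epoch, cfg.lr_init, cfg.lr_min, cfg.t0,
                                  cfg.t_mult))
        log.train_loss.append(float(np.mean(losses)) if losses else float("nan"))
        log.val_miou.append(report.miou)
        if report.miou > best_miou:
            best_miou = report.miou
            best_state = copy.deepcopy(model.state_dict())
        if verbose:
            print(f"epoch {epoch}: loss={log.train_loss[-1]:.4f} "
                  f"val_mIoU={report.miou:.4f}")
        if max_steps is not None and steps_done >= max_steps:
            break
    model.load_state_dict(best_state)
    model.eval()
    if checkpoint_path is not None:
        from .model import save_checkpoint

        save_checkpoint(checkpoint_path, model,
                        extra={"best_val_miou": best_miou,
                               "best_epoch": log.best_epoch,
                               "train_config": cfg.to_dict()})
    return model, log


def run_ablation(grid, tiles_by_selection, split, base_cfg: TrainConfig,
                 max_steps: int | None = None) -> pd.DataFrame:
    """Train/test one model per grid cell under a shared seed.

    `grid` is a list of override dicts (keys: attention, decoder_widths,
    band_selection); `tiles_by_selection` maps band-selection name to its
    tile list.  Failures are recorded per cell without aborting the grid.
    """
    rows = []
    for cell in grid:
        cfg = TrainConfig.from_dict(base_cfg.to_dict())
        sel = cell.get("band_selection", cfg.band_selection)
        tiles = tiles_by_selection[sel]
        cfg.band_selection = sel
        cfg.model.in_channels = tiles[0].cube.shape[2]
        if "attention" in cell:
            cfg.model.attention = cell["attention"]
        if "decoder_widths" in cell:
            cfg.model.decoder_widths = tuple(cell["decoder_widths"])
        fingerprint = (f"att={cfg.model.attention},"
                       f"w={cfg.model.decoder_widths[0]}..{cfg.model.decoder_widths[-1]},"
                       f"sel={sel}")
        row = {"fingerprint": fingerprint, "attention": cfg.model.attention,
               "widths": str(cfg.model.decoder_widths),
               "band_selection": sel}
        try:
            model, log = train(cfg, tiles, split, max_steps=max_steps)
            row["n_params"] = model.num_parameters()
            report = evaluate_model(model, tiles, split.test_ids,
                                    cfg.batch_size)
            row.update({"test_miou": report.miou, "test_fwiou": report.fwiou,
                        "test_accuracy": report.accuracy,
                        "best_val_miou": log.best_val_miou})
        except Exception as exc:  # noqa: BLE001 - grid must survive one bad cell
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)
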