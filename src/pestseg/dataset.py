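"""Tiling, train/val/test splitting and HDF5 persistence of training cubes.

Feature stacks and label rasters are cut on a regular, non-overlapping grid
into fixed-size cubes (default 256 x 256 x C).  Edge remainders are
zero-padded; padded label pixels get an *ignore* value that is excluded from
losses and metrics downstream.  The split is a seeded uniform shuffle into
64 / 16 / 20 percent train / validation / test by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

from .spectral import SceneStack

#: label value for padded / unlabelled pixels, excluded from loss and metrics
IGNORE_LABEL = 255

#: class ids: background, bark beetle, aspen leaf miner
CLASS_NAMES = {0: "BG", 1: "BB", 2: "ALM"}
N_CLASSES = 3


@dataclass
class LabelRaster:
    """Integer class raster {0: background, 1: bark beetle, 2: aspen leaf miner}."""

    values: np.ndarray
    nodata: int = IGNORE_LABEL

    def __post_init__(self):
        self.values = np.asarray(self.values)
        bad = ~(np.isin(self.values, list(CLASS_NAMES)) | (self.values == self.nodata))
        if bad.any():
            raise ValueError(
                f"labels contain values outside {sorted(CLASS_NAMES)} "
                f"and nodata={self.nodata}"
            )

    @property
    def shape(self):
        return self.values.shape


@dataclass
class Tile:
    """One training unit: a feature cube and its aligned label patch."""

    cube: np.ndarray        # (ts, ts, C) uint8
    label: np.ndarray       # (ts, ts) uint8
    origin: tuple           # (row, col) offset in the parent scene
    scene_id: str = "scene"

    def __post_init__(self):
        if self.cube.shape[:2] != self.label.shape:
            raise ValueError("cube and label are not spatially aligned")


@dataclass
class DatasetSplit:
    train_ids: list
    val_ids: list
    test_ids: list
    seed: int
    fractions: tuple = (0.64, 0.16, 0.20)

    def __post_init__(self):
        ids = self.train_ids + self.val_ids + self.test_ids
        if len(set(ids)) != len(ids):
            raise ValueError("split lists are not disjoint")

    def to_dict(self):
        return {
            "train_ids": list(map(int, self.train_ids)),
            "val_ids": list(map(int, self.val_ids)),
            "test_ids": list(map(int, self.test_ids)),
            "seed": int(self.seed),
            "fractions": list(self.fractions),
        }

    @classmethod
    def from_dict(cls, d):
        return cls(d["train_ids"], d["val_ids"], d["test_ids"], d["seed"],
                   tuple(d["fractions"]))


def grid_crop(stack: SceneStack, labels: LabelRaster,
              tile_size: int = 256, scene_id: str = "scene") -> list:
    """Cut stack + labels into non-overlapping tiles from the top-left corner.

    Produces ceil(H/ts) * ceil(W/ts) tiles; edge tiles are zero-padded in the
    cube and padded with the ignore value in the label.
    """
    if (stack.height, stack.width) != labels.shape:
        raise ValueError("stack and labels shapes differ")
    ts = int(tile_size)
    h, w = stack.height, stack.width
    arr = stack.array()
    lab = labels.values
    nh = -(-h // ts)
    nw = -(-w // ts)
    tiles = []
    for i in range(nh):
        for j in range(nw):
            r0, c0 = i * ts, j * ts
            cube = arr[r0: r0 + ts, c0: c0 + ts]
            patch = lab[r0: r0 + ts, c0: c0 + ts]
            if cube.shape[:2] != (ts, ts):
                ph, pw = ts - cube.shape[0], ts - cube.shape[1]
                cube = np.pad(cube, ((0, ph), (0, pw), (0, 0)))
                patch = np.pad(patch, ((0, ph), (0, pw)),
                               constant_values=labels.nodata)
            tiles.append(Tile(cube, patch, (r0, c0), scene_id))
    return tiles


def drop_empty_tiles(tiles, ignore: int = IGNORE_LABEL) -> list:
    """Remove tiles whose label patch is entirely ignore/nodata."""
    return [t for t in tiles if not np.all(t.label == ignore)]


def split_dataset(tiles, fractions=(0.64, 0.16, 0.20), seed: int = 0,
                  spatial: bool = False) -> DatasetSplit:
    """Partition tile indices into train/val/test.

    Default is a uniform random shuffle under `seed`; val and test counts are
    round(fraction * n), the remainder goes to train.  ``spatial=True`` keeps
    tiles in scene order and cuts contiguous blocks instead, which limits
    spatial-autocorrelation leakage between partitions.
    """
    fractions = tuple(float(f) for f in fractions)
    if any(f <= 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be positive and sum to 1")
    n = len(tiles)
    if n < 3:
        raise ValueError(f"need at least 3 tiles to split, got {n}")
    n_val = round(fractions[1] * n)
    n_test = round(fractions[2] * n)
    n_train = n - n_val - n_test
    if spatial:
        order = np.arange(n)
    else:
        order = np.random.default_rng(seed).permutation(n)
    return DatasetSplit(
        train_ids=order[:n_train].tolist(),
        val_ids=order[n_train: n_train + n_val].tolist(),
        test_ids=order[n_train + n_val:].tolist(),
        seed=seed,
        fractions=fractions,
    )


# ------------------------------------------------------------------ storage

def write_tiles(path, tiles, channel_names=None, seed=None):
    """Persist tiles to an HDF5 store (cubes, labels, origins + attributes)."""
    tiles = list(tiles)
    if not tiles:
        raise ValueError("no tiles to write")
    c = tiles[0].cube.shape[2]
    for t in tiles:
        if t.cube.shape[2] != c:
            raise ValueError(
                f"channel-count mismatch: expected {c}, got {t.cube.shape[2]}"
            )
    with h5py.File(path, "w") as f:
        f.create_dataset("cubes", data=np.stack([t.cube for t in tiles]),
                         dtype="uint8", compression="gzip", compression_opts=1)
        f.create_dataset("labels", data=np.stack([t.label for t in tiles]),
                         dtype="uint8", compression="gzip", compression_opts=1)
        f.create_dataset("origins",
                         data=np.array([t.origin for t in tiles], dtype=np.int32))
        f.attrs["scene_ids"] = [t.scene_id for t in tiles]
        f.attrs["n_channels"] = c
        if channel_names is not None:
            f.attrs["channel_names"] = list(channel_names)
        if seed is not None:
            f.attrs["seed"] = int(seed)


def read_tiles(path, ids=None):
    """Load tiles back from an HDF5 store; round-trips bit-for-bit."""
    with h5py.File(path, "r") as f:
        n = f["cubes"].shape[0]
        if ids is None:
            ids = range(n)
        scene_ids = list(f.attrs["scene_ids"])
        tiles = []
        for i in ids:
            i = int(i)
            if not 0 <= i < n:
                raise KeyError(f"tile id {i} not in store of size {n}")
            tiles.append(Tile(f["cubes"][i], f["labels"][i],
                              tuple(f["origins"][i]), scene_ids[i]))
    return tiles


def read_store_meta(path) -> dict:
    with h5py.File(path, "r") as f:
        meta = {"n_tiles": f["cubes"].shape[0],
                "n_channels": int(f.attrs["n_channels"]),
                "tile_size": f["cubes"].shape[1]}
        if "channel_names" in f.attrs:
            meta["channel_names"] = list(f.attrs["channel_names"])
        if "seed" in f.attrs:
            meta["seed"] = int(f.attrs["seed"])
    return meta
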