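"""Raster, profile and configuration file IO.

Multi-band stacks travel as TIFF with a JSON image description carrying the
channel names and optional geo metadata (geotransform + CRS string), so a
stack round-trips with its channel order intact.  Label and prediction
rasters are single-band uint8 TIFFs.  Experiment configuration is YAML.
"""

from __future__ import annotations

import json

import numpy as np
import tifffile
import yaml

from .dataset import LabelRaster
from .spectral import BandImage, SceneStack


def write_stack(path, stack: SceneStack):
    """Write a SceneStack as a (C, H, W) TIFF with named channels."""
    data = np.stack([b.values for b in stack.bands])
    meta = {
        "band_names": stack.band_names,
        "resolutions_m": [b.resolution_m for b in stack.bands],
        "geo_meta": stack.geo_meta,
    }
    nodata = stack.nodata()
    if nodata.any():
        meta["has_nodata_plane"] = True
        data = np.concatenate([data, nodata[None].astype(data.dtype)])
    tifffile.imwrite(path, data, photometric="minisblack",
                     description=json.dumps(meta))


def read_stack(path) -> SceneStack:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description
    meta = json.loads(desc)
    names = meta["band_names"]
    res = meta.get("resolutions_m", [10.0] * len(names))
    nodata = None
    if meta.get("has_nodata_plane"):
        nodata = data[-1].astype(bool)
        data = data[:-1]
    bands = [
        BandImage(n, data[i], res[i],
                  nodata if nodata is not None else None)
        for i, n in enumerate(names)
    ]
    return SceneStack(bands, geo_meta=meta.get("geo_meta"))


def write_labels(path, labels: LabelRaster):
    tifffile.imwrite(path, labels.values.astype(np.uint8),
                     description=json.dumps({"nodata": int(labels.nodata)}))


def read_labels(path) -> LabelRaster:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description
    nodata = 255
    if desc:
        try:
            nodata = int(json.loads(desc).get("nodata", 255))
        except (ValueError, json.JSONDecodeError):
            pass
    return LabelRaster(data.astype(np.uint8), nodata=nodata)


def write_prediction(path, pred, prob_path=None):
    tifffile.imwrite(path, pred.labels.astype(np.uint8),
                     description=json.dumps({"geo_meta": pred.geo_meta}))
    if prob_path is not None and pred.probabilities is not None:
        tifffile.imwrite(prob_path, pred.probabilities.astype(np.float32),
                         photometric="minisblack")


def write_yaml(path, obj: dict):
    with open(path, "w") as f:
        yaml.safe_dump(obj, f, sort_keys=False)


def read_yaml(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)
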