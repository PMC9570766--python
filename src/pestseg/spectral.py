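"""Spectral feature engineering for Sentinel-2-like multiband imagery.

A scene is an ordered stack of named bands (B2...B12).  From the raw
digital-number bands this module derives vegetation indices (NDVI, NDWI,
NDRE and friends — 13 broadly used indices plus 8 red-edge indices),
linearly stretches them to 8 bit between the 2.5th and 97.5th percentiles,
scales the raw 12-bit bands to 8 bit, and assembles the channel stacks the
segmentation model consumes.  Class-wise mean spectra can be profiled from
a labelled scene to inspect how damage classes separate per channel.
"""

from __future__ import annotations

import ast
import logging
import operator
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: guard below which a denominator is treated as zero and the pixel as nodata
DENOM_EPS = 1e-8

#: the 11 bands usable after atmospheric correction (B1/B10 are dropped by it)
BANDS_11 = ("B2", "B3", "B4", "B5", "B6", "B7", "B8", "B8A", "B9", "B11", "B12")

#: native ground-sample distance (m) per band
BAND_RESOLUTION_M = {
    "B1": 60, "B2": 10, "B3": 10, "B4": 10, "B5": 20, "B6": 20, "B7": 20,
    "B8": 10, "B8A": 20, "B9": 60, "B10": 60, "B11": 20, "B12": 20,
}


class MissingBandError(KeyError):
    """A required band is absent from the scene."""


class UnknownIndexError(KeyError):
    """An index name is not in the registry."""


# --------------------------------------------------------------------- types

@dataclass
class BandImage:
    """A single named raster band."""

    name: str
    values: np.ndarray
    resolution_m: float = 10.0
    nodata_mask: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape:
            raise ValueError("values and nodata_mask shapes differ")

    @property
    def shape(self):
        return self.values.shape


@dataclass(frozen=True)
class IndexDefinition:
    """A named arithmetic formula over band names.

    The expression grammar supports + - * / ** parentheses, numeric literals
    and ``sqrt``; every name occurring in it must be listed in
    ``band_inputs``.
    """

    name: str
    expression: str
    band_inputs: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        used = _expression_names(self.expression)
        if not used <= set(self.band_inputs):
            missing = sorted(used - set(self.band_inputs))
            raise ValueError(
                f"index {self.name!r}: bands {missing} used in expression "
                "but not declared in band_inputs"
            )


@dataclass
class SceneStack:
    """An ordered multi-band raster; band order is the channel order."""

    bands: list
    geo_meta: dict | None = None

    def __post_init__(self):
        shapes = {b.shape for b in self.bands}
        if len(shapes) > 1:
            raise ValueError(f"bands have differing shapes: {shapes}")
        names = [b.name for b in self.bands]
        if len(set(names)) != len(names):
            raise ValueError("duplicate band names in stack")

    @property
    def height(self):
        return self.bands[0].shape[0]

    @property
    def width(self):
        return self.bands[0].shape[1]

    @property
    def band_names(self):
        return [b.name for b in self.bands]

    def __contains__(self, name):
        return name in self.band_names

    def get(self, name: str) -> BandImage:
        for b in self.bands:
            if b.name == name:
                return b
        raise MissingBandError(f"band {name!r} not in stack {self.band_names}")

    def array(self, dtype=None) -> np.ndarray:
        """Stack to (H, W, C) in band order."""
        arr = np.stack([b.values for b in self.bands], axis=-1)
        return arr if dtype is None else arr.astype(dtype)

    def nodata(self) -> np.ndarray:
        """Union of per-band nodata masks."""
        m = np.zeros((self.height, self.width), dtype=bool)
        for b in self.bands:
            m |= b.nodata_mask
        return m

    @classmethod
    def from_array(cls, arr, band_names, geo_meta=None, resolution_m=10.0):
        arr = np.asarray(arr)
        if arr.shape[-1] != len(band_names):
            raise ValueError("channel count does not match band_names")
        bands = [
            BandImage(n, arr[..., i],
                      BAND_RESOLUTION_M.get(n, resolution_m))
            for i, n in enumerate(band_names)
        ]
        return cls(bands, geo_meta=geo_meta)


# --------------------------------------------------- expression evaluation

_BINOPS = {
    ast.Add: operator.add,
    ast.Sub: operator.sub,
    ast.Mult: operator.mul,
    ast.Pow: operator.pow,
}


def _expression_names(expression: str) -> set:
    tree = ast.parse(expression, mode="eval")
    return {n.id for n in ast.walk(tree) if isinstance(n, ast.Name) and n.id != "sqrt"}


def _eval_expression(expression: str, env: dict, guard: np.ndarray):
    """Evaluate an index formula; flag |denominator| < DENOM_EPS in `guard`."""

    def ev(node):
        if isinstance(node, ast.Expression):
            return ev(node.body)
        if isinstance(node, ast.Constant):
            return float(node.value)
        if isinstance(node, ast.Name):
            if node.id not in env:
                raise MissingBandError(f"band {node.id!r} required but missing")
            return env[node.id]
        if isinstance(node, ast.UnaryOp) and isinstance(node.op, ast.USub):
            return -ev(node.operand)
        if isinstance(node, ast.BinOp):
            left, right = ev(node.left), ev(node.right)
            if isinstance(node.op, ast.Div):
                den = np.asarray(right, dtype=float)
                bad = np.abs(den) < DENOM_EPS
                np.logical_or(guard, np.broadcast_to(bad, guard.shape), out=guard)
                safe = np.where(bad, 1.0, den)
                return left / safe
            op = _BINOPS.get(type(node.op))
            if op is None:
                raise ValueError(f"unsupported operator in expression: {node.op}")
            return op(left, right)
        if (isinstance(node, ast.Call) and isinstance(node.func, ast.Name)
                and node.func.id == "sqrt" and len(node.args) == 1):
            return np.sqrt(ev(node.args[0]))
        raise ValueError(f"unsupported expression element: {ast.dump(node)}")

    return ev(ast.parse(expression, mode="eval"))


def _defn(name, expression):
    return IndexDefinition(name, expression, frozenset(_expression_names(expression)))


#: the 13 broadly used vegetation indices
INDICES_13 = tuple(
    _defn(n, e)
    for n, e in [
        ("NDWI", "(B8A - B11) / (B8A + B11)"),
        ("DWSI", "(B8 + B3) / (B4 + B11)"),
        ("NGRDI", "(B3 - B4) / (B3 + B4)"),
        ("RDI", "B12 / B8A"),
        ("GLI", "(2 * B3 - B2 - B4) / (2 * B3 + B2 + B4)"),
        ("NDRE2", "(B7 - B5) / (B7 + B5)"),
        ("PBI", "B8 / B3"),
        ("NDVI", "(B8A - B4) / (B8A + B4)"),
        ("GNDVI", "(B8A - B3) / (B8A + B3)"),
        ("CIG", "B8A / B3 - 1"),
        ("CVI", "(B8A * B5) / (B3 ** 2)"),
        ("NDRE3", "(B8A - B7) / (B8A + B7)"),
        # Euclidean distance of red and SWIR-2 reflectance
        ("DRS", "sqrt(B4 ** 2 + B12 ** 2)"),
    ]
)

#: the 8 additional red-edge vegetation indices
INDICES_RED_EDGE_8 = tuple(
    _defn(n, e)
    for n, e in [
        ("ND790_670", "(B7 - B4) / (B7 + B4)"),
        ("NDVI690_710", "(B9 - B5) / (B9 + B5)"),
        ("NDRE", "(B8 - B5) / (B8 + B5)"),
        ("NDVI65", "(B6 - B5) / (B6 + B5)"),
        ("GNDVIhyper", "(B7 - B3) / (B7 + B3)"),
        ("RENDVI1", "(B5 - B4) / (B5 + B4)"),
        ("RENDVI2", "(B6 - B4) / (B6 + B4)"),
        ("RI", "(B5 - B3) / (B5 + B3)"),
    ]
)

INDEX_REGISTRY = {d.name: d for d in INDICES_13 + INDICES_RED_EDGE_8}

#: index names whose formula is a normalised difference (range [-1, 1] for
#: positive inputs)
NORMALIZED_DIFFERENCE_INDICES = (
    "NDWI", "NGRDI", "GLI", "NDRE2", "NDVI", "GNDVI", "NDRE3",
    "ND790_670", "NDVI690_710", "NDRE", "NDVI65", "GNDVIhyper",
    "RENDVI1", "RENDVI2", "RI",
)

_NAMES_13 = tuple(d.name for d in INDICES_13)
_NAMES_8 = tuple(d.name for d in INDICES_RED_EDGE_8)
_RGB = ("B4", "B3", "B2")
# red-edge-free reduction: drop the three red-edge bands and the three
# red-edge-derived indices from the 11-band + 13-index set
_BANDS_8 = tuple(b for b in BANDS_11 if b not in ("B5", "B6", "B7"))
_INDICES_10 = tuple(n for n in _NAMES_13 if n not in ("NDRE2", "NDRE3", "CVI"))

#: the six channel selections used in the band-subset experiments
BAND_SELECTIONS = {
    "rgb": _RGB,
    "bands11": BANDS_11,
    "rgb+indices13": _RGB + _NAMES_13,
    "bands11+indices13": BANDS_11 + _NAMES_13,
    "bands8+indices10": _BANDS_8 + _INDICES_10,
    "bands11+indices21": BANDS_11 + _NAMES_13 + _NAMES_8,
}


def register_index(defn: IndexDefinition):
    """Add a user-defined vegetation index to the registry."""
    INDEX_REGISTRY[defn.name] = defn


# ----------------------------------------------------------------- operations

def compute_index(scene: SceneStack, defn) -> BandImage:
    """Evaluate a vegetation-index formula on raw (pre-stretch) band values.

    Pixels where any input band is nodata, or where a denominator magnitude
    falls below ``DENOM_EPS``, are marked nodata in the result.
    """
    if isinstance(defn, str):
        if defn not in INDEX_REGISTRY:
            raise UnknownIndexError(f"unknown vegetation index {defn!r}")
        defn = INDEX_REGISTRY[defn]
    env, mask = {}, np.zeros((scene.height, scene.width), dtype=bool)
    for name in sorted(defn.band_inputs):
        band = scene.get(name)  # raises MissingBandError naming the band
        env[name] = band.values.astype(np.float64)
        mask |= band.nodata_mask
    guard = np.zeros_like(mask)
    values = np.asarray(
        _eval_expression(defn.expression, env, guard), dtype=np.float64
    )
    values = np.broadcast_to(values, mask.shape).copy()
    mask = mask | guard
    values[mask] = 0.0
    res = scene.bands[0].resolution_m
    return BandImage(defn.name, values, res, mask)


def percentile_stretch(band: BandImage, p_low: float = 2.5,
                       p_high: float = 97.5) -> BandImage:
    """Linear stretch to 8 bit: the p_low percentile maps to 0, p_high to 255.

    Values outside the percentile window are clipped; nodata is preserved.
    A constant band maps to all zeros (with a logged warning).
    """
    valid = ~band.nodata_mask
    vals = band.values[valid].astype(np.float64)
    out = np.zeros(band.values.shape, dtype=np.uint8)
    if vals.size == 0:
        logger.warning("band %s: no valid pixels to stretch", band.name)
        return BandImage(band.name, out, band.resolution_m, band.nodata_mask.copy())
    lo = np.percentile(vals, p_low)
    hi = np.percentile(vals, p_high)
    if hi - lo < 1e-12:
        logger.warning("band %s is constant; stretched to all zeros", band.name)
        warnings.warn(f"band {band.name} is constant; stretched to all zeros",
                      stacklevel=2)
    else:
        scaled = (band.values.astype(np.float64) - lo) / (hi - lo) * 255.0
        out = np.clip(np.rint(scaled), 0, 255).astype(np.uint8)
        out[band.nodata_mask] = 0
    return BandImage(band.name, out, band.resolution_m, band.nodata_mask.copy())


def scale_raw_band(band: BandImage, bit_depth: int = 12) -> BandImage:
    """Scale integer digital numbers of the given bit depth directly to 0-255."""
    full = float(2 ** bit_depth - 1)
    vals = band.values.astype(np.float64)
    n_over = int(np.count_nonzero(vals[~band.nodata_mask] > full))
    if n_over:
        logger.warning("band %s: %d values exceed %d-bit range; clipped",
                       band.name, n_over, bit_depth)
    out = np.clip(np.rint(vals / full * 255.0), 0, 255).astype(np.uint8)
    out[band.nodata_mask] = 0
    return BandImage(band.name, out, band.resolution_m, band.nodata_mask.copy())


def resample_band(band: BandImage, target_res_m: float,
                  method: str = "nearest") -> BandImage:
    """Resample between resolutions related by an integer factor.

    Upsampling (e.g. 20 m -> 10 m) enlarges the grid; downsampling averages
    (bilinear) or subsamples (nearest).  Nodata propagates by nearest
    neighbour in both directions.
    """
    if method not in ("nearest", "bilinear"):
        raise ValueError(f"unknown resampling method {method!r}")
    src, dst = float(band.resolution_m), float(target_res_m)
    if src == dst:
        return BandImage(band.name, band.values.copy(), dst,
                         band.nodata_mask.copy())
    if dst < src:  # upsample
        f = src / dst
        if abs(f - round(f)) > 1e-9:
            raise ValueError(f"non-integer resampling factor {f} "
                             f"({src} m -> {dst} m)")
        f = int(round(f))
        mask = band.nodata_mask.repeat(f, axis=0).repeat(f, axis=1)
        if method == "nearest":
            vals = band.values.repeat(f, axis=0).repeat(f, axis=1)
        else:
            from skimage.transform import resize

            vals = resize(band.values.astype(np.float64),
                          (band.shape[0] * f, band.shape[1] * f),
                          order=1, anti_aliasing=False, preserve_range=True)
    else:  # downsample
        f = dst / src
        if abs(f - round(f)) > 1e-9:
            raise ValueError(f"non-integer resampling factor {f} "
                             f"({src} m -> {dst} m)")
        f = int(round(f))
        if band.shape[0] % f or band.shape[1] % f:
            raise ValueError("raster dimensions not divisible by factor")
        mask = band.nodata_mask[::f, ::f]
        if method == "nearest":
            vals = band.values[::f, ::f]
        else:
            h, w = band.shape[0] // f, band.shape[1] // f
            vals = band.values.astype(np.float64).reshape(h, f, w, f).mean(axis=(1, 3))
    return BandImage(band.name, vals, dst, mask)


def build_feature_stack(scene: SceneStack, band_selection) -> SceneStack:
    """Assemble the 8-bit channel stack for a named or explicit selection.

    Raw bands are scaled from 12 bit; indices are computed from the raw bands
    then percentile-stretched.  Channel order follows the selection.
    """
    if isinstance(band_selection, str):
        if band_selection not in BAND_SELECTIONS:
            raise KeyError(
                f"unknown selection {band_selection!r}; "
                f"known: {sorted(BAND_SELECTIONS)}"
            )
        band_selection = BAND_SELECTIONS[band_selection]
    out = []
    for name in band_selection:
        if name in scene:
            out.append(scale_raw_band(scene.get(name)))
        elif name in INDEX_REGISTRY:
            try:
                idx = compute_index(scene, INDEX_REGISTRY[name])
            except MissingBandError as exc:
                raise MissingBandError(
                    f"index {name!r} not computable: {exc.args[0]}"
                ) from exc
            out.append(percentile_stretch(idx))
        else:
            raise UnknownIndexError(
                f"{name!r} is neither a scene band nor a registered index"
            )
    return SceneStack(out, geo_meta=scene.geo_meta)


def class_spectral_profile(stack: SceneStack, labels) -> pd.DataFrame:
    """Per-class, per-band mean pixel value over labelled non-nodata pixels.

    Returns a DataFrame indexed by class id with one column per band, in
    stack channel order.  Classes absent from the labels are omitted.
    """
    lab = np.asarray(getattr(labels, "values", labels))
    if lab.shape != (stack.height, stack.width):
        raise ValueError("labels shape does not match stack")
    nodata = stack.nodata()
    ignore = getattr(labels, "nodata", None)
    rows = {}
    for cls in np.unique(lab):
        if ignore is not None and cls == ignore:
            continue
        sel = (lab == cls) & ~nodata
        if not sel.any():
            continue
        rows[int(cls)] = [float(b.values[sel].mean()) for b in stack.bands]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=stack.band_names)
    df.index.name = "class"
    return df
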