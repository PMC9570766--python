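"""Seed-reproducible synthetic multispectral scenes with labelled damage.

Scenes emulate the spectral structure of pest-damaged boreal forest in
atmospherically corrected Sentinel-2 imagery: a healthy-forest background
with elliptical bark-beetle and leaf-miner damage patches, each class with
its own 11-band mean spectrum (12-bit DN scale).  Pixel variation has two
components: a spatially smoothed multiplicative brightness field shared by
all bands (illumination/canopy-density variation) and smaller additive
per-band noise.  Because the brightness component cancels in band ratios,
class separation is weak in the raw bands but strong in normalised-
difference indices (NDVI, NDWI, NDRE...), reproducing the qualitative
pattern observed in real class-wise spectral profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter

from .dataset import LabelRaster
from .spectral import BANDS_11, SceneStack, BandImage, BAND_RESOLUTION_M

DN_MAX = 4095  # 12-bit

#: per-class per-band mean spectra (DN).  Damage shifts concentrate in the
#: red-edge/NIR (down) and SWIR (up) regions; visible-band shifts are small.
DEFAULT_CLASS_SPECTRA = {
    # band order: B2    B3    B4    B5    B6    B7    B8    B8A   B9    B11   B12
    0: dict(zip(BANDS_11, (300., 520., 360., 740., 1650., 1950., 2150., 2250., 2350., 1150., 620.))),   # healthy forest
    1: dict(zip(BANDS_11, (310., 530., 395., 780., 1420., 1600., 1600., 1650., 1800., 1500., 900.))),   # bark beetle
    2: dict(zip(BANDS_11, (305., 545., 385., 830., 1400., 1520., 1650., 1700., 1900., 1320., 760.))),   # aspen leaf miner
}


@dataclass
class PatchModel:
    """Elliptical damage patches for one class."""

    count: int
    radius_range: tuple  # (min, max) semi-axis in pixels
    shape: str = "ellipse"

    def expected_area(self) -> float:
        r = 0.5 * (self.radius_range[0] + self.radius_range[1])
        return self.count * np.pi * r * r


@dataclass
class SyntheticSpec:
    height: int = 256
    width: int = 256
    band_names: tuple = BANDS_11
    class_spectra: dict = field(
        default_factory=lambda: {c: dict(s) for c, s in
                                 DEFAULT_CLASS_SPECTRA.items()})
    patch_model: dict = field(
        default_factory=lambda: {1: PatchModel(10, (6, 18)),
                                 2: PatchModel(8, (5, 14))})
    pixel_noise_sd: float = 35.0
    brightness_sd: float = 0.18
    spatial_smoothing_scale: float = 4.0
    seed: int = 0

    def __post_init__(self):
        for cls, spectrum in self.class_spectra.items():
            missing = set(self.band_names) - set(spectrum)
            if missing:
                raise ValueError(f"class {cls} spectrum missing bands {missing}")
            for b, m in spectrum.items():
                if not 0 <= m <= DN_MAX:
                    raise ValueError(f"class {cls} band {b} mean {m} outside "
                                     f"12-bit range")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["band_names"] = list(self.band_names)
        d["patch_model"] = {c: {"count": p.count,
                                "radius_range": list(p.radius_range),
                                "shape": p.shape}
                            for c, p in self.patch_model.items()}
        return d

    @classmethod
    def from_dict(cls, d) -> "SyntheticSpec":
        d = dict(d)
        if "band_names" in d:
            d["band_names"] = tuple(d["band_names"])
        if "class_spectra" in d:
            d["class_spectra"] = {int(c): dict(s)
                                  for c, s in d["class_spectra"].items()}
        if "patch_model" in d:
            d["patch_model"] = {
                int(c): PatchModel(p["count"], tuple(p["radius_range"]),
                                   p.get("shape", "ellipse"))
                for c, p in d["patch_model"].items()
            }
        return cls(**d)


def default_spec(seed: int = 0) -> SyntheticSpec:
    """The standard 3-class, 11-band scene specification.

    Damage classes differ from healthy forest mainly through lowered
    red-edge/NIR and raised SWIR reflectance, with visible-band shifts
    below the within-class spread, so index channels carry most of the
    separability; bark-beetle and leaf-miner spectra are mutually distinct
    (SWIR and red-edge-1 shifts differ).
    """
    return SyntheticSpec(seed=seed)


def _smooth_noise(rng, shape, sigma):
    """Unit-variance spatially correlated Gaussian field."""
    f = gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def _stamp_patches(rng, spec) -> np.ndarray:
    h, w = spec.height, spec.width
    total_requested = sum(p.expected_area() for p in spec.patch_model.values())
    if total_requested > 0.8 * h * w:
        raise ValueError(
            f"requested patch area {total_requested:.0f} px exceeds scene "
            f"capacity ({h}x{w})"
        )
    labels = np.zeros((h, w), dtype=np.uint8)
    yy, xx = np.mgrid[0:h, 0:w]
    for cls in sorted(spec.patch_model):
        pm = spec.patch_model[cls]
        rmin, rmax = pm.radius_range
        placed = 0
        for _ in range(pm.count * 50):
            if placed >= pm.count:
                break
            a = rng.uniform(rmin, rmax)
            b = rng.uniform(rmin, rmax)
            margin = int(np.ceil(max(a, b)))
            if 2 * margin >= min(h, w):
                raise ValueError("patch radius too large for scene")
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            theta = rng.uniform(0, np.pi)
            ct, st = np.cos(theta), np.sin(theta)
            u = (xx - cx) * ct + (yy - cy) * st
            v = -(xx - cx) * st + (yy - cy) * ct
            mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
            if (labels[mask] != 0).any():
                continue  # classes (and patches) never overlap
            labels[mask] = cls
            placed += 1
        if placed < pm.count:
            raise ValueError(
                f"could not place {pm.count} non-overlapping patches for "
                f"class {cls}; scene too crowded"
            )
    return labels


def generate_scene(spec: SyntheticSpec):
    """Generate one (SceneStack, LabelRaster) pair; same seed, same output."""
    rng = np.random.default_rng(spec.seed)
    labels = _stamp_patches(rng, spec)
    h, w = spec.height, spec.width
    sigma = spec.spatial_smoothing_scale
    brightness = 1.0 + spec.brightness_sd * _smooth_noise(rng, (h, w), sigma)
    bands = []
    for name in spec.band_names:
        base = np.zeros((h, w))
        for cls, spectrum in spec.class_spectra.items():
            base[labels == cls] = spectrum[name]
        noise = spec.pixel_noise_sd * _smooth_noise(rng, (h, w), sigma)
        dn = np.clip(base * brightness + noise, 0, DN_MAX)
        bands.append(BandImage(name, dn, BAND_RESOLUTION_M.get(name, 10)))
    return SceneStack(bands), LabelRaster(labels)


def generate_scenes(n: int, seed: int = 0, **overrides):
    """Generate n scenes with per-scene derived seeds (reproducible)."""
    out = []
    for i in range(n):
        spec = SyntheticSpec(seed=(seed * 100003 + i) % (2 ** 31 - 1), **overrides)
        out.append(generate_scene(spec))
    return out
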