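"""Vegetation-index computation, stretching, scaling, stacking, profiling."""

import numpy as np
import pytest

from pestseg.spectral import (BAND_SELECTIONS, BANDS_11, INDEX_REGISTRY,
                              NORMALIZED_DIFFERENCE_INDICES, BandImage,
                              IndexDefinition, MissingBandError, SceneStack,
                              UnknownIndexError, build_feature_stack,
                              class_spectral_profile, compute_index,
                              percentile_stretch, resample_band,
                              scale_raw_band)


def _scene_from(band_values: dict, resolution=10.0):
    bands = [BandImage(n, np.asarray(v, dtype=float), resolution)
             for n, v in band_values.items()]
    return SceneStack(bands)


# ------------------------------------------------------------ index formulas

def _oracle_index(name, px):
    """Independent per-pixel re-evaluation of each printed formula."""
    b = px
    formulas = {
        "NDWI": lambda: (b["B8A"] - b["B11"]) / (b["B8A"] + b["B11"]),
        "DWSI": lambda: (b["B8"] + b["B3"]) / (b["B4"] + b["B11"]),
        "NGRDI": lambda: (b["B3"] - b["B4"]) / (b["B3"] + b["B4"]),
        "RDI": lambda: b["B12"] / b["B8A"],
        "GLI": lambda: (2 * b["B3"] - b["B2"] - b["B4"])
        / (2 * b["B3"] + b["B2"] + b["B4"]),
        "NDRE2": lambda: (b["B7"] - b["B5"]) / (b["B7"] + b["B5"]),
        "PBI": lambda: b["B8"] / b["B3"],
        "NDVI": lambda: (b["B8A"] - b["B4"]) / (b["B8A"] + b["B4"]),
        "GNDVI": lambda: (b["B8A"] - b["B3"]) / (b["B8A"] + b["B3"]),
        "CIG": lambda: b["B8A"] / b["B3"] - 1,
        "CVI": lambda: (b["B8A"] * b["B5"]) / b["B3"] ** 2,
        "NDRE3": lambda: (b["B8A"] - b["B7"]) / (b["B8A"] + b["B7"]),
        "DRS": lambda: np.sqrt(b["B4"] ** 2 + b["B12"] ** 2),
        "ND790_670": lambda: (b["B7"] - b["B4"]) / (b["B7"] + b["B4"]),
        "NDVI690_710": lambda: (b["B9"] - b["B5"]) / (b["B9"] + b["B5"]),
        "NDRE": lambda: (b["B8"] - b["B5"]) / (b["B8"] + b["B5"]),
        "NDVI65": lambda: (b["B6"] - b["B5"]) / (b["B6"] + b["B5"]),
        "GNDVIhyper": lambda: (b["B7"] - b["B3"]) / (b["B7"] + b["B3"]),
        "RENDVI1": lambda: (b["B5"] - b["B4"]) / (b["B5"] + b["B4"]),
        "RENDVI2": lambda: (b["B6"] - b["B4"]) / (b["B6"] + b["B4"]),
        "RI": lambda: (b["B5"] - b["B3"]) / (b["B5"] + b["B3"]),
    }
    return formulas[name]()


@pytest.mark.parametrize("name", sorted(INDEX_REGISTRY))
def test_index_matches_per_pixel_oracle(name, rng):
    """Registry evaluation equals an independent per-pixel re-computation."""
    vals = {b: rng.uniform(50, 4000, size=(7, 9)) for b in BANDS_11}
    scene = _scene_from(vals)
    got = compute_index(scene, name).values
    want = np.empty((7, 9))
    for i in range(7):
        for j in range(9):
            want[i, j] = _oracle_index(name, {b: vals[b][i, j] for b in vals})
    np.testing.assert_allclose(got, want, atol=1e-9)


def test_index_hand_examples():
    scene = _scene_from({"B8A": [[0.5]], "B4": [[0.1]], "B11": [[0.5]]})
    assert compute_index(scene, "NDVI").values[0, 0] == pytest.approx(
        0.666667, abs=1e-6)
    # symmetric numerator: B8A == B11 everywhere -> NDWI == 0
    assert compute_index(scene, "NDWI").values[0, 0] == 0.0
    scene2 = _scene_from({"B8A": [[0.6]], "B3": [[0.2]]})
    assert compute_index(scene2, "CIG").values[0, 0] == pytest.approx(2.0)


def test_normalized_difference_indices_bounded(rng):
    """Every normalised-difference index lies in [-1, 1] for positive inputs."""
    vals = {b: rng.uniform(1, 4095, size=(31, 17)) for b in BANDS_11}
    scene = _scene_from(vals)
    for name in NORMALIZED_DIFFERENCE_INDICES:
        v = compute_index(scene, name).values
        assert v.min() >= -1.0 - 1e-12 and v.max() <= 1.0 + 1e-12, name


def test_index_nodata_and_zero_denominator():
    mask = np.array([[True, False], [False, False]])
    bands = [BandImage("B8A", np.array([[1.0, 2.0], [3.0, 0.1]]), 10, mask),
             BandImage("B4", np.array([[1.0, 1.0], [-3.0, 0.1]]), 10)]
    out = compute_index(SceneStack(bands), "NDVI")
    assert out.nodata_mask[0, 0]           # propagated input nodata
    assert out.nodata_mask[1, 0]           # denominator below the guard
    assert not out.nodata_mask[0, 1] and not out.nodata_mask[1, 1]


def test_index_errors():
    scene = _scene_from({"B4": [[1.0]]})
    with pytest.raises(MissingBandError, match="B8A"):
        compute_index(scene, "NDVI")
    with pytest.raises(UnknownIndexError):
        compute_index(scene, "NOPE")
    with pytest.raises(ValueError, match="band_inputs"):
        IndexDefinition("bad", "B1 + B2", frozenset({"B1"}))


# ------------------------------------------------------- stretch and scaling

def test_percentile_stretch_ramp():
    """On a 1000-point ramp in [0,1], 0.025 -> 0 and 0.975 -> 255."""
    ramp = np.linspace(0, 1, 1000).reshape(40, 25)
    out = percentile_stretch(BandImage("x", ramp)).values
    assert out[ramp <= 0.025].max() == 0
    assert out[ramp >= 0.975].min() == 255
    mid = np.isclose(ramp, 0.5, atol=5e-4)
    assert abs(int(out[mid][0]) - 128) <= 1


def test_percentile_stretch_three_level():
    """{-1, 0, +1} at frequencies 2.5/95/2.5 percent maps to {0, 128, 255}."""
    v = np.concatenate([np.full(25, -1.0), np.zeros(950), np.full(25, 1.0)])
    out = percentile_stretch(BandImage("x", v.reshape(40, 25))).values
    assert set(np.unique(out)) == {0, 128, 255}  # 127.5 rounds to 128


def test_percentile_stretch_monotone(rng):
    v = rng.normal(size=(30, 30))
    out = percentile_stretch(BandImage("x", v)).values.astype(int)
    a, b = v.ravel(), out.ravel()
    order = np.argsort(a)
    assert (np.diff(b[order]) >= 0).all()


def test_percentile_stretch_constant_warns():
    with pytest.warns(UserWarning, match="constant"):
        out = percentile_stretch(BandImage("x", np.full((5, 5), 7.0)))
    assert (out.values == 0).all()


@pytest.mark.parametrize("dn,expected", [(4095, 255), (0, 0), (2048, 128)])
def test_scale_raw_band_values(dn, expected):
    out = scale_raw_band(BandImage("B4", np.array([[dn]])))
    assert out.values[0, 0] == expected
    assert out.values.dtype == np.uint8


def test_scale_raw_band_clips_over_range():
    out = scale_raw_band(BandImage("B4", np.array([[5000.0]])))
    assert out.values[0, 0] == 255


# ------------------------------------------------------------------ stacking

@pytest.mark.parametrize("selection,expected", [
    ("rgb", 3), ("bands11", 11), ("rgb+indices13", 16),
    ("bands11+indices13", 24), ("bands8+indices10", 18),
    ("bands11+indices21", 32),
])
def test_selection_channel_counts(scene_and_labels, selection, expected):
    scene, _ = scene_and_labels
    stack = build_feature_stack(scene, selection)
    assert len(stack.bands) == expected == len(BAND_SELECTIONS[selection])
    assert stack.band_names == list(BAND_SELECTIONS[selection])
    assert all(b.values.dtype == np.uint8 for b in stack.bands)


def test_rgb_selection_order(scene_and_labels):
    scene, _ = scene_and_labels
    assert build_feature_stack(scene, "rgb").band_names == ["B4", "B3", "B2"]


def test_stack_missing_band_error():
    scene = _scene_from({"B2": [[1.0]], "B3": [[1.0]], "B4": [[1.0]]})
    with pytest.raises(MissingBandError, match="NDVI"):
        build_feature_stack(scene, ["NDVI"])


def test_feature_stack_deterministic(scene_and_labels):
    scene, _ = scene_and_labels
    a = build_feature_stack(scene, "rgb+indices13").array()
    b = build_feature_stack(scene, "rgb+indices13").array()
    np.testing.assert_array_equal(a, b)


# ---------------------------------------------------------------- resampling

def test_resample_shapes_and_invariance():
    band = BandImage("B11", np.full((8, 8), 3.3), resolution_m=20)
    up = resample_band(band, 10, "bilinear")
    assert up.shape == (16, 16)
    np.testing.assert_allclose(up.values, 3.3)

    checker = np.array([[1, 2], [3, 4]], dtype=float)
    up2 = resample_band(BandImage("B5", checker, 20), 10, "nearest")
    np.testing.assert_array_equal(
        up2.values, np.array([[1, 1, 2, 2], [1, 1, 2, 2],
                              [3, 3, 4, 4], [3, 3, 4, 4]]))
    with pytest.raises(ValueError, match="non-integer"):
        resample_band(BandImage("B9", checker, 60), 25)


# ----------------------------------------------------------------- profiling

def test_profile_constant_classes():
    stack = SceneStack([BandImage("B2", np.where(np.eye(4) > 0, 200.0, 50.0))])
    labels = np.eye(4, dtype=int)
    prof = class_spectral_profile(stack, labels)
    assert prof.loc[0, "B2"] == 50.0 and prof.loc[1, "B2"] == 200.0


def test_profile_matches_loop_oracle(feature_stack, scene_and_labels, rng):
    _, labels = scene_and_labels
    prof = class_spectral_profile(feature_stack, labels)
    lab = labels.values
    for cls in prof.index:
        for k, name in enumerate(feature_stack.band_names):
            acc, n = 0.0, 0
            plane = feature_stack.bands[k].values
            sel = lab == cls
            acc = plane[sel].astype(float).sum()
            n = int(sel.sum())
            assert prof.loc[cls, name] == pytest.approx(acc / n, abs=1e-9)


def test_profile_omits_absent_class(feature_stack):
    labels = np.zeros((feature_stack.height, feature_stack.width), dtype=int)
    prof = class_spectral_profile(feature_stack, labels)
    assert list(prof.index) == [0]
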