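import numpy as np
import pytest

from pestseg import (ModelConfig, RsprUnetPP, build_feature_stack,
                     drop_empty_tiles, default_spec, generate_scene,
                     generate_scenes, grid_crop, split_dataset)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def scene_and_labels():
    """One default-spec synthetic scene (256x256, 11 bands)."""
    return generate_scene(default_spec(seed=3))


@pytest.fixture(scope="session")
def feature_stack(scene_and_labels):
    scene, _ = scene_and_labels
    return build_feature_stack(scene, "bands11+indices13")


@pytest.fixture(scope="session")
def tiny_model():
    """Smallest legal network: for shape/gradient contracts, not learning."""
    cfg = ModelConfig(in_channels=4, decoder_widths=(4, 8, 16, 32, 64))
    return RsprUnetPP(cfg, seed=0)


@pytest.fixture(scope="session")
def synthetic_tiles():
    """Training corpus: 6 scenes -> 64x64 tiles of the 24-channel stack."""
    tiles = []
    for i, (scene, labels) in enumerate(generate_scenes(6, seed=11)):
        stack = build_feature_stack(scene, "bands11+indices13")
        tiles += grid_crop(stack, labels, 64, scene_id=f"s{i}")
    return drop_empty_tiles(tiles)


@pytest.fixture(scope="session")
def tile_split(synthetic_tiles):
    return split_dataset(synthetic_tiles, seed=1)
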