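import warnings

import numpy as np
import pytest
from hypothesis import settings

import leafvit as lv

# property tests are derandomised so runs are reproducible everywhere
settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")

# non-standard input sides are used freely in tests to keep them fast
warnings.filterwarnings(
    "ignore", message="input_side .* outside the standard set")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_dataset():
    """45-image, 3-class separable synthetic set at 32px (fast fixture)."""
    cfg = lv.SyntheticConfig(
        side=32,
        class_counts={"brown_rust": 15, "healthy": 15, "yellow_rust": 15},
        dot_radius_range=(2.0, 3.5),
        seed=7,
    )
    return lv.generate_dataset(cfg)


@pytest.fixture(scope="session")
def wrcd_style_dataset():
    """90-image, 3-class separable set at 50px (the training benchmark)."""
    cfg = lv.SyntheticConfig(
        side=50,
        class_counts={"brown_rust": 30, "healthy": 30, "yellow_rust": 30},
        seed=0,
    )
    return lv.generate_dataset(cfg)


def tiny_spec(model_id: int, side: int = 35, n_classes: int = 3,
              **overrides) -> lv.ModelSpec:
    """A narrow spec (2 filters, 4-dim tokens) for fast structural tests."""
    from leafvit.blocks import (ConvBlockConfig, PatchEmbedConfig,
                                TransformerBlockConfig)
    defaults = dict(
        model_id=model_id, input_side=side, n_classes=n_classes,
        conv=ConvBlockConfig(filters=2),
        transformer=TransformerBlockConfig(num_heads=2, proj_dim=4,
                                           mlp_widths=(6, 4)),
        patch=PatchEmbedConfig(patch_side=5, proj_dim=4),
        head_widths=(5, 4), head_dropout=0.0,
    )
    defaults.update(overrides)
    return lv.ModelSpec(**defaults)
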