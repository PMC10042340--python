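"""Shared fixtures.

The trained network is expensive (minutes on one CPU), so it is built
once per session and shared by the recovery, cohort-discrimination and
map-localization tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from octamb.phantom import PhantomConfig, generate_bscan
from octamb.segnet import (
    AugmentConfig,
    ModelConfig,
    TrainConfig,
    build_model,
    train_model,
)

#: deliberately small but full-pipeline scale: 128 x 256 phantoms,
#: 8 base channels; enough for <= 2 px recovery in ~2 min of training
TRAIN_N = 96
TRAIN_EPOCHS = 5


@pytest.fixture(scope="session")
def phantom_config() -> PhantomConfig:
    return PhantomConfig()


@pytest.fixture(scope="session")
def tiny_config() -> PhantomConfig:
    """A small phantom for fast unit tests (64 x 64)."""
    from octamb.phantom import FovealPit

    return PhantomConfig(
        width_ascans=64,
        depth_pixels=64,
        boundary_waviness_amplitude=1.0,
        foveal_pit=FovealPit(depth_px=5.0, halfwidth_px=10.0),
    )


@pytest.fixture(scope="session")
def model_config(phantom_config) -> ModelConfig:
    return ModelConfig(
        input_depth=phantom_config.depth_pixels,
        input_width=phantom_config.width_ascans // 4,
        base_channels=8,
        seed=0,
    )


@pytest.fixture(scope="session")
def train_config() -> TrainConfig:
    # flip-only augmentation keeps the session fixture fast; the full
    # scale/rotation path is covered by the augment_sample unit tests
    return TrainConfig(
        epochs=TRAIN_EPOCHS,
        seed=0,
        augmentation=AugmentConfig(
            lr_flip=True,
            scale_range=(1.0, 1.0),
            rotation_deg=0.0,
            quarter_split=True,
        ),
    )


@pytest.fixture(scope="session")
def clean_training_samples(phantom_config):
    return [
        generate_bscan(phantom_config, (), seed=1000 + i) for i in range(TRAIN_N)
    ]


@pytest.fixture(scope="session")
def trained_model(model_config, train_config, clean_training_samples):
    model = build_model(model_config)
    model, history = train_model(model, clean_training_samples, train_config)
    assert history[-1] < history[0]
    return model


@pytest.fixture(scope="session")
def heldout_clean_samples(phantom_config):
    return [
        generate_bscan(phantom_config, (), seed=50_000 + i) for i in range(50)
    ]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
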