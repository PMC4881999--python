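"""Shared fixtures: small feature configurations and synthetic material.

The "small" configuration (8 px window, 2 rings, modes up to 2) keeps the
loop-based oracles and trained-classifier fixtures fast while exercising
every code path of the full-size default configuration.
"""

from __future__ import annotations

import sys
from dataclasses import replace
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from wildcount.detector import DetectorConfig, harvest_training_set, train
from wildcount.fourierhog import FeatureConfig, FourierHOG
from wildcount.synthetic import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def small_config() -> FeatureConfig:
    return FeatureConfig(
        window=8, m_max=2, k_max=2, n_rings=2, composite_budget=8
    )


@pytest.fixture(scope="session")
def small_hog(small_config) -> FourierHOG:
    return FourierHOG(small_config)


@pytest.fixture(scope="session")
def default_hog() -> FourierHOG:
    return FourierHOG(FeatureConfig())


@pytest.fixture(scope="session")
def small_scene_config() -> SceneConfig:
    """A compact scene matched to the small 8 px feature window."""
    return SceneConfig(
        width=96,
        height=96,
        n_animals=6,
        blob_length=6.0,
        blob_width=2.5,
        min_separation=16.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def small_detector_config() -> DetectorConfig:
    return DetectorConfig(contrast_window=5, contrast_threshold=0.05, seed=11)


@pytest.fixture(scope="session")
def small_classifier(small_hog, small_scene_config, small_detector_config):
    """A classifier trained on a handful of small synthetic scenes."""
    images, truths = [], []
    for i in range(8):
        image, truth = generate_scene(replace(small_scene_config, seed=100 + i))
        images.append(image)
        truths.append(truth[["x", "y"]].to_numpy())
    samples = harvest_training_set(
        images,
        truths,
        small_hog,
        n_negative_per_image=6,
        rng=np.random.default_rng(42),
    )
    return train(
        samples, feature_config=small_hog.config, config=small_detector_config
    )
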