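"""Shared fixtures: small synthetic datasets and a lightly trained pipeline."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from wildface.chipping import ChipSpec
from wildface.detection import DetectorConfig
from wildface.embedding import EmbedderConfig
from wildface.landmarks import ShapeConfig
from wildface.manifest import split_dataset
from wildface.pipeline import train_pipeline
from wildface.synthetic import SyntheticDatasetConfig, generate_dataset


@pytest.fixture(scope="session")
def tiny_manifest():
    """36 in-memory images, 6 identities, easy regime."""
    return generate_dataset(
        SyntheticDatasetConfig(n_identities=6, images_per_identity=6, image_size=160, seed=11)
    )


@pytest.fixture(scope="session")
def small_split():
    """48 images, 8 identities, split 80/20."""
    m = generate_dataset(
        SyntheticDatasetConfig(n_identities=8, images_per_identity=6, image_size=160, seed=21)
    )
    return split_dataset(m, 0.2, stratify_key="identity", seed=0)


# light configs: same algorithms, smaller budgets, shared across the suite
LIGHT_SHAPE = ShapeConfig(cascade_depth=4, trees_per_stage=15, oversample=5, seed=0)
LIGHT_DETECTOR = DetectorConfig(hard_negative_rounds=1, seed=0)


@pytest.fixture(scope="session")
def trained_small(small_split):
    """A full pipeline trained with reduced budgets on the small split."""
    train, _ = small_split
    return train_pipeline(
        train,
        seed=0,
        detector_config=LIGHT_DETECTOR,
        shape_config=LIGHT_SHAPE,
        embed_config=EmbedderConfig(seed=0),
        chip_spec=ChipSpec(),
    )
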