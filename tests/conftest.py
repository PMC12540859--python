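"""Shared fixtures: synthetic crop sets and one trained desk encoder.

The expensive artifacts (balanced 2,000-crop set, desk-profile encoders)
are session-scoped so the representation-learning, robustness and
clustering benchmarks all evaluate the same models on the same pixels.
"""

from __future__ import annotations

import numpy as np
import pytest

from lbxpheno.contrastive import (
    AugmentationConfig,
    ContrastiveEncoder,
    EncoderConfig,
    train_encoder,
)
from lbxpheno.synthetic import generate_crop_dataset


@pytest.fixture(scope="session")
def balanced_crops():
    """2,000 balanced crops (200 per phenotype), the desk training corpus."""
    crops, labels = generate_crop_dataset(200, seed=101)
    return crops, labels


@pytest.fixture(scope="session")
def small_crops():
    """300 crops over 5 phenotypes for cheap unit tests."""
    crops, labels = generate_crop_dataset(
        60, phenotypes=("CTC", "CEC", "Lymph", "Mono", "Gran"), seed=7
    )
    return crops, labels


@pytest.fixture(scope="session")
def trained_encoders(balanced_crops):
    """Desk-profile encoders trained from 3 seeds, with their loss traces."""
    crops, _ = balanced_crops
    out = {}
    for seed in (0, 1, 2):
        model, trace = train_encoder(
            crops, EncoderConfig(), AugmentationConfig(), seed=seed
        )
        out[seed] = (model, trace)
    return out


@pytest.fixture(scope="session")
def desk_encoder(trained_encoders):
    """The seed-0 trained desk encoder."""
    return trained_encoders[0][0]


@pytest.fixture(scope="session")
def random_encoder(balanced_crops):
    """An untrained (randomly initialized) encoder with fitted normalization."""
    crops, _ = balanced_crops
    model = ContrastiveEncoder(EncoderConfig(), seed=900)
    model.set_normalization(crops)
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
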