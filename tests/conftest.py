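"""Shared fixtures: tiny synthetic datasets and a quickly trained model."""

import numpy as np
import pytest

from m6acnn.datasets import split_train_test
from m6acnn.encoding import enac_encode_batch
from m6acnn.model import M6AConvNet, ModelConfig
from m6acnn.synthetic import (
    PlantedMotif,
    SimSpec,
    generate_dataset,
    motif_pfm_from_consensus,
)

#: A config small enough for 21-nt toy windows and fast unit tests.
TINY_CONFIG = ModelConfig(
    conv_blocks=[{"n_filters": 8, "kernel_rows": 4, "pool": 2, "dropout": 0.1}],
    fc_units=[8],
    fc_dropout=0.1,
    learning_rate=2e-3,
    batch_size=16,
    max_epochs=4,
    seed=3,
)


@pytest.fixture(scope="session")
def tiny_samples():
    """60+60 toy windows of length 21 with a planted upstream GGU triplet."""
    pm = PlantedMotif(
        motif_pfm_from_consensus("GGU"), offset_range=(-8, -5), insertion_rate=1.0
    )
    spec = SimSpec(60, 60, length=21, planted_motifs=(pm,), seed=5)
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def tiny_encoded(tiny_samples):
    return enac_encode_batch(tiny_samples)


@pytest.fixture(scope="session")
def tiny_results(tiny_encoded):
    X, y = tiny_encoded
    return M6AConvNet(X, y, TINY_CONFIG).fit()
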