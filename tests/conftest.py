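"""Shared fixtures: small network configurations and toy data.

The small configurations keep every architectural component (conv stack,
shortcut, depthwise-separable primary capsules, routing, decoder) while
shrinking filter counts so unit tests run in seconds.
"""

import numpy as np
import pytest

from ecapsp.capsnet import NetworkConfig
from ecapsp.peptides import ProteinRecord, PeptideWindow, extract_window
from ecapsp.synthetic import SyntheticSpec, generate
from ecapsp.training import TrainConfig


def tiny_network_config(**overrides) -> NetworkConfig:
    base = dict(conv1_filters=8, conv2_filters=8, n_primary=15, d_primary=4,
                decoder_hidden=(16, 16), dropout_p=0.0)
    base.update(overrides)
    return NetworkConfig(**base)


@pytest.fixture
def tiny_config() -> NetworkConfig:
    return tiny_network_config()


@pytest.fixture
def fast_train_config() -> TrainConfig:
    return TrainConfig(epochs=3, batch_size=32, seed=0, val_fraction=0.0)


@pytest.fixture
def toy_records() -> list[ProteinRecord]:
    rng = np.random.default_rng(7)
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    recs = []
    for i in range(6):
        seq = "".join(rng.choice(aas, size=50))
        # guarantee at least one serine well inside the sequence
        seq = seq[:25] + "S" + seq[26:]
        recs.append(ProteinRecord(f"prot{i}", seq))
    return recs


@pytest.fixture
def toy_window(toy_records) -> PeptideWindow:
    return extract_window(toy_records[0], 26)


@pytest.fixture
def separable_dataset():
    """A strongly motif-driven synthetic dataset (deterministic motif)."""
    spec = SyntheticSpec(n_pos=60, n_neg=60, seed=11,
                         motif={-3: ("K", 1.0), 2: ("K", 1.0)},
                         boundary_fraction=0.0)
    dataset, records, sites = generate(spec)
    return dataset
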