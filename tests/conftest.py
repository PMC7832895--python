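"""Shared fixtures: small synthetic datasets generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from atpres.features import build_dataset
from atpres.subclassifiers_cnn import NetworkSpec, TrainingConfig
from atpres.synthetic_data import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def sim_small():
    """Eight short chains with a planted profile signal."""
    cfg = SimConfig(n_chains=8, length_range=(40, 60), signal_strength=4.0,
                    seed=3)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def dataset_small(sim_small):
    chains, profiles, ss = sim_small
    return build_dataset(chains, profiles, ss)


@pytest.fixture(scope="session")
def sim_medium():
    """~1500 residues, strong signal: enough for quick model fits."""
    cfg = SimConfig(n_chains=16, length_range=(80, 110),
                    signal_strength=4.0, seed=7)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def dataset_medium(sim_medium):
    chains, profiles, ss = sim_medium
    return build_dataset(chains, profiles, ss)


@pytest.fixture(scope="session")
def tiny_spec():
    """Narrow network: the architectures at minimum width for fast tests."""
    return NetworkSpec(branch_filters=2, head_units=16)


@pytest.fixture(scope="session")
def quick_config():
    return TrainingConfig(max_epochs=2, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
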