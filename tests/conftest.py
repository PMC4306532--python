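"""Shared fixtures: small synthetic datasets reused across test modules."""

import numpy as np
import pytest

from prestim import synthetic as syn

#: lattice-aligned occipital source position used throughout the tests
SOURCE_POS = (0.0, -60.0, 15.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_260_927)


@pytest.fixture(scope="session")
def coupled_config():
    """Desk-scale config with one alpha source coupled to RT at r = 0.2."""
    return syn.SimConfig(
        n_trials=500,
        n_channels=30,
        epoch_window=(-1.4, 0.2),
        seed=42,
        source_specs=[
            syn.GroundTruthSource(position=SOURCE_POS, rt_coupling_r=0.2)
        ],
    )


@pytest.fixture(scope="session")
def coupled_dataset(coupled_config):
    """One simulated subject with ground-truth amplitude-RT coupling."""
    table, epochs, eog, amp = syn.simulate_dataset(coupled_config)
    return {
        "config": coupled_config,
        "table": table,
        "epochs": epochs,
        "eog": eog,
        "true_amp": amp,
    }


@pytest.fixture(scope="session")
def tiny_config():
    """Very small noiseless-ish config for fast structural tests."""
    return syn.SimConfig(
        n_trials=40,
        n_blocks=4,
        n_channels=12,
        epoch_window=(-1.2, 0.2),
        seed=7,
        source_specs=[syn.GroundTruthSource(position=SOURCE_POS)],
    )
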