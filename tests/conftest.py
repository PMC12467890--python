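"""Shared fixtures: small simulated datasets and one pre-trained estimator
reused across tests to keep the suite fast."""

from __future__ import annotations

import numpy as np
import pytest

from bcen.estimator import BcenConfig, train_bcen
from bcen.synthetic import (
    SimulationConfig,
    make_group_dataset,
    sample_directed_graph,
    simulate_nonlinear_var,
)


@pytest.fixture(scope="session")
def small_var():
    """A 6-region linear VAR series with known ground truth."""
    net = sample_directed_graph(6, 0.25, 1.0, seed=11)
    cfg = SimulationConfig(n_regions=6, n_timepoints=240, edge_density=0.25,
                           noise_sd=0.1, nonlinearity="identity", seed=11)
    return net, simulate_nonlinear_var(net, cfg)


@pytest.fixture(scope="session")
def trained_bcen(small_var):
    """Gates + trace from a short training run on the small series."""
    _, ts = small_var
    cfg = BcenConfig(generator_epochs=90, discriminator_epochs=30, seed=3)
    gates, trace = train_bcen(ts, cfg)
    return cfg, gates, trace


@pytest.fixture(scope="session")
def tiny_group_dataset():
    """A small two-class graph population for classifier tests."""
    return make_group_dataset(n_per_class=10, v=12, n_perturbed_edges=6,
                              effect_size=0.9, noise_sd=0.1, seed=5)
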