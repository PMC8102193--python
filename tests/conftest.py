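import logging

import numpy as np
import pytest

from cascadeomics.datasets import TemporalOmicsDataset
from cascadeomics.synthetic import (
    GroundTruthNetwork,
    SimulationConfig,
    generate_network,
    simulate_dataset,
)

logging.getLogger("cascadeomics").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_net() -> GroundTruthNetwork:
    """10-actor, 2-cluster planted cascade."""
    return generate_network(10, 2, mean_out_degree=1.5, seed=7)


@pytest.fixture(scope="session")
def noiseless_config() -> SimulationConfig:
    return SimulationConfig(seed=7, deterministic=True, noise_sd=0.0,
                            n_background=20, protein_missing_rate=0.0)


@pytest.fixture(scope="session")
def noiseless_datasets(small_net, noiseless_config):
    return simulate_dataset(small_net, noiseless_config, "proliferative")


@pytest.fixture(scope="session")
def noisy_datasets(small_net):
    config = SimulationConfig(seed=7, noise_sd=0.1, n_background=50)
    return simulate_dataset(small_net, config, "proliferative")


def make_transcript(values, **kw):
    """Small transcript dataset around an explicit (F, T+1, P) array."""
    values = np.asarray(values, dtype=float)
    F, T1, P = values.shape
    defaults = dict(
        modality="transcript",
        features=[f"G{i}" for i in range(F)],
        time_hours=tuple(float(t) for t in range(T1)),
        individuals=[f"P{p + 1}" for p in range(P)],
        groups=["proliferative"] * P,
    )
    defaults.update(kw)
    return TemporalOmicsDataset(values=values, **defaults)


def make_protein(values, **kw):
    kw.setdefault("modality", "protein")
    return make_transcript(values, **kw)
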