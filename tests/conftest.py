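import numpy as np
import pytest

from ophpred.curation import curate_optimal_ph
from ophpred.data import CuratedDataset, ProteinRecord
from ophpred.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """Small family-structured dataset shared across tests (read-only)."""
    return simulate_dataset(
        SimulationConfig(
            n_families=6,
            members_per_family=8,
            seed_length=80,
            mutation_rate=0.05,
            label_noise_sd=0.3,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def small_dataset(small_sim):
    dataset, _ = curate_optimal_ph(small_sim.measurements, small_sim.records)
    return dataset


@pytest.fixture()
def toy_dataset():
    """Four hand-written records with labels, for exact-value tests."""
    records = [
        ProteinRecord("r1", "MKVLAA"),
        ProteinRecord("r2", "MKVLAC"),
        ProteinRecord("r3", "GGGGGG"),
        ProteinRecord("r4", "WWWWWW"),
    ]
    labels = {"r1": 5.0, "r2": 5.5, "r3": 7.0, "r4": 9.0}
    return CuratedDataset(records, labels)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
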