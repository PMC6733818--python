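import numpy as np
import pytest

from satconnect.seqio import SequenceRecord

BASES = "ACGT"


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def mutate(seq: str, positions, rng: np.random.Generator) -> str:
    out = list(seq)
    for p in positions:
        out[p] = rng.choice([b for b in BASES if b != out[p]])
    return "".join(out)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def monomer(rng):
    """One 345-bp satellite monomer with a single MspI site."""
    from satconnect.simsat import _random_monomer

    return _random_monomer(345, np.random.default_rng(42), "CCGG")


@pytest.fixture(scope="session")
def monomer_record(monomer):
    return SequenceRecord(id="monomer", bases=monomer)


@pytest.fixture(scope="session")
def drive_dataset():
    """Small seeded drive-regime dataset shared across tests."""
    from satconnect.simsat import SimulationConfig, simulate_dataset

    return simulate_dataset(
        SimulationConfig(mode="drive", seed=11, library_size=12, n_pairs=60)
    )


@pytest.fixture(scope="session")
def frozen_dataset():
    from satconnect.simsat import SimulationConfig, simulate_dataset

    return simulate_dataset(
        SimulationConfig(mode="frozen", seed=11, library_size=12, n_pairs=60)
    )
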