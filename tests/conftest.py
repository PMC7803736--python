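"""Shared fixtures: small simulated datasets, reusable across test modules."""

import numpy as np
import pytest

from rollcirc.align import GenomeIndex
from rollcirc.sim import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def clean_dataset():
    """Zero-error dataset: 8 isoforms, 2 reads each."""
    cfg = SimConfig(
        seed=7,
        n_genes=5,
        n_isoforms=8,
        reads_per_isoform=2,
        sub_rate=0.0,
        ins_rate=0.0,
        del_rate=0.0,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def noisy_dataset():
    """Default-error (8%) dataset: 6 isoforms, 3 reads each."""
    cfg = SimConfig(seed=11, n_genes=5, n_isoforms=6, reads_per_isoform=3)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def clean_index(clean_dataset):
    return GenomeIndex(clean_dataset.genome)


@pytest.fixture(scope="session")
def noisy_index(noisy_dataset):
    return GenomeIndex(noisy_dataset.genome)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_seq(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
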