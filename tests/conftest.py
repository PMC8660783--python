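import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from panelburden.data_io import TranscriptModel
from panelburden.simulate import SpikeIns, SyntheticConfig, make_toy_transcripts


@pytest.fixture(scope="session")
def toy_transcripts():
    return make_toy_transcripts()


@pytest.fixture(scope="session")
def plus_tx(toy_transcripts):
    tx = toy_transcripts["ATM"]
    assert tx.strand == "+"
    return tx


@pytest.fixture(scope="session")
def minus_tx(toy_transcripts):
    for tx in toy_transcripts.values():
        if tx.strand == "-":
            return tx
    raise AssertionError("no minus-strand toy transcript")


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


def small_synthetic_config(seed: int = 42, **overrides) -> SyntheticConfig:
    """A scaled-down cohort that keeps every filter's arithmetic coherent
    (the cohort-frequency threshold still resolves to >= 1 carrier)."""
    defaults = dict(
        n_cases=250,
        n_abcfs_controls=150,
        n_aspree_controls=2500,
        seed=seed,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)
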