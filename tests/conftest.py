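import numpy as np
import pytest

from saavkit.core_io import ProteinRecord
from saavkit.saav_db import build_database
from saavkit.simulate import simulate_proteome, simulate_variants


@pytest.fixture(scope="session")
def proteome():
    return simulate_proteome(30, seed=101)


@pytest.fixture(scope="session")
def variants(proteome):
    return simulate_variants(proteome, 200, il_fraction=0.15, seed=102)


@pytest.fixture(scope="session")
def database(proteome, variants):
    records, entries, report = build_database(proteome, variants)
    return records, entries, report


@pytest.fixture()
def tiny_protein():
    return ProteinRecord("P1", "MKAR", "P1 tiny")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(7)
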