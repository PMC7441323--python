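import numpy as np
import pytest

from trgscreen import SimulationConfig, default_scoring, simulate_clade


@pytest.fixture(scope="session")
def scoring():
    return default_scoring()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def default_clade():
    """One seeded clade at the default study conditions, shared across
    tests that only read from it."""
    return simulate_clade(SimulationConfig(seed=7))


@pytest.fixture()
def clade_on_disk(tmp_path, default_clade):
    from trgscreen import write_clade

    return write_clade(default_clade, tmp_path / "clade")


def random_protein_str(rng, length):
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))
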