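import numpy as np
import pytest

from plastedit.simulate import SimulationConfig, table1_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Fast settings for unit tests: short gene, modest coverage."""
    return SimulationConfig(
        seed=7,
        gene_length_nt=300,
        rna_coverage=60.0,
        dna_coverage=60.0,
        read_length_nt=50,
        n_edits=8,
    )


@pytest.fixture(scope="session")
def table1():
    return table1_fixture()
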