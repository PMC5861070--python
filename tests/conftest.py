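import pytest

from domainevol.phylo import jtt_model
from domainevol.simulate import SimulationConfig, simulate_family


@pytest.fixture(scope="session")
def jtt():
    return jtt_model()


@pytest.fixture(scope="session")
def sim_family():
    """One simulated family under the default study conditions."""
    return simulate_family(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def small_family():
    """A small, fast family for pipeline/CLI smoke tests."""
    return simulate_family(
        SimulationConfig(
            n_taxa=8,
            pro_codons=80,
            mature_codons=60,
            nls_insert_codon=30,
            seed=11,
        )
    )
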