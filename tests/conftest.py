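import pytest

from cyanosphere import SimulationConfig, default_lexicon, simulate_all


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def default_sim():
    """The default synthetic community (seed 42, 20 heterotrophs)."""
    return simulate_all(SimulationConfig(seed=42))
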