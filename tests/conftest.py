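import pytest

from supportdyn.lexicons import default_lexicons
from supportdyn.simulate import SimConfig, fixture_dictionaries, simulate_corpus


@pytest.fixture(scope="session")
def small_community():
    """A 60-thread synthetic community with ground truth (shared, read-only)."""
    return simulate_corpus(SimConfig(seed=42, n_threads=60))


@pytest.fixture(scope="session")
def dictionaries():
    return fixture_dictionaries()


@pytest.fixture(scope="session")
def lexicons():
    return default_lexicons()
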