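import pytest

from pycdb import EnumerationConfig, enumerate_catalog


@pytest.fixture(scope="session")
def full_catalog():
    """The default (published-configuration) catalog, built once per session."""
    return enumerate_catalog()


@pytest.fixture(scope="session")
def small_catalog():
    """A 4-metal sub-catalog: sparse enough in m/z for guarded decoy placement."""
    return enumerate_catalog(EnumerationConfig(metals=("Cd", "Hg", "Pb", "Zn")))
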