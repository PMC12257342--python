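import pytest
from hypothesis import settings

import bmbkit as bk

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lib():
    return bk.default_library()


@pytest.fixture(scope="session")
def brass():
    return bk.yellow_brass()


@pytest.fixture(scope="session")
def cu62(lib):
    return lib.get_nuclide("Cu-62")


@pytest.fixture(scope="session")
def zn63(lib):
    return lib.get_nuclide("Zn-63")


@pytest.fixture(scope="session")
def cu64(lib):
    return lib.get_nuclide("Cu-64")


@pytest.fixture(scope="session")
def sn123m(lib):
    return lib.get_nuclide("Sn-123m")


@pytest.fixture(scope="session")
def annihilation_mixture(cu62, zn63):
    """The 511 keV peak decay mixture measured after 15 MV in-field irradiation."""
    return bk.MixtureDecay([(cu62, 0.87), (zn63, 0.13)])
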