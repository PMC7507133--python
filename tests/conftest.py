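import numpy as np
import pytest

from shapecloud import build_surface_cloud, carve_fragment, load_fixture


@pytest.fixture(scope="session")
def sorbic():
    return load_fixture("sorbic_acid")


@pytest.fixture(scope="session")
def benzene():
    return load_fixture("benzene")


@pytest.fixture(scope="session")
def druglike():
    return load_fixture("druglike")


@pytest.fixture(scope="session")
def sorbic_cloud(sorbic):
    return build_surface_cloud(sorbic)


@pytest.fixture(scope="session")
def druglike_cloud(druglike):
    return build_surface_cloud(druglike)


@pytest.fixture(scope="session")
def chain_fragment(sorbic):
    """Carbon-chain analogue carved from sorbic acid (all C + their H)."""
    subset = [i for i, e in enumerate(sorbic.elements) if e == "C"]
    subset += [
        i
        for i, e in enumerate(sorbic.elements)
        if e == "H" and any(j in subset for j in sorbic.neighbors(i))
    ]
    return carve_fragment(sorbic, subset)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
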