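import pytest

from symbiofba import (
    assemble_community,
    make_toy_symbiosis,
)


@pytest.fixture(scope="session")
def toy():
    """Default-parameter toy symbiosis (calibrated anchors)."""
    return make_toy_symbiosis()


@pytest.fixture(scope="session")
def two_compartment(toy):
    """Obligate symbiont + host community (facultative symbiont absent)."""
    return assemble_community(toy.spec(None))


@pytest.fixture(scope="session")
def three_compartment(toy):
    """Full trio at biomass ratio 1:1."""
    return assemble_community(toy.spec(1.0))
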