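import pytest

from envdesign import fixture as fx
from envdesign.benchmark import ReferenceDistribution


@pytest.fixture(scope="session")
def pool():
    return fx.fixture_pool()


@pytest.fixture(scope="session")
def space():
    return fx.fixture_space()


@pytest.fixture(scope="session")
def community():
    return fx.fixture_community()


@pytest.fixture(scope="session")
def mapping():
    """The exhaustive 176-environment mapping of the packaged community.

    Built once per session; every downstream benchmark test reuses it.
    """
    return fx.fixture_mapping()


@pytest.fixture(scope="session")
def objectives(mapping):
    return fx.fixture_objectives(mapping)


@pytest.fixture(scope="session")
def references(mapping, objectives):
    return {
        name: ReferenceDistribution.from_mapping(mapping, obj)
        for name, obj in objectives.items()
    }
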