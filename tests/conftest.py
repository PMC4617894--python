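import pytest

from contextcore import fixtures
from contextcore.consistency import DEFAULT_POLICY, fastcc


@pytest.fixture(scope="session")
def toy1():
    model, truth = fixtures.toy1()
    return model, truth


@pytest.fixture(scope="session")
def toy1_model(toy1):
    return toy1[0]


@pytest.fixture(scope="session")
def toy1_consistent(toy1):
    model, _ = toy1
    return model.restrict(fastcc(model, DEFAULT_POLICY))


@pytest.fixture(scope="session")
def parallel():
    return fixtures.parallel_paths()


@pytest.fixture(scope="session")
def biomass_toy():
    return fixtures.biomass_toy()
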