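import math

import pytest

from rnaxplore import (
    BpStackModel,
    RnaSequence,
    enumerate_structures,
    generate_bistable_fixture,
    partition_function,
)


@pytest.fixture(scope="session")
def model():
    return BpStackModel()


@pytest.fixture(scope="session")
def bistable():
    return generate_bistable_fixture()


@pytest.fixture(scope="session")
def triple_helix():
    return RnaSequence("GGGAAACCC", id="triple")


@pytest.fixture(scope="session")
def bistable_enum(bistable, model):
    return enumerate_structures(bistable, model)


@pytest.fixture(scope="session")
def bistable_pf(bistable, model):
    return partition_function(bistable, model)


@pytest.fixture(scope="session")
def bistable_exact_p(bistable, model, bistable_enum):
    """Exact Boltzmann distribution of the bistable fixture, by enumeration."""
    beta = model.beta
    w = {s: math.exp(-beta * e) for s, e in bistable_enum}
    Z = sum(w.values())
    return {s: v / Z for s, v in w.items()}
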