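import pytest

from ramthr.gradients import default_gradients
from ramthr.root_sim import SimConfig, simulate
from ramthr.thr_model import MUTANT, WT, ThrModelParams


@pytest.fixture(scope="session")
def gradients():
    return default_gradients()


@pytest.fixture(scope="session")
def params():
    return ThrModelParams()


@pytest.fixture(scope="session")
def wt_trajectory():
    return simulate(SimConfig(genotype=WT))


@pytest.fixture(scope="session")
def mutant_trajectory():
    return simulate(SimConfig(genotype=MUTANT))
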