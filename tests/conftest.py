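import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from coopage.demography import BREEDER, Population

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def add_female(pop, *, age=0, role=BREEDER, terr=-1, s=0.8, neut=(0.0, 0.0)):
    """Append one living female to a manually built population; returns the row."""
    row = int(pop.claim_slots(1)[0])
    pop.alive[row] = True
    pop.age[row] = age
    pop.role[row] = role
    pop.terr[row] = terr
    pop.newborn[row] = False
    pop.afr[row] = -1
    pop.sur_m[row] = s
    pop.sur_p[row] = s
    pop.mate_m[row] = s
    pop.mate_p[row] = s
    pop.neut[row] = neut
    pop.mate_neut[row] = neut
    return row


@pytest.fixture
def blank_population():
    def factory(n_territories, c, capacity=64):
        return Population(n_territories, c, capacity)

    return factory
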