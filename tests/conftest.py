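import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from queuemet.network import (
    BalancingFlow,
    KineticLaw,
    MetabolicNetwork,
    MetabolitePool,
    Reaction,
)

settings.register_profile(
    "queuemet",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("queuemet")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def uni_uni_network(
    vf=1.0, vr=0.0, k_s=1.0, k_p=1.0, s0=1.0, p0=0.0, packet=0.001
) -> MetabolicNetwork:
    """Two pools, one reaction A -> B; uniform packet quantum."""
    pools = [
        MetabolitePool("a", "A", s0, packet, pathway_tags=frozenset({"shared"})),
        MetabolitePool("b", "B", p0, packet, pathway_tags=frozenset({"shared"})),
    ]
    law = KineticLaw(vf=vf, vr=vr, k_s1=k_s, k_p1=k_p)
    rxn = Reaction("r1", "toy enzyme", ["a"], ["b"], law)
    return MetabolicNetwork(pools, [rxn], name="uni_uni_toy").validate()


def constant_arrival_network(mu=0.02, packet=0.001, dt=0.01) -> MetabolicNetwork:
    """One pool fed by a constant flow firing with exactly probability mu."""
    pools = [
        MetabolitePool("a", "A", 1.0, packet, pathway_tags=frozenset({"shared"}))
    ]
    flow = BalancingFlow("src", "a", coefficient=mu * packet / dt)
    return MetabolicNetwork(pools, [], [flow], name="constant_arrival").validate()


@pytest.fixture
def toy_uni_uni():
    return uni_uni_network()
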