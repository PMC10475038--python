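"""Analytically tractable toy networks used for testing and validation.

All fixtures use a uniform packet size across pools, so one firing moves the
same concentration quantum everywhere and packet bookkeeping maps exactly
onto concentration flux.  Constants are sized so every initial firing
probability is well inside the mu << 1 band at the default 0.01 s step.

* ``uni_uni_chain`` — an irreversible linear chain P1 -> P2 -> ... -> Pn
  (Vr = 0); relaxes toward the Michaelis-Menten flux of the head pool and
  its terminal pool is monotonically non-decreasing in every realization.
* ``closed_cycle`` — a ring with no flows; total packet count is exactly
  conserved for the lifetime of any run.
* ``branch_competition`` — several reactions draining one small queue;
  exercises underflow skipping and random application order.
* ``planted_steady_state`` — a source -> chain -> sink whose constants make
  the initial state stationary in expectation (every pool's arrival and
  service probabilities balance at t = 0).
"""

from __future__ import annotations

import numpy as np

from .errors import SizeTooSmall
from .network import (
    BalancingFlow,
    KineticLaw,
    MetabolicNetwork,
    MetabolitePool,
    Reaction,
)

FIXTURE_KINDS = (
    "uni_uni_chain",
    "closed_cycle",
    "branch_competition",
    "planted_steady_state",
)

_PACKET = 0.001  # uniform quantum, mmol/L
_DT0 = 0.01  # reference step used to size firing probabilities


def _pool(pid: str, conc: float) -> MetabolitePool:
    return MetabolitePool(
        id=pid, name=pid, initial_concentration=conc, packet_size=_PACKET,
        pathway_tags=frozenset({"shared"}), compartment="cytosol",
    )


def _vf_for_velocity(v0: float, den0: float, reversible: bool) -> float:
    # v0 = (Vf*1 - Vr*1)/den0 with all species ratios 1 at t=0
    factor = 0.99 if reversible else 1.0
    return v0 * den0 / factor


def make_fixture(
    kind: str, size: int = 3, rng: np.random.Generator | None = None
) -> MetabolicNetwork:
    """Construct a named toy network with `size` pools (deterministic)."""
    if size < 2:
        raise SizeTooSmall(f"fixture needs >= 2 pools, got {size}")
    if kind == "uni_uni_chain":
        return _uni_uni_chain(size)
    if kind == "closed_cycle":
        return _closed_cycle(size)
    if kind == "branch_competition":
        return _branch_competition(size)
    if kind == "planted_steady_state":
        return _planted_steady_state(size)
    raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")


def _uni_uni_chain(size: int) -> MetabolicNetwork:
    pools = [_pool("p1", 1.0)] + [_pool(f"p{i}", 0.1) for i in range(2, size + 1)]
    reactions = []
    for i in range(1, size):
        # irreversible: v0 = Vf*(S/K)/(1 + S/K + P/K); mu0 ~ 0.02 at the head
        law = KineticLaw(vf=0.0042, vr=0.0, k_s1=1.0, k_p1=1.0)
        reactions.append(
            Reaction(
                id=f"r{i}", enzyme=f"step {i}", substrates=[f"p{i}"],
                products=[f"p{i + 1}"], law=law,
            )
        )
    return MetabolicNetwork(
        pools=pools, reactions=reactions, name=f"uni_uni_chain_{size}", version="fixture"
    ).validate()


def _closed_cycle(size: int) -> MetabolicNetwork:
    pools = [_pool(f"p{i}", 1.0) for i in range(1, size + 1)]
    v0 = 0.002  # mu0 = 0.02
    vf = _vf_for_velocity(v0, den0=3.0, reversible=True)
    reactions = [
        Reaction(
            id=f"r{i}",
            enzyme=f"ring step {i}",
            substrates=[f"p{i}"],
            products=[f"p{i % size + 1}"],
            law=KineticLaw(vf=vf, vr=vf / 100.0, k_s1=1.0, k_p1=1.0),
            reverse_defaulted=True,
        )
        for i in range(1, size + 1)
    ]
    return MetabolicNetwork(
        pools=pools, reactions=reactions, name=f"closed_cycle_{size}", version="fixture"
    ).validate()


def _branch_competition(size: int) -> MetabolicNetwork:
    # a deliberately tiny source queue (5 packets) feeding size-1 drains
    pools = [_pool("source", 0.005)] + [
        _pool(f"sink{i}", 0.1) for i in range(1, size)
    ]
    reactions = []
    for i in range(1, size):
        law = KineticLaw(vf=0.0105, vr=0.0, k_s1=0.005, k_p1=1.0)
        reactions.append(
            Reaction(
                id=f"drain{i}", enzyme=f"drain {i}", substrates=["source"],
                products=[f"sink{i}"], law=law,
            )
        )
    return MetabolicNetwork(
        pools=pools, reactions=reactions, name=f"branch_competition_{size}",
        version="fixture",
    ).validate()


def _planted_steady_state(size: int) -> MetabolicNetwork:
    # source -> p1 -> ... -> pn -> sink, all concentrations 1.0; every step
    # and both flows run at velocity v0, so expected net drift is 0 everywhere
    pools = [_pool(f"p{i}", 1.0) for i in range(1, size + 1)]
    v0 = 0.005  # mu0 = 0.05
    vf = _vf_for_velocity(v0, den0=3.0, reversible=True)
    reactions = [
        Reaction(
            id=f"r{i}",
            enzyme=f"chain step {i}",
            substrates=[f"p{i}"],
            products=[f"p{i + 1}"],
            law=KineticLaw(vf=vf, vr=vf / 100.0, k_s1=1.0, k_p1=1.0),
            reverse_defaulted=True,
        )
        for i in range(1, size)
    ]
    # the flows are part of the planted construction, hence not GA-tunable
    flows = [
        BalancingFlow(id="inflow", pool_id="p1", coefficient=v0, tunable=False),
        BalancingFlow(id="outflow", pool_id=f"p{size}", coefficient=-v0, tunable=False),
    ]
    return MetabolicNetwork(
        pools=pools, reactions=reactions, flows=flows,
        name=f"planted_steady_state_{size}", version="fixture",
    ).validate()
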