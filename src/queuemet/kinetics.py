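"""Reversible two-substrate/two-product Michaelis-Menten rate law.

The full bi-bi form is

    v = (Vf * S1*S2/(K_S1*K_S2) - Vr * P1*P2/(K_P1*K_P2))
        / ((1 + S1/K_S1 + P1/K_P1) * (1 + S2/K_S2 + P2/K_P2))

For reactions with a single substrate and/or a single product the absent
species' ratio term is omitted: its factor contributes 1 to the numerator
product and the second denominator parenthesis collapses toward 1.  With
Vr = 0 and P = 0 this reduces to the classical irreversible Michaelis-Menten
law Vf*S/(K_S + S).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping

from .errors import MissingConcentration, NegativeConcentration, ReverseAlreadySet
from .network import KineticLaw, MetabolicNetwork, Reaction

#: reverse velocity defaulting rule: reverse reactions run 100x slower
REVERSE_DEFAULT_RATIO = 100.0


@dataclass(frozen=True)
class RateSnapshot:
    """Signed instantaneous velocity of one reaction or balancing flow."""

    reaction_id: str
    velocity: float  # mmol/L/s, signed: >0 net forward, <0 net reverse
    direction: str  # "forward" | "reverse" | "equilibrium"

    @staticmethod
    def from_velocity(reaction_id: str, velocity: float) -> "RateSnapshot":
        if velocity > 0:
            direction = "forward"
        elif velocity < 0:
            direction = "reverse"
        else:
            direction = "equilibrium"
        return RateSnapshot(reaction_id, velocity, direction)


def _ratio(conc: float, k: float | None) -> float:
    # absent slot: K is None, ratio term omitted
    return conc / k if k is not None else 0.0


def reaction_rate(
    reaction: Reaction, concentrations: Mapping[str, float]
) -> RateSnapshot:
    """Evaluate the rate law for one reaction at the given concentrations."""
    conc = []
    for pid in reaction.species:
        if pid not in concentrations:
            raise MissingConcentration(
                f"reaction {reaction.id!r}: no concentration for pool {pid!r}"
            )
        value = concentrations[pid]
        if value < 0:
            raise NegativeConcentration(
                f"reaction {reaction.id!r}: negative concentration for pool {pid!r}"
            )
        conc.append(value)
    law = reaction.law
    ns = len(reaction.substrates)
    s1 = conc[0]
    s2 = conc[1] if ns == 2 else None
    p1 = conc[ns]
    p2 = conc[ns + 1] if len(reaction.products) == 2 else None

    rs1 = _ratio(s1, law.k_s1)
    rs2 = _ratio(s2, law.k_s2) if s2 is not None else None
    rp1 = _ratio(p1, law.k_p1)
    rp2 = _ratio(p2, law.k_p2) if p2 is not None else None

    num = law.vf * rs1 * (rs2 if rs2 is not None else 1.0)
    num -= law.vr * rp1 * (rp2 if rp2 is not None else 1.0)
    den = (1.0 + rs1 + rp1) * (1.0 + (rs2 or 0.0) + (rp2 or 0.0))
    velocity = num / den
    if not math.isfinite(velocity):  # pragma: no cover - guarded by validation
        raise NegativeConcentration(f"reaction {reaction.id!r}: non-finite rate")
    return RateSnapshot.from_velocity(reaction.id, velocity)


def apply_reverse_default(law: KineticLaw) -> KineticLaw:
    """Fill an absent reverse velocity with Vf / 100.

    Raises :class:`ReverseAlreadySet` when Vr is already present (non-None and
    not marked absent by the caller); callers flag ``reverse_defaulted``.
    """
    if law.vr is not None:
        raise ReverseAlreadySet("law already has a reverse velocity")
    return replace(law, vr=law.vf / REVERSE_DEFAULT_RATIO)


def rate_vector(
    network: MetabolicNetwork, concentrations: Mapping[str, float]
) -> list[RateSnapshot]:
    """One snapshot per reaction plus one per balancing flow, ordered by id.

    Flow velocities equal their (concentration-independent) coefficients.
    """
    snaps = [reaction_rate(r, concentrations) for r in network.reactions]
    snaps.sort(key=lambda s: s.reaction_id)
    flow_snaps = [
        RateSnapshot.from_velocity(f.id, f.coefficient) for f in network.flows
    ]
    flow_snaps.sort(key=lambda s: s.reaction_id)
    return snaps + flow_snaps
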