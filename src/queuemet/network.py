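"""Metabolic-network domain model and its on-disk format.

A network is a set of metabolite *pools* (queues of discrete concentration
packets), enzymatic *reactions* (reversible Michaelis-Menten steps with at
most two substrates and two products, unit stoichiometry) and *balancing
flows* (constant-rate pseudo-reactions standing in for everything outside
the modelled pathways).

The file format is plain TOML with three section families::

    [pool.<id>]      name, initial_mmol_per_l, packet_size_mmol_per_l?,
                     lumped_members?, pathways, compartment
    [reaction.<id>]  enzyme, substrates, products, vf, vr?, k_s1, k_s2?,
                     k_p1, k_p2?, k_i? (accepted, documented as unused)
    [flow.<id>]      pool, coefficient, tunable

All concentrations are mmol/L; velocities and flow coefficients mmol/L/s.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path

from .errors import (
    DuplicateId,
    MalformedSection,
    MissingPoolReference,
    NonPositiveConstant,
    SelfLump,
    UnknownPool,
    UnwritableLocation,
)

PATHWAY_TAGS = frozenset({"glycolysis", "ppp", "tca", "beta_oxidation", "shared"})
COMPARTMENTS = frozenset({"cytosol", "mitochondrion", "lumped"})

#: floor for the default packet-size rule, mmol/L
PACKET_SIZE_FLOOR = 1e-6


def default_packet_size(initial_concentration: float) -> float:
    """Default concentration quantum: ~1000 packets per pool, floored at 1e-6."""
    return max(initial_concentration / 1000.0, PACKET_SIZE_FLOOR)


@dataclass
class MetabolitePool:
    """One metabolite queue: its concentration and packet quantum Delta(C_i)."""

    id: str
    name: str
    initial_concentration: float  # mmol/L
    packet_size: float  # mmol/L
    lumped_members: list[str] = field(default_factory=list)
    pathway_tags: frozenset[str] = frozenset()
    compartment: str = "cytosol"

    def validate(self) -> None:
        if self.initial_concentration < 0:
            raise NonPositiveConstant(
                f"pool {self.id!r}: initial concentration must be >= 0"
            )
        if not self.packet_size > 0:
            raise NonPositiveConstant(f"pool {self.id!r}: packet size must be > 0")
        bad = set(self.pathway_tags) - PATHWAY_TAGS
        if bad:
            raise MalformedSection(f"pool {self.id!r}: unknown pathway tags {sorted(bad)}")
        if self.compartment not in COMPARTMENTS:
            raise MalformedSection(
                f"pool {self.id!r}: unknown compartment {self.compartment!r}"
            )

    @property
    def is_lumped(self) -> bool:
        return len(self.lumped_members) >= 2


@dataclass
class KineticLaw:
    """Constants of one reversible (bi-bi or reduced) Michaelis-Menten step.

    K constants are present exactly for the occupied species slots; ``k_i``
    (an inhibition constant) is accepted from files for completeness but the
    rate law carries no inhibition term, so it is stored and otherwise unused.
    """

    vf: float  # mmol/L/s
    vr: float | None = None  # mmol/L/s; None until set or defaulted to Vf/100
    k_s1: float | None = None
    k_s2: float | None = None
    k_p1: float | None = None
    k_p2: float | None = None
    k_i: float | None = None  # parsed but not used by the rate law

    def validate(self, n_substrates: int, n_products: int, context: str = "") -> None:
        if self.vr is None:
            raise MalformedSection(
                f"{context}: reverse velocity unset (apply the Vf/100 default first)"
            )
        if self.vf < 0 or self.vr < 0:
            raise NonPositiveConstant(f"{context}: Vf and Vr must be >= 0")
        slots = {
            "k_s1": (self.k_s1, n_substrates >= 1),
            "k_s2": (self.k_s2, n_substrates >= 2),
            "k_p1": (self.k_p1, n_products >= 1),
            "k_p2": (self.k_p2, n_products >= 2),
        }
        for key, (value, occupied) in slots.items():
            if occupied and value is None:
                raise MalformedSection(f"{context}: missing {key} for occupied slot")
            if not occupied and value is not None:
                raise MalformedSection(f"{context}: {key} given but slot is empty")
            if value is not None and not value > 0:
                raise NonPositiveConstant(f"{context}: {key} must be > 0")


@dataclass
class Reaction:
    id: str
    enzyme: str
    substrates: list[str]  # 1-2 pool ids
    products: list[str]  # 1-2 pool ids
    law: KineticLaw
    #: True when Vr was filled in by the "100x slower" rule rather than measured
    reverse_defaulted: bool = False

    def validate(self) -> None:
        if not 1 <= len(self.substrates) <= 2 or not 1 <= len(self.products) <= 2:
            raise MalformedSection(
                f"reaction {self.id!r}: needs 1-2 substrates and 1-2 products"
            )
        if set(self.substrates) & set(self.products):
            raise MalformedSection(
                f"reaction {self.id!r}: substrates and products must be disjoint"
            )
        self.law.validate(len(self.substrates), len(self.products), f"reaction {self.id!r}")

    @property
    def species(self) -> list[str]:
        return list(self.substrates) + list(self.products)


@dataclass
class BalancingFlow:
    """Constant external source (coefficient > 0) or sink (< 0) on one pool."""

    id: str
    pool_id: str
    coefficient: float  # mmol/L/s, signed
    tunable: bool = True

    def validate(self) -> None:
        if not math.isfinite(self.coefficient):
            raise MalformedSection(f"flow {self.id!r}: coefficient must be finite")


@dataclass
class MetabolicNetwork:
    pools: list[MetabolitePool]
    reactions: list[Reaction]
    flows: list[BalancingFlow] = field(default_factory=list)
    name: str = "unnamed"
    version: str = "0"

    # -- validation ----------------------------------------------------------

    def validate(self) -> "MetabolicNetwork":
        if not self.pools:
            raise MalformedSection("a network must contain at least one pool")
        for coll, label in ((self.pools, "pool"), (self.reactions, "reaction"),
                            (self.flows, "flow")):
            seen: set[str] = set()
            for item in coll:
                if item.id in seen:
                    raise DuplicateId(f"duplicate {label} id {item.id!r}")
                seen.add(item.id)
        ids = {p.id for p in self.pools}
        for pool in self.pools:
            pool.validate()
        for rxn in self.reactions:
            rxn.validate()
            for pid in rxn.species:
                if pid not in ids:
                    raise MissingPoolReference(
                        f"reaction {rxn.id!r} references unknown pool {pid!r}"
                    )
        for flow in self.flows:
            flow.validate()
            if flow.pool_id not in ids:
                raise MissingPoolReference(
                    f"flow {flow.id!r} references unknown pool {flow.pool_id!r}"
                )
        return self

    # -- lookups -------------------------------------------------------------

    def pool(self, pool_id: str) -> MetabolitePool:
        for p in self.pools:
            if p.id == pool_id:
                return p
        raise UnknownPool(f"no pool {pool_id!r} in network {self.name!r}")

    def initial_concentrations(self) -> dict[str, float]:
        return {p.id: p.initial_concentration for p in self.pools}

    def reaction_count_per_pool(self) -> dict[str, int]:
        """K_i of the time-step condition: reactions (and flows) touching each pool."""
        counts = {p.id: 0 for p in self.pools}
        for rxn in self.reactions:
            for pid in rxn.species:
                counts[pid] += 1
        for flow in self.flows:
            counts[flow.pool_id] += 1
        return counts


# ---------------------------------------------------------------------------
# lumping


def lump_pools(
    network: MetabolicNetwork,
    member_a: str,
    member_b: str,
    kinetic_identity: str,
    lumped_id: str | None = None,
) -> MetabolicNetwork:
    """Merge two adjacent pools into a single queue.

    The lumped pool starts at the summed concentration; every reaction
    referencing either member is re-pointed at the lumped pool and keeps the
    kinetic constants it already carried (by convention these are the
    constants of ``kinetic_identity``, the member whose enzyme kinetics were
    available).  A reaction that referenced *both* members becomes an internal
    conversion of the lumped queue and is dropped.
    """
    if member_a == member_b:
        raise SelfLump(f"cannot lump pool {member_a!r} with itself")
    if kinetic_identity not in (member_a, member_b):
        raise UnknownPool(
            f"kinetic identity {kinetic_identity!r} must be one of the members"
        )
    pa, pb = network.pool(member_a), network.pool(member_b)
    new_id = lumped_id or f"{member_a}_{member_b}"
    total = pa.initial_concentration + pb.initial_concentration
    lumped = MetabolitePool(
        id=new_id,
        name=f"{pa.name} {pb.name}",
        initial_concentration=total,
        packet_size=default_packet_size(total),
        lumped_members=(pa.lumped_members or [pa.name]) + (pb.lumped_members or [pb.name]),
        pathway_tags=frozenset(pa.pathway_tags | pb.pathway_tags),
        compartment=pa.compartment if pa.compartment == pb.compartment else "lumped",
    )
    members = {member_a, member_b}
    pools = [p for p in network.pools if p.id not in members] + [lumped]

    def repoint(ids: list[str]) -> list[str]:
        return [new_id if i in members else i for i in ids]

    reactions = []
    for rxn in network.reactions:
        subs, prods = repoint(rxn.substrates), repoint(rxn.products)
        if set(subs) & set(prods):
            continue  # internal conversion within the lumped queue
        reactions.append(replace(rxn, substrates=subs, products=prods))
    flows = [
        replace(f, pool_id=new_id) if f.pool_id in members else f for f in network.flows
    ]
    return MetabolicNetwork(
        pools=pools, reactions=reactions, flows=flows,
        name=network.name, version=network.version,
    ).validate()


# ---------------------------------------------------------------------------
# file format

_POOL_KEYS = {
    "name", "initial_mmol_per_l", "packet_size_mmol_per_l", "lumped_members",
    "pathways", "compartment",
}
_REACTION_KEYS = {
    "enzyme", "substrates", "products", "vf", "vr",
    "k_s1", "k_s2", "k_p1", "k_p2", "k_i",
}
_FLOW_KEYS = {"pool", "coefficient", "tunable"}


def _check_keys(section: dict, allowed: set[str], context: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise MalformedSection(f"{context}: unknown keys {sorted(unknown)}")


def _number(section: dict, key: str, context: str, optional: bool = False):
    value = section.get(key)
    if value is None:
        if optional:
            return None
        raise MalformedSection(f"{context}: missing required key {key!r}")
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise MalformedSection(f"{context}: key {key!r} must be a number")
    return float(value)


def read_network(path: str | Path) -> MetabolicNetwork:
    """Parse and fully validate a network definition file."""
    path = Path(path)
    with open(path, "rb") as fh:
        try:
            doc = tomllib.load(fh)
        except tomllib.TOMLDecodeError as exc:
            raise MalformedSection(f"{path}: {exc}") from exc

    _check_keys(doc, {"network", "pool", "reaction", "flow"}, str(path))
    meta = doc.get("network", {})
    _check_keys(meta, {"name", "version"}, f"{path} [network]")

    pools = []
    for pid, sec in doc.get("pool", {}).items():
        ctx = f"[pool.{pid}]"
        if not isinstance(sec, dict):
            raise MalformedSection(f"{ctx}: not a table")
        _check_keys(sec, _POOL_KEYS, ctx)
        conc = _number(sec, "initial_mmol_per_l", ctx)
        psize = _number(sec, "packet_size_mmol_per_l", ctx, optional=True)
        pools.append(
            MetabolitePool(
                id=pid,
                name=str(sec.get("name", pid)),
                initial_concentration=conc,
                packet_size=psize if psize is not None else default_packet_size(conc),
                lumped_members=[str(m) for m in sec.get("lumped_members", [])],
                pathway_tags=frozenset(sec.get("pathways", [])),
                compartment=str(sec.get("compartment", "cytosol")),
            )
        )

    # zero-concentration pools without an explicit quantum inherit the network median
    explicit = [p.packet_size for p in pools if p.initial_concentration > 0]
    if explicit:
        median = sorted(explicit)[len(explicit) // 2]
        for p in pools:
            if p.initial_concentration == 0 and p.packet_size == PACKET_SIZE_FLOOR:
                p.packet_size = median

    reactions = []
    for rid, sec in doc.get("reaction", {}).items():
        ctx = f"[reaction.{rid}]"
        if not isinstance(sec, dict):
            raise MalformedSection(f"{ctx}: not a table")
        _check_keys(sec, _REACTION_KEYS, ctx)
        subs = [str(s) for s in sec.get("substrates", [])]
        prods = [str(s) for s in sec.get("products", [])]
        vf = _number(sec, "vf", ctx)
        vr = _number(sec, "vr", ctx, optional=True)
        law = KineticLaw(
            vf=vf,
            vr=vr if vr is not None else vf / 100.0,
            k_s1=_number(sec, "k_s1", ctx, optional=True),
            k_s2=_number(sec, "k_s2", ctx, optional=True),
            k_p1=_number(sec, "k_p1", ctx, optional=True),
            k_p2=_number(sec, "k_p2", ctx, optional=True),
            k_i=_number(sec, "k_i", ctx, optional=True),
        )
        reactions.append(
            Reaction(
                id=rid,
                enzyme=str(sec.get("enzyme", rid)),
                substrates=subs,
                products=prods,
                law=law,
                reverse_defaulted=vr is None,
            )
        )

    flows = []
    for fid, sec in doc.get("flow", {}).items():
        ctx = f"[flow.{fid}]"
        if not isinstance(sec, dict):
            raise MalformedSection(f"{ctx}: not a table")
        _check_keys(sec, _FLOW_KEYS, ctx)
        if "pool" not in sec:
            raise MalformedSection(f"{ctx}: missing required key 'pool'")
        flows.append(
            BalancingFlow(
                id=fid,
                pool_id=str(sec["pool"]),
                coefficient=_number(sec, "coefficient", ctx),
                tunable=bool(sec.get("tunable", True)),
            )
        )

    return MetabolicNetwork(
        pools=pools,
        reactions=reactions,
        flows=flows,
        name=str(meta.get("name", path.stem)),
        version=str(meta.get("version", "0")),
    ).validate()


def _toml_value(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    if isinstance(value, str):
        return '"' + value.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(value, (list, tuple)):
        return "[" + ", ".join(_toml_value(v) for v in value) + "]"
    raise TypeError(f"unsupported TOML value {value!r}")


def write_network(network: MetabolicNetwork, path: str | Path) -> None:
    """Serialize a network; ``read_network`` of the result is field-identical."""
    network.validate()
    lines = [
        "[network]",
        f"name = {_toml_value(network.name)}",
        f"version = {_toml_value(network.version)}",
        "",
    ]
    for p in network.pools:
        lines.append(f"[pool.{p.id}]")
        lines.append(f"name = {_toml_value(p.name)}")
        lines.append(f"initial_mmol_per_l = {_toml_value(p.initial_concentration)}")
        lines.append(f"packet_size_mmol_per_l = {_toml_value(p.packet_size)}")
        if p.lumped_members:
            lines.append(f"lumped_members = {_toml_value(p.lumped_members)}")
        lines.append(f"pathways = {_toml_value(sorted(p.pathway_tags))}")
        lines.append(f"compartment = {_toml_value(p.compartment)}")
        lines.append("")
    for r in network.reactions:
        lines.append(f"[reaction.{r.id}]")
        lines.append(f"enzyme = {_toml_value(r.enzyme)}")
        lines.append(f"substrates = {_toml_value(r.substrates)}")
        lines.append(f"products = {_toml_value(r.products)}")
        lines.append(f"vf = {_toml_value(r.law.vf)}")
        if not r.reverse_defaulted:
            lines.append(f"vr = {_toml_value(r.law.vr)}")
        for key in ("k_s1", "k_s2", "k_p1", "k_p2", "k_i"):
            value = getattr(r.law, key)
            if value is not None:
                lines.append(f"{key} = {_toml_value(value)}")
        lines.append("")
    for f in network.flows:
        lines.append(f"[flow.{f.id}]")
        lines.append(f"pool = {_toml_value(f.pool_id)}")
        lines.append(f"coefficient = {_toml_value(f.coefficient)}")
        lines.append(f"tunable = {_toml_value(f.tunable)}")
        lines.append("")
    try:
        Path(path).write_text("\n".join(lines), encoding="utf-8")
    except OSError as exc:
        raise UnwritableLocation(f"cannot write network to {path}: {exc}") from exc


def export_reaction_table(network: MetabolicNetwork, path: str | Path) -> None:
    """Tab-separated audit export of the reaction table."""
    header = "id\tenzyme\tsubstrates\tproducts\tvf\tvr\tk_s1\tk_s2\tk_p1\tk_p2"
    rows = [header]
    for r in network.reactions:
        fields = [
            r.id, r.enzyme, ",".join(r.substrates), ",".join(r.products),
            repr(r.law.vf), repr(r.law.vr),
        ] + [
            "" if getattr(r.law, k) is None else repr(getattr(r.law, k))
            for k in ("k_s1", "k_s2", "k_p1", "k_p2")
        ]
        rows.append("\t".join(fields))
    try:
        Path(path).write_text("\n".join(rows) + "\n", encoding="utf-8")
    except OSError as exc:
        raise UnwritableLocation(f"cannot write reaction table to {path}: {exc}") from exc
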