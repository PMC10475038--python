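"""Bundled default network: integrated cellular energy metabolism.

68 enzymatic reactions spanning glycolysis, the pentose phosphate pathway,
the TCA cycle and fatty-acid beta-oxidation (palmitate, seven spiral turns),
plus the anaplerotic links between them.  Two TCA queues are lumped pairs —
isocitrate + cis-aconitate and succinyl-CoA + succinate — each carrying the
kinetic identity of the second member, and TCA starting concentrations are
literature values.  Glucose starts at 5.0 mmol/L (normal blood glucose) and
is deliberately not replenished: as it runs out, glycolytic firing
probabilities collapse and beta-oxidation becomes the dominant acetyl-CoA
source.

The exact kinetic constants of the integrated model are not published, so
this network is a curated, approximate stand-in with faithful topology: the
Michaelis constants are set to the initial concentrations (each reaction
starts at half-saturation) and every forward velocity is calibrated so that
the reaction's initial firing probability equals a designed target in the
1-10%-per-step band at the reference time step of 0.01 s.  The per-step
packet-flow targets are routed so that every pool except glucose is balanced
at t = 0; residual exchange with processes outside the model (cofactor
turnover, transport, biosynthetic drains) is carried by constant balancing
flows, which are the GA-tunable quantities.  Reverse velocities all use the
Vf/100 default.
"""

from __future__ import annotations

import numpy as np

from .network import (
    BalancingFlow,
    KineticLaw,
    MetabolicNetwork,
    MetabolitePool,
    Reaction,
    default_packet_size,
)

#: reference time step (s) used for the firing-probability calibration
CALIBRATION_DT = 0.01

#: pool ids of the TCA cycle, in cycle order (starting concentrations are
#: literature values for liver cells)
TCA_POOL_IDS = [
    "acetyl_coa",
    "oxaloacetate",
    "citrate",
    "isocitrate_cisaconitate",
    "alpha_ketoglutarate",
    "succinylcoa_succinate",
    "fumarate",
    "malate",
]

# id, name, initial mmol/L, tags, compartment, lumped members
_POOLS = [
    # glycolysis
    ("glucose", "Glucose", 5.0, ("glycolysis",), "cytosol", ()),
    ("g6p", "Glucose 6-phosphate", 0.083, ("glycolysis", "ppp"), "cytosol", ()),
    ("f6p", "Fructose 6-phosphate", 0.030, ("glycolysis", "ppp"), "cytosol", ()),
    ("fbp", "Fructose 1,6-bisphosphate", 0.031, ("glycolysis",), "cytosol", ()),
    ("dhap", "Dihydroxyacetone phosphate", 0.140, ("glycolysis",), "cytosol", ()),
    ("gap", "Glyceraldehyde 3-phosphate", 0.019, ("glycolysis", "ppp"), "cytosol", ()),
    ("bpg13", "1,3-bisphosphoglycerate", 0.004, ("glycolysis",), "cytosol", ()),
    ("pg3", "3-phosphoglycerate", 0.120, ("glycolysis",), "cytosol", ()),
    ("pg2", "2-phosphoglycerate", 0.030, ("glycolysis",), "cytosol", ()),
    ("pep", "Phosphoenolpyruvate", 0.023, ("glycolysis",), "cytosol", ()),
    ("pyruvate", "Pyruvate", 0.100, ("glycolysis", "shared"), "cytosol", ()),
    # cytosolic side branches
    ("lactate", "Lactate", 1.500, ("shared",), "cytosol", ()),
    ("alanine", "Alanine", 0.500, ("shared",), "cytosol", ()),
    ("g1p", "Glucose 1-phosphate", 0.060, ("shared",), "cytosol", ()),
    ("g3p", "Glycerol 3-phosphate", 0.160, ("shared",), "cytosol", ()),
    # pentose phosphate pathway
    ("pgl6", "6-phosphogluconolactone", 0.010, ("ppp",), "cytosol", ()),
    ("pgc6", "6-phosphogluconate", 0.020, ("ppp",), "cytosol", ()),
    ("ru5p", "Ribulose 5-phosphate", 0.012, ("ppp",), "cytosol", ()),
    ("r5p", "Ribose 5-phosphate", 0.020, ("ppp",), "cytosol", ()),
    ("x5p", "Xylulose 5-phosphate", 0.020, ("ppp",), "cytosol", ()),
    ("s7p", "Sedoheptulose 7-phosphate", 0.070, ("ppp",), "cytosol", ()),
    ("e4p", "Erythrose 4-phosphate", 0.004, ("ppp",), "cytosol", ()),
    ("prpp", "Phosphoribosyl pyrophosphate", 0.010, ("ppp", "shared"), "cytosol", ()),
    # amino-acid exchange
    ("aspartate", "Aspartate", 0.500, ("shared",), "cytosol", ()),
    ("glutamate", "Glutamate", 3.000, ("shared",), "cytosol", ()),
    ("glutamine", "Glutamine", 4.000, ("shared",), "cytosol", ()),
    # TCA cycle (Table-2 starting concentrations; two lumped queues)
    ("acetyl_coa", "Acetyl-CoA", 0.070, ("tca", "shared"), "mitochondrion", ()),
    ("oxaloacetate", "Oxaloacetate", 0.006, ("tca",), "mitochondrion", ()),
    ("citrate", "Citrate", 0.190, ("tca",), "mitochondrion", ()),
    ("isocitrate_cisaconitate", "Isocitrate cis-aconitate", 0.020, ("tca",),
     "mitochondrion", ("isocitrate", "cis-aconitate")),
    ("alpha_ketoglutarate", "alpha-ketoglutarate", 0.030, ("tca",), "mitochondrion", ()),
    ("succinylcoa_succinate", "Succinyl-CoA succinate", 0.730, ("tca",),
     "mitochondrion", ("succinyl-CoA", "succinate")),
    ("fumarate", "Fumarate", 0.485, ("tca",), "mitochondrion", ()),
    ("malate", "Malate", 0.495, ("tca",), "mitochondrion", ()),
    # beta-oxidation (palmitate, C16)
    ("palmitate", "Palmitate", 0.300, ("beta_oxidation",), "cytosol", ()),
    ("pcoa", "Palmitoyl-CoA", 0.050, ("beta_oxidation",), "cytosol", ()),
    ("pcar", "Palmitoyl-carnitine", 0.030, ("beta_oxidation",), "cytosol", ()),
]
for _n in (16, 14, 12, 10, 8, 6, 4):
    _POOLS += [
        (f"acyl{_n}", f"C{_n} acyl-CoA", 0.020, ("beta_oxidation",), "mitochondrion", ()),
        (f"enoyl{_n}", f"C{_n} enoyl-CoA", 0.010, ("beta_oxidation",), "mitochondrion", ()),
        (f"hacyl{_n}", f"C{_n} 3-hydroxyacyl-CoA", 0.010, ("beta_oxidation",),
         "mitochondrion", ()),
        (f"kacyl{_n}", f"C{_n} 3-ketoacyl-CoA", 0.010, ("beta_oxidation",),
         "mitochondrion", ()),
    ]

# id, enzyme, substrates, products, target initial firing probability per step
_REACTIONS = [
    # glycolysis
    ("hk", "hexokinase", ("glucose",), ("g6p",), 0.050),
    ("pgi", "glucose-6-phosphate isomerase", ("g6p",), ("f6p",), 0.020),
    ("pfk", "phosphofructokinase-1", ("f6p",), ("fbp",), 0.040),
    ("ald", "fructose-bisphosphate aldolase", ("fbp",), ("dhap", "gap"), 0.040),
    ("tpi", "triose-phosphate isomerase", ("dhap",), ("gap",), 0.030),
    ("gapdh", "glyceraldehyde-3-phosphate dehydrogenase", ("gap",), ("bpg13",), 0.080),
    ("pgk", "phosphoglycerate kinase", ("bpg13",), ("pg3",), 0.080),
    ("pgam", "phosphoglycerate mutase", ("pg3",), ("pg2",), 0.080),
    ("eno", "enolase", ("pg2",), ("pep",), 0.080),
    ("pk", "pyruvate kinase", ("pep",), ("pyruvate",), 0.080),
    # cytosolic side branches
    ("pgm1", "phosphoglucomutase", ("g6p",), ("g1p",), 0.010),
    ("g3pdh", "glycerol-3-phosphate dehydrogenase", ("dhap",), ("g3p",), 0.010),
    ("ldh", "lactate dehydrogenase", ("pyruvate",), ("lactate",), 0.010),
    ("alt", "alanine transaminase", ("pyruvate",), ("alanine",), 0.010),
    # pyruvate branch point into the TCA cycle
    ("pdh", "pyruvate dehydrogenase", ("pyruvate",), ("acetyl_coa",), 0.050),
    ("pc", "pyruvate carboxylase", ("pyruvate",), ("oxaloacetate",), 0.020),
    ("me1", "malic enzyme", ("malate",), ("pyruvate",), 0.010),
    # pentose phosphate pathway
    ("g6pd", "glucose-6-phosphate dehydrogenase", ("g6p",), ("pgl6",), 0.020),
    ("pgls", "6-phosphogluconolactonase", ("pgl6",), ("pgc6",), 0.020),
    ("pgd", "6-phosphogluconate dehydrogenase", ("pgc6",), ("ru5p",), 0.020),
    ("rpi", "ribose-5-phosphate isomerase", ("ru5p",), ("r5p",), 0.010),
    ("rpe", "ribulose-5-phosphate epimerase", ("ru5p",), ("x5p",), 0.010),
    ("tkt1", "transketolase", ("r5p", "x5p"), ("s7p", "gap"), 0.010),
    ("tal", "transaldolase", ("s7p", "gap"), ("e4p", "f6p"), 0.010),
    ("tkt2", "transketolase", ("x5p", "e4p"), ("f6p", "gap"), 0.010),
    ("prpps", "PRPP synthetase", ("r5p",), ("prpp",), 0.010),
    # TCA cycle (aconitase and succinyl-CoA synthetase folded into the lumps)
    ("cs", "citrate synthase", ("acetyl_coa", "oxaloacetate"), ("citrate",), 0.095),
    ("acn", "aconitase", ("citrate",), ("isocitrate_cisaconitate",), 0.075),
    ("idh", "isocitrate dehydrogenase", ("isocitrate_cisaconitate",),
     ("alpha_ketoglutarate",), 0.075),
    ("akgdh", "alpha-ketoglutarate dehydrogenase", ("alpha_ketoglutarate",),
     ("succinylcoa_succinate",), 0.085),
    ("sdh", "succinate dehydrogenase", ("succinylcoa_succinate",), ("fumarate",), 0.085),
    ("fh", "fumarase", ("fumarate",), ("malate",), 0.085),
    ("mdh", "malate dehydrogenase", ("malate",), ("oxaloacetate",), 0.075),
    # anaplerosis / cataplerosis
    ("acl", "ATP-citrate lyase", ("citrate",), ("oxaloacetate", "acetyl_coa"), 0.010),
    ("ast", "aspartate transaminase", ("oxaloacetate",), ("aspartate",), 0.010),
    ("gls", "glutaminase", ("glutamine",), ("glutamate",), 0.010),
    ("gdh", "glutamate dehydrogenase", ("glutamate",), ("alpha_ketoglutarate",), 0.010),
    # beta-oxidation entry and carnitine shuttle
    ("acs", "acyl-CoA synthetase", ("palmitate",), ("pcoa",), 0.010),
    ("cpt1", "carnitine palmitoyltransferase I", ("pcoa",), ("pcar",), 0.010),
    ("cpt2", "carnitine palmitoyltransferase II", ("pcar",), ("acyl16",), 0.010),
]
# seven turns of the beta-oxidation spiral; the final thiolysis of
# acetoacetyl-CoA emits a single acetyl-CoA packet (unit stoichiometry)
for _n in (16, 14, 12, 10, 8, 6, 4):
    _prods = (f"acyl{_n - 2}", "acetyl_coa") if _n > 4 else ("acetyl_coa",)
    _REACTIONS += [
        (f"acad{_n}", f"acyl-CoA dehydrogenase (C{_n})",
         (f"acyl{_n}",), (f"enoyl{_n}",), 0.010),
        (f"ech{_n}", f"enoyl-CoA hydratase (C{_n})",
         (f"enoyl{_n}",), (f"hacyl{_n}",), 0.010),
        (f"hadh{_n}", f"3-hydroxyacyl-CoA dehydrogenase (C{_n})",
         (f"hacyl{_n}",), (f"kacyl{_n}",), 0.010),
        (f"thio{_n}", f"3-ketoacyl-CoA thiolase (C{_n})",
         (f"kacyl{_n}",), _prods, 0.010),
    ]

#: pools intentionally left unbalanced (no compensating flow): glucose is the
#: depleting substrate of the experiment
_FLOW_EXEMPT = frozenset({"glucose"})


def build_default_network() -> MetabolicNetwork:
    """Construct the calibrated 68-reaction default network."""
    conc0 = {pid: c for pid, _, c, _, _, _ in _POOLS}
    pools = [
        MetabolitePool(
            id=pid,
            name=name,
            initial_concentration=c,
            packet_size=default_packet_size(c),
            lumped_members=list(members),
            pathway_tags=frozenset(tags),
            compartment=compartment,
        )
        for pid, name, c, tags, compartment, members in _POOLS
    ]
    psize = {p.id: p.packet_size for p in pools}

    reactions = []
    for rid, enzyme, subs, prods, mu0 in _REACTIONS:
        # Michaelis constants at the initial concentrations: every species
        # ratio is 1 at t=0, so the initial velocity is 0.99*Vf/den0
        ks = [conc0[s] for s in subs]
        kp = [conc0[p] for p in prods]
        den0 = 3.0 * (1.0 + (len(subs) == 2) + (len(prods) == 2))
        delta_ref = min(psize[pid] for pid in subs + prods)
        v_target = mu0 * delta_ref / CALIBRATION_DT
        vf = v_target * den0 / 0.99
        law = KineticLaw(
            vf=vf,
            vr=vf / 100.0,
            k_s1=ks[0],
            k_s2=ks[1] if len(ks) == 2 else None,
            k_p1=kp[0],
            k_p2=kp[1] if len(kp) == 2 else None,
        )
        reactions.append(
            Reaction(
                id=rid, enzyme=enzyme, substrates=list(subs), products=list(prods),
                law=law, reverse_defaulted=True,
            )
        )

    # balancing flows absorb each pool's designed residual packet drift
    drift = {pid: 0.0 for pid in conc0}
    for rid, _, subs, prods, mu0 in _REACTIONS:
        for s in subs:
            drift[s] -= mu0
        for p in prods:
            drift[p] += mu0
    flows = []
    for pid in conc0:
        b = drift[pid]
        if pid in _FLOW_EXEMPT or abs(b) < 1e-9:
            continue
        coefficient = -b * psize[pid] / CALIBRATION_DT
        flows.append(
            BalancingFlow(id=f"bal_{pid}", pool_id=pid, coefficient=coefficient,
                          tunable=True)
        )

    return MetabolicNetwork(
        pools=pools,
        reactions=reactions,
        flows=flows,
        name="default-energy-metabolism",
        version="approximate-1",
    ).validate()


def default_network_path():
    """Path of the bundled TOML serialization of the default network."""
    from importlib import resources

    return resources.files("queuemet.data") / "default_network.toml"


def tca_reference_concentrations() -> dict[str, float]:
    """Literature starting concentrations of the TCA queues (mmol/L)."""
    net = build_default_network()
    return {pid: net.pool(pid).initial_concentration for pid in TCA_POOL_IDS}


def initial_mu_table(network: MetabolicNetwork, dt: float = CALIBRATION_DT):
    """Initial firing probability of every reaction and flow (diagnostic)."""
    from .engine import CompiledNetwork

    compiled = CompiledNetwork(network)
    v = compiled.rates(compiled.conc0[None, :])[0]
    mu_r = np.abs(v) * dt / compiled.psize_ref
    mu_f = np.abs(compiled.fcoeff) * dt / compiled.psize[compiled.flow_pool]
    return dict(zip(compiled.event_ids, np.concatenate([mu_r, mu_f])))
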