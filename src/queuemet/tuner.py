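"""Genetic-algorithm calibration of kinetic constants and balancing flows.

A chromosome is a vector of positive multipliers on the seeded network's
table — one gene per reaction forward velocity, one per reverse velocity and
one per tunable balancing-flow coefficient.  Evaluating a chromosome means
simulating the parametrized network and scoring it with a composite loss:

* a literature term: the sum of squared relative distances between the
  per-second sampled concentrations and the literature reference vector,
  g_p = sum_i ((Xhat_i - X_i) / X_i)^2, and
* a stability term: the mean absolute difference between the average of the
  last 100 recordings and the initial concentrations.

A trivial global minimum exists (zero every rate and nothing moves), so
reproduction enforces that every reaction and flow has an initial firing
probability between 1% and 10%; violating genes are repaired by resampling.
Selection is elitist truncation (the best 10 of 100 reproduce), children are
uniform crossovers of random elite pairs, and each gene mutates with 10%
probability by a Gaussian perturbation of amplitude 1.0 (scaled to 10% of
the gene's bound width).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import CompiledNetwork, SimulationConfig, TimeSeries, run_batch
from .errors import SeriesTooShort, ZeroReferenceEntry
from .network import MetabolicNetwork


@dataclass
class GAConfig:
    population_size: int = 100
    elite_count: int = 10
    mutation_probability: float = 0.10
    mutation_amplitude: float = 1.0
    generations: int = 30
    evaluation_duration: float = 3600.0  # s of simulation per evaluation
    min_initial_probability: float = 0.01
    max_initial_probability: float = 0.10
    gene_bounds: tuple[float, float] = (0.2, 5.0)  # multipliers on the seed table
    stability_tail: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.elite_count < self.population_size:
            raise ValueError("need 0 < elite_count < population_size")
        if not 0 < self.min_initial_probability < self.max_initial_probability < 1:
            raise ValueError("need 0 < min < max < 1 for initial probabilities")
        if not self.gene_bounds[0] < self.gene_bounds[1]:
            raise ValueError("gene bounds must be ordered")


@dataclass
class Chromosome:
    """Candidate multiplier table; gene layout [vf (R) | vr (R) | flows (F)]."""

    genes: np.ndarray
    low: np.ndarray
    high: np.ndarray
    fitness: float | None = None

    def validate_bounds(self) -> bool:
        return bool((self.genes >= self.low).all() and (self.genes <= self.high).all())


@dataclass
class ProbabilityCheck:
    passed: bool
    violators: list[tuple[str, float]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# loss functions


def loss_literature(simulated, reference) -> float:
    """Sum of squared relative deviations from the literature vector."""
    sim = np.asarray(simulated, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if sim.shape[-1] != ref.shape[-1]:
        raise ValueError("simulated and reference lengths differ")
    if (ref == 0).any():
        raise ZeroReferenceEntry("reference concentrations must be nonzero")
    return float(np.sum(((sim - ref) / ref) ** 2))


def loss_stability(series: TimeSeries, initial, tail: int = 100) -> float:
    """Mean |average of the last `tail` recordings - initial concentration|."""
    conc = series.concentrations
    if conc.shape[0] < tail:
        raise SeriesTooShort(f"series has {conc.shape[0]} rows, tail is {tail}")
    initial = np.asarray(initial, dtype=float)
    return float(np.mean(np.abs(conc[-tail:].mean(axis=0) - initial)))


# ---------------------------------------------------------------------------
# the tuning problem


class _Problem:
    """Precompiled arrays mapping genes to constants and initial probabilities."""

    def __init__(
        self,
        network: MetabolicNetwork,
        sim_config: SimulationConfig,
        ga_config: GAConfig,
        reference: dict[str, float],
    ):
        self.compiled = CompiledNetwork(network)
        self.sim_config = sim_config
        self.ga = ga_config
        c = self.compiled
        self.R, self.F = c.n_reactions, c.n_flows
        # genes cover every reaction's Vf and Vr plus the *tunable* flows only
        self.tunable_idx = np.array(
            [k for k, f in enumerate(network.flows) if f.tunable], dtype=np.intp
        )
        self.Ft = len(self.tunable_idx)
        self.n_genes = 2 * self.R + self.Ft
        self.low = np.full(self.n_genes, ga_config.gene_bounds[0])
        self.high = np.full(self.n_genes, ga_config.gene_bounds[1])

        # linearization of the initial firing probability in the genes:
        # mu_j(g) = |a_j * g_vf - b_j * g_vr|, flow mu_k = base_k * g_k
        conc0 = c.conc0[None, :]
        rs1 = conc0[:, c.s1] / c.ks1
        rp1 = conc0[:, c.p1] / c.kp1
        rs2 = np.where(c.has_s2, conc0[:, c.s2] / c.ks2, 1.0)
        rp2 = np.where(c.has_p2, conc0[:, c.p2] / c.kp2, 1.0)
        den = (1.0 + rs1 + rp1) * (
            1.0 + np.where(c.has_s2, rs2, 0.0) + np.where(c.has_p2, rp2, 0.0)
        )
        scale = sim_config.dt / c.psize_ref
        self._a = (c.vf * (rs1 * rs2) / den)[0] * scale
        self._b = (c.vr * (rp1 * rp2) / den)[0] * scale
        flow_mu_all = np.abs(c.fcoeff) * sim_config.dt / c.psize[c.flow_pool]
        self._flow_base = flow_mu_all[self.tunable_idx]
        self._flow_mu_fixed = np.delete(flow_mu_all, self.tunable_idx)
        self._fixed_flow_ids = [
            network.flows[k].id for k in range(self.F) if k not in set(self.tunable_idx)
        ]

        ref_ids = sorted(reference)
        self.ref_idx = np.array([c.index[pid] for pid in ref_ids], dtype=np.intp)
        self.ref = np.array([reference[pid] for pid in ref_ids])
        if (self.ref == 0).any():
            raise ZeroReferenceEntry("reference concentrations must be nonzero")

        # per-second sampling rows of the recorded series
        mps = sim_config.measurements_per_second
        rows = int(np.floor(ga_config.evaluation_duration * mps))
        if rows < ga_config.stability_tail:
            raise SeriesTooShort(
                f"evaluation records {rows} rows, stability tail needs "
                f"{ga_config.stability_tail}"
            )
        self.eval_config = SimulationConfig(
            duration=ga_config.evaluation_duration,
            dt=sim_config.dt,
            cells=1,
            measurements_per_second=mps,
            seed=sim_config.seed,
            mu_threshold=sim_config.mu_threshold,
        )
        per_second = max(1, int(round(mps)))
        self.second_rows = np.arange(per_second - 1, rows, per_second)

    # -- gene decoding -------------------------------------------------------

    def split(self, genes: np.ndarray):
        R = self.R
        return genes[..., :R], genes[..., R : 2 * R], genes[..., 2 * R :]

    def initial_mu(self, genes: np.ndarray) -> np.ndarray:
        g_vf, g_vr, g_fl = self.split(genes)
        mu_r = np.abs(self._a * g_vf - self._b * g_vr)
        return np.concatenate([mu_r, self._flow_base * g_fl], axis=-1)

    def check(self, genes: np.ndarray) -> ProbabilityCheck:
        mu = self.initial_mu(genes)
        lo, hi = self.ga.min_initial_probability, self.ga.max_initial_probability
        tunable_ids = [self.compiled.event_ids[j] for j in range(self.R)] + [
            self.compiled.event_ids[self.R + k] for k in self.tunable_idx
        ]
        bad = (mu < lo) | (mu > hi)
        violators = [(tunable_ids[e], float(mu[e])) for e in np.nonzero(bad)[0]]
        # fixed flows are part of the constraint too, though not repairable
        violators += [
            (fid, float(m))
            for fid, m in zip(self._fixed_flow_ids, self._flow_mu_fixed)
            if not lo <= m <= hi
        ]
        return ProbabilityCheck(passed=not violators, violators=violators)

    def repair(self, genes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Resample genes whose event violates the 1-10% band; mu_j depends
        only on that event's own genes, so one pass per event converges."""
        lo, hi = self.ga.min_initial_probability, self.ga.max_initial_probability
        target = 0.5 * (lo + hi)
        out = genes.copy()
        g_vf, g_vr, g_fl = self.split(out)
        mu_r = np.abs(self._a * g_vf - self._b * g_vr)
        for j in np.nonzero((mu_r < lo) | (mu_r > hi))[0]:
            for _ in range(30):
                g_vf[j] = self.low[j] + (self.high[j] - self.low[j]) * rng.random()
                mu = abs(self._a[j] * g_vf[j] - self._b[j] * g_vr[j])
                if lo <= mu <= hi:
                    break
            else:
                if self._a[j] > 0:
                    g_vf[j] = np.clip(
                        (target + self._b[j] * g_vr[j]) / self._a[j],
                        self.low[j], self.high[j],
                    )
        if self.Ft:
            mu_f = self._flow_base * g_fl
            for k in np.nonzero((mu_f < lo) | (mu_f > hi))[0]:
                if self._flow_base[k] > 0:
                    g_fl[k] = np.clip(
                        target / self._flow_base[k],
                        self.low[2 * self.R + k], self.high[2 * self.R + k],
                    )
        return out

    # -- evaluation ----------------------------------------------------------

    def evaluate_batch(
        self, genes: np.ndarray, rng: np.random.Generator
    ) -> np.ndarray:
        """Composite fitness for a (population x genes) matrix in one run."""
        P = genes.shape[0]
        g_vf, g_vr, g_fl = self.split(genes)
        c = self.compiled
        fcoeff = None
        if self.F:
            fcoeff = np.tile(c.fcoeff, (P, 1))
            if self.Ft:
                fcoeff[:, self.tunable_idx] *= g_fl
        _, recorded, _ = run_batch(
            c,
            self.eval_config,
            rng,
            cells=P,
            vf=c.vf * g_vf,
            vr=c.vr * g_vr,
            fcoeff=fcoeff,
        )
        sampled = recorded[:, self.second_rows][:, :, self.ref_idx]
        lit = np.sum(((sampled - self.ref) / self.ref) ** 2, axis=(1, 2))
        tail = self.ga.stability_tail
        stab = np.mean(
            np.abs(recorded[:, -tail:, :].mean(axis=1) - c.conc0), axis=1
        )
        return lit + stab


# ---------------------------------------------------------------------------
# public operations


def initial_probability_check(
    network: MetabolicNetwork,
    chromosome: Chromosome,
    sim_config: SimulationConfig,
    ga_config: GAConfig | None = None,
    reference: dict[str, float] | None = None,
) -> ProbabilityCheck:
    """Verify every reaction and flow starts in the 1-10% probability band."""
    reference = reference or _default_reference(network)
    problem = _Problem(network, sim_config, ga_config or GAConfig(), reference)
    return problem.check(chromosome.genes)


def _default_reference(network: MetabolicNetwork) -> dict[str, float]:
    return {
        p.id: p.initial_concentration
        for p in network.pools
        if p.initial_concentration > 0
    }


def _chromosome_seed(ga_seed: int, generation: int, index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=ga_seed, spawn_key=(generation, index))
    )


def evaluate_chromosome(
    chromosome: Chromosome,
    network: MetabolicNetwork,
    sim_config: SimulationConfig,
    ga_config: GAConfig,
    reference: dict[str, float],
    generation: int = 0,
    index: int = 0,
) -> float:
    """Fitness of one chromosome; deterministic given (seed, generation, index).

    Chromosomes violating the initial-probability constraint receive infinite
    fitness without simulation.
    """
    problem = _Problem(network, sim_config, ga_config, reference)
    if not problem.check(chromosome.genes).passed:
        chromosome.fitness = float("inf")
        return chromosome.fitness
    rng = _chromosome_seed(ga_config.seed, generation, index)
    fitness = float(problem.evaluate_batch(chromosome.genes[None, :], rng)[0])
    chromosome.fitness = fitness
    return fitness


def evolve(
    network: MetabolicNetwork,
    sim_config: SimulationConfig,
    ga_config: GAConfig,
    reference: dict[str, float],
    rng: np.random.Generator | None = None,
    return_population: bool = False,
) -> tuple[Chromosome, pd.DataFrame] | tuple[Chromosome, pd.DataFrame, np.ndarray]:
    """Run the GA; returns the best chromosome and the fitness trace.

    Elites carry their evaluated fitness unchanged into the next generation,
    so the per-generation best fitness is non-increasing.  With
    ``generations = 0`` the initial population is evaluated once and its best
    member returned (the trace has a single row).
    """
    rng = np.random.default_rng(ga_config.seed) if rng is None else rng
    problem = _Problem(network, sim_config, ga_config, reference)
    P, G = ga_config.population_size, problem.n_genes
    low, high = problem.low, problem.high

    pop = low + (high - low) * rng.random((P, G))
    pop[0] = 1.0  # the incumbent seeded table is always in the initial population
    pop = np.stack([problem.repair(row, rng) for row in pop])
    fitness = problem.evaluate_batch(
        pop, _chromosome_seed(ga_config.seed, 0, 0)
    )
    trace_rows = []
    for gen in range(ga_config.generations + 1):
        trace_rows.append(
            {
                "generation": gen,
                "best": float(fitness.min()),
                "median": float(np.median(fitness)),
            }
        )
        if gen == ga_config.generations:
            break
        order = np.argsort(fitness)
        elite, elite_fit = pop[order[: ga_config.elite_count]], fitness[
            order[: ga_config.elite_count]
        ]
        n_children = P - ga_config.elite_count
        parents = rng.integers(0, ga_config.elite_count, size=(n_children, 2))
        mix = rng.random((n_children, G)) < 0.5
        children = np.where(mix, elite[parents[:, 0]], elite[parents[:, 1]])
        mutate = rng.random(children.shape) < ga_config.mutation_probability
        noise = rng.standard_normal(children.shape) * (
            ga_config.mutation_amplitude * 0.10 * (high - low)
        )
        children = np.clip(children + mutate * noise, low, high)
        children = np.stack([problem.repair(row, rng) for row in children])
        child_fit = problem.evaluate_batch(
            children, _chromosome_seed(ga_config.seed, gen + 1, 0)
        )
        pop = np.concatenate([elite, children], axis=0)
        fitness = np.concatenate([elite_fit, child_fit])

    best_i = int(np.argmin(fitness))
    best = Chromosome(
        genes=pop[best_i].copy(), low=low, high=high, fitness=float(fitness[best_i])
    )
    trace = pd.DataFrame(trace_rows)
    if return_population:
        return best, trace, pop
    return best, trace


def apply_chromosome(
    network: MetabolicNetwork, chromosome: Chromosome
) -> MetabolicNetwork:
    """Return a copy of the network with the chromosome's multipliers applied."""
    import copy

    out = copy.deepcopy(network)
    R = len(out.reactions)
    tunable = [f for f in out.flows if f.tunable]
    g = chromosome.genes
    if len(g) != 2 * R + len(tunable):
        raise ValueError(
            f"chromosome has {len(g)} genes, network needs {2 * R + len(tunable)}"
        )
    for j, rxn in enumerate(out.reactions):
        rxn.law.vf *= float(g[j])
        rxn.law.vr *= float(g[R + j])
    for k, flow in enumerate(tunable):
        flow.coefficient *= float(g[2 * R + k])
    return out


def write_fitness_trace(trace: pd.DataFrame, path: str | Path) -> None:
    trace.to_csv(path, index=False, float_format="%.6g")
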