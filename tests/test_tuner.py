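"""GA calibration: losses, the 1-10% constraint, elitism and degeneracies."""

import numpy as np
import pytest

from queuemet.engine import SimulationConfig, TimeSeries
from queuemet.errors import SeriesTooShort, ZeroReferenceEntry
from queuemet.fixtures import make_fixture
from queuemet.tuner import (
    Chromosome,
    GAConfig,
    _Problem,
    apply_chromosome,
    evaluate_chromosome,
    evolve,
    initial_probability_check,
    loss_literature,
    loss_stability,
)


def _series(matrix, pool_ids):
    matrix = np.asarray(matrix, dtype=float)
    return TimeSeries(
        times=np.arange(1, matrix.shape[0] + 1.0),
        concentrations=matrix,
        pool_ids=pool_ids,
    )


class TestLossLiterature:
    def test_perfect_match(self):
        assert loss_literature([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_hand_values(self):
        assert loss_literature([2.0, 3.0], [1.0, 2.0]) == pytest.approx(1.25)
        assert loss_literature([2.0], [4.0]) == pytest.approx(0.25)

    def test_zero_reference_rejected(self):
        with pytest.raises(ZeroReferenceEntry):
            loss_literature([1.0], [0.0])

    def test_strictly_positive_unless_equal(self):
        assert loss_literature([1.0, 2.00001], [1.0, 2.0]) > 0.0


class TestLossStability:
    def test_constant_series(self):
        series = _series(np.tile([1.0, 2.0], (150, 1)), ["a", "b"])
        assert loss_stability(series, [1.0, 2.0]) == 0.0

    def test_uniform_offset(self):
        series = _series(np.tile([1.1, 2.1], (150, 1)), ["a", "b"])
        assert loss_stability(series, [1.0, 2.0]) == pytest.approx(0.1)

    def test_too_short(self):
        series = _series(np.ones((50, 2)), ["a", "b"])
        with pytest.raises(SeriesTooShort):
            loss_stability(series, [1.0, 1.0], tail=100)


class TestInitialProbabilityCheck:
    def _setup(self):
        net = make_fixture("planted_steady_state", 3)  # every mu0 = 0.05
        sim = SimulationConfig(duration=30.0, seed=0)
        ga = GAConfig(population_size=10, elite_count=2, generations=1,
                      evaluation_duration=30.0)
        problem = _Problem(net, sim, ga, {"p1": 1.0, "p2": 1.0, "p3": 1.0})
        return net, sim, ga, problem

    def test_interior_point_passes(self):
        net, sim, ga, problem = self._setup()
        genes = np.ones(problem.n_genes)
        chromo = Chromosome(genes, problem.low, problem.high)
        assert initial_probability_check(net, chromo, sim, ga).passed

    def test_below_floor_fails_named(self):
        net, sim, ga, problem = self._setup()
        genes = np.ones(problem.n_genes)
        genes[0] = 0.1  # drives r1's initial mu to ~0.005
        problem.low[0] = 0.05  # permit the low gene for this check
        check = problem.check(genes)
        assert not check.passed
        assert check.violators[0][0] == "r1"
        assert check.violators[0][1] < 0.01

    def test_above_ceiling_fails(self):
        net, sim, ga, problem = self._setup()
        genes = np.ones(problem.n_genes)
        genes[0] = 4.0  # mu ~ 0.2
        check = problem.check(genes)
        assert not check.passed
        assert any(mu > 0.10 for _, mu in check.violators)

    def test_repair_restores_band(self, rng):
        net, sim, ga, problem = self._setup()
        genes = problem.low + (problem.high - problem.low) * rng.random(
            (50, problem.n_genes)
        )
        for row in genes:
            repaired = problem.repair(row, rng)
            assert problem.check(repaired).passed


class TestEvaluation:
    def test_steady_state_scores_near_zero(self):
        net = make_fixture("planted_steady_state", 3)
        sim = SimulationConfig(duration=30.0, seed=1)
        ga = GAConfig(population_size=10, elite_count=2, generations=0,
                      evaluation_duration=30.0)
        reference = {p.id: p.initial_concentration for p in net.pools}
        problem = _Problem(net, sim, ga, reference)
        chromo = Chromosome(np.ones(problem.n_genes), problem.low, problem.high)
        fitness = evaluate_chromosome(chromo, net, sim, ga, reference)
        assert fitness < 1e-2 * 30 * 3  # tiny Monte-Carlo noise only

    def test_constraint_violation_is_infinite_without_simulation(self):
        net = make_fixture("planted_steady_state", 3)
        sim = SimulationConfig(duration=30.0, seed=1)
        ga = GAConfig(population_size=10, elite_count=2, generations=0,
                      evaluation_duration=30.0)
        reference = {p.id: p.initial_concentration for p in net.pools}
        problem = _Problem(net, sim, ga, reference)
        genes = np.full(problem.n_genes, 5.0)  # saturated: mu far above 10%
        chromo = Chromosome(genes, problem.low, problem.high)
        assert evaluate_chromosome(chromo, net, sim, ga, reference) == np.inf

    def test_closer_match_scores_lower(self):
        assert loss_literature([1.1, 2.2], [1.0, 2.0]) < loss_literature(
            [1.2, 2.4], [1.0, 2.0]
        )

    def test_deterministic_given_seed(self):
        net = make_fixture("planted_steady_state", 2)
        sim = SimulationConfig(duration=25.0, seed=8)
        ga = GAConfig(population_size=10, elite_count=2, generations=0,
                      evaluation_duration=25.0)
        reference = {p.id: p.initial_concentration for p in net.pools}
        problem = _Problem(net, sim, ga, reference)
        chromo = Chromosome(np.ones(problem.n_genes), problem.low, problem.high)
        f1 = evaluate_chromosome(chromo, net, sim, ga, reference, 2, 5)
        f2 = evaluate_chromosome(chromo, net, sim, ga, reference, 2, 5)
        assert f1 == f2


class TestEvolve:
    def _run(self, generations, seed=0, mutation=0.10, elite=3, pop=12):
        net = make_fixture("planted_steady_state", 2)
        sim = SimulationConfig(duration=25.0, seed=seed)
        ga = GAConfig(
            population_size=pop, elite_count=elite, generations=generations,
            evaluation_duration=25.0, mutation_probability=mutation, seed=seed,
        )
        reference = {p.id: p.initial_concentration for p in net.pools}
        return net, sim, ga, reference

    def test_trace_non_increasing(self):
        net, sim, ga, ref = self._run(generations=6)
        best, trace = evolve(net, sim, ga, ref)
        assert (np.diff(trace["best"].to_numpy()) <= 1e-12).all()
        assert best.fitness == pytest.approx(trace["best"].iloc[-1])

    def test_zero_generations_returns_initial_best(self):
        net, sim, ga, ref = self._run(generations=0)
        best, trace = evolve(net, sim, ga, ref)
        assert len(trace) == 1
        assert best.fitness is not None

    def test_population_respects_constraint_after_reproduction(self):
        net, sim, ga, ref = self._run(generations=4)
        problem = _Problem(net, sim, ga, ref)
        # re-run evolution and spot-check the best member of every generation
        best, trace = evolve(net, sim, ga, ref)
        assert problem.check(best.genes).passed
        assert best.validate_bounds()

    def test_no_mutation_single_elite_converges_to_clones(self):
        net = make_fixture("planted_steady_state", 2)
        sim = SimulationConfig(duration=25.0, seed=3)
        ga = GAConfig(
            population_size=8, elite_count=1, generations=3,
            evaluation_duration=25.0, mutation_probability=0.0, seed=3,
        )
        ref = {p.id: p.initial_concentration for p in net.pools}
        best, _, pop = evolve(net, sim, ga, ref, return_population=True)
        assert all(np.array_equal(row, best.genes) for row in pop)

    def test_apply_chromosome_scales_constants(self):
        net = make_fixture("planted_steady_state", 2)
        R = len(net.reactions)
        genes = np.array([2.0] * R + [3.0] * R)  # flows are not tunable here
        chromo = Chromosome(genes, np.full(2 * R, 0.2), np.full(2 * R, 5.0))
        tuned = apply_chromosome(net, chromo)
        for before, after in zip(net.reactions, tuned.reactions):
            assert after.law.vf == pytest.approx(2.0 * before.law.vf)
            assert after.law.vr == pytest.approx(3.0 * before.law.vr)
        assert tuned.flows[0].coefficient == net.flows[0].coefficient

    def test_config_validation(self):
        with pytest.raises(ValueError):
            GAConfig(population_size=5, elite_count=5)
        with pytest.raises(ValueError):
            GAConfig(min_initial_probability=0.2, max_initial_probability=0.1)
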