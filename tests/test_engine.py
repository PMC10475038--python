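"""Queueing engine: normalization, time-step condition, stepping, recording."""

import numpy as np
import pytest

from queuemet.engine import (
    CompiledNetwork,
    QueueState,
    SimulationConfig,
    normalize_rate,
    perturb_constants,
    run_batch,
    sd_over_mean_90p,
    simulate,
    simulate_ensemble,
    step,
    validate_timestep,
    TimeSeries,
)
from queuemet.errors import DegenerateSeries, TimestepConditionViolated
from queuemet.fixtures import make_fixture

from tests.conftest import constant_arrival_network, uni_uni_network


class TestNormalizeRate:
    def test_arrival(self):
        mu, role = normalize_rate(0.002, dt=0.01, packet_size=0.001)
        assert mu == pytest.approx(0.02)
        assert role == "arrival"

    def test_zero(self):
        mu, _ = normalize_rate(0.0, dt=0.01, packet_size=0.001)
        assert mu == 0.0

    def test_service(self):
        mu, role = normalize_rate(-0.001, dt=0.01, packet_size=0.001)
        assert mu == pytest.approx(0.01)
        assert role == "service"


class TestValidateTimestep:
    def test_below_threshold_passes(self):
        net = make_fixture("planted_steady_state", 2)  # mu0 = 0.05 everywhere
        report = validate_timestep(net, SimulationConfig(duration=1.0, dt=0.01))
        assert report.passed
        assert report.max_mu == pytest.approx(0.05, rel=1e-6)

    def test_scaling_dt_by_ten_fails(self):
        net = make_fixture("planted_steady_state", 2)
        report = validate_timestep(net, SimulationConfig(duration=1.0, dt=0.1))
        assert not report.passed
        assert report.max_mu == pytest.approx(0.5, rel=1e-6)
        assert len(report.violators) > 0

    def test_empty_reaction_set(self):
        from queuemet.network import MetabolicNetwork, MetabolitePool

        net = MetabolicNetwork(
            [MetabolitePool("a", "A", 1.0, 0.001)], []
        ).validate()
        report = validate_timestep(net, SimulationConfig(duration=1.0))
        assert report.passed
        assert report.max_mu == 0.0

    def test_simulate_refuses_on_violation(self):
        net = make_fixture("planted_steady_state", 2)
        with pytest.raises(TimestepConditionViolated):
            simulate(net, SimulationConfig(duration=1.0, dt=0.1, seed=0))


class TestStep:
    def test_zero_rate_never_fires(self, rng):
        net = uni_uni_network(vf=0.0, vr=0.0)
        state = QueueState({"a": 1000, "b": 0})
        config = SimulationConfig(duration=1.0)
        for _ in range(50):
            state, outcome = step(net, state, config, rng)
            assert not outcome.fired
        assert state.packet_counts == {"a": 1000, "b": 0}

    def test_closed_pair_conserves_packets(self, rng):
        net = make_fixture("closed_cycle", 2)
        state = QueueState({"p1": 1000, "p2": 1000})
        config = SimulationConfig(duration=1.0)
        for _ in range(200):
            state, outcome = step(net, state, config, rng)
            assert sum(state.packet_counts.values()) == 2000
            assert not (outcome.fired & outcome.skipped_underflow)

    def test_time_advances_by_dt(self, rng):
        net = uni_uni_network()
        state = QueueState({"a": 10, "b": 0}, time=0.0)
        state, _ = step(net, state, SimulationConfig(duration=1.0, dt=0.25), rng)
        assert state.time == pytest.approx(0.25)


class TestFiringStatistics:
    def test_binomial_mean_of_constant_rate(self, rng):
        # constant arrival with mu = 0.02 over n = 10,000 steps
        net = constant_arrival_network(mu=0.02)
        compiled = CompiledNetwork(net)
        config = SimulationConfig(duration=100.0, dt=0.01, measurements_per_second=1)
        _, recorded, _ = run_batch(compiled, config, rng, cells=1)
        n, mu = 10_000, 0.02
        fired = (recorded[0, -1, 0] - 1.0) / 0.001
        assert abs(fired - n * mu) <= 3 * np.sqrt(n * mu * (1 - mu))

    def test_firing_counts_match_poisson(self, rng):
        # counts over cells ~ Binomial(n, mu) ~ Poisson(n mu) in the small-mu
        # limit; chi-square goodness of fit at alpha = 0.01
        from scipy import stats

        net = constant_arrival_network(mu=0.02)
        compiled = CompiledNetwork(net)
        config = SimulationConfig(duration=20.0, dt=0.01, measurements_per_second=1)
        _, recorded, _ = run_batch(compiled, config, rng, cells=400)
        counts = np.round((recorded[:, -1, 0] - 1.0) / 0.001).astype(int)
        lam = 2000 * 0.02
        edges = [0, 30, 34, 37, 40, 43, 46, 50, 1000]
        observed = np.histogram(counts, bins=edges)[0]
        cdf = stats.poisson(lam).cdf
        expected = np.diff([cdf(e - 1) for e in edges]) * len(counts)
        chi2 = ((observed - expected) ** 2 / expected).sum()
        pvalue = stats.chi2(len(observed) - 1).sf(chi2)
        assert pvalue > 0.01

    def test_interfiring_gaps_exponential(self, rng):
        # gaps of a constant-probability event follow the exponential law
        # implied by the per-step probability (KS at alpha = 0.01)
        from scipy import stats

        mu, dt = 0.05, 0.01
        net = constant_arrival_network(mu=mu, dt=dt)
        compiled = CompiledNetwork(net)
        config = SimulationConfig(
            duration=1300.0, dt=dt, measurements_per_second=1 / dt
        )
        _, recorded, _ = run_batch(compiled, config, rng, cells=1)
        counts = np.round((recorded[0, :, 0] - 1.0) / 0.001)
        fire_steps = np.nonzero(np.diff(counts, prepend=1000.0) > 0)[0]
        # a k-step gap corresponds to the exponential mass on ((k-1)dt, k dt);
        # uniform placement inside that interval removes the grid discreteness
        gap_steps = np.diff(fire_steps)
        gaps = (gap_steps - 1 + rng.random(len(gap_steps))) * dt
        assert len(gaps) >= 5000
        rate = -np.log(1 - mu) / dt
        result = stats.kstest(gaps, "expon", args=(0, 1 / rate))
        assert result.pvalue > 0.01


class TestSimulate:
    def test_cadence_row_count(self):
        net = make_fixture("closed_cycle", 3)
        ts = simulate(net, SimulationConfig(duration=1.0, seed=1))
        assert ts.concentrations.shape[0] == 5

    def test_conservation_in_closed_cycle(self):
        net = make_fixture("closed_cycle", 3)
        ts = simulate(net, SimulationConfig(duration=50.0, seed=2))
        totals = np.round(ts.concentrations.sum(axis=1) / 0.001)
        assert (totals == 3000).all()

    def test_determinism_under_seed(self):
        net = make_fixture("branch_competition", 3)
        cfg = SimulationConfig(duration=20.0, seed=42)
        a = simulate(net, cfg)
        b = simulate(net, cfg)
        assert np.array_equal(a.concentrations, b.concentrations)

    def test_nonnegative_even_under_heavy_drain(self):
        # the tiny source queue of branch_competition empties repeatedly
        net = make_fixture("branch_competition", 4)
        ts = simulate(net, SimulationConfig(duration=100.0, seed=3))
        assert (ts.concentrations >= 0).all()

    def test_ensemble_mean_matches_ode_oracle(self, rng):
        # ensemble mean of the uni-uni toy against a fine explicit-Euler
        # integration of the deterministic rate law (dt/100)
        net = uni_uni_network(vf=0.004, vr=0.0, s0=1.0, p0=0.1)
        cells = 60
        config = SimulationConfig(
            duration=100.0, dt=0.01, cells=cells, measurements_per_second=1, seed=9
        )
        mean, per_cell = simulate_ensemble(net, config)

        h = 0.0001
        a, b = 1.0, 0.1
        ode = []
        for i in range(int(100.0 / h)):
            v = (0.004 * a / 1.0) / (1 + a / 1.0 + b / 1.0)
            a, b = a - h * v, b + h * v
            if (i + 1) % int(1.0 / h) == 0:
                ode.append(a)
        ode = np.array(ode)
        sim = mean.column("a")
        spread = np.std([ts.column("a") for ts in per_cell], axis=0, ddof=1)
        mc_se = spread / np.sqrt(cells)
        for idx in (9, 49, 99):
            assert abs(sim[idx] - ode[idx]) <= 3 * max(mc_se[idx], 1e-9)

    def test_ensemble_of_one_equals_single_cell(self):
        net = make_fixture("closed_cycle", 3)
        cfg = SimulationConfig(duration=5.0, cells=1, seed=7)
        mean, per_cell = simulate_ensemble(net, cfg)
        assert len(per_cell) == 1
        assert np.array_equal(mean.concentrations, per_cell[0].concentrations)

    def test_ensemble_mean_variance_shrinks(self, rng):
        # var of the ensemble mean ~ 1/cells: log-log slope ~ -1 +- 0.3
        net = uni_uni_network(vf=0.004, vr=0.0)
        variances = []
        sizes = [5, 20, 80]
        for cells in sizes:
            finals = []
            for rep in range(12):
                cfg = SimulationConfig(
                    duration=20.0, cells=cells, measurements_per_second=1,
                    seed=1000 + 97 * cells + rep,
                )
                mean, _ = simulate_ensemble(net, cfg)
                finals.append(mean.column("b")[-1])
            variances.append(np.var(finals, ddof=1))
        slope = np.polyfit(np.log(sizes), np.log(variances), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.3)


class TestPerturbConstants:
    def test_zero_cv_is_identity(self, rng, toy_uni_uni):
        assert perturb_constants(toy_uni_uni, 0.0, rng) == toy_uni_uni

    def test_determinism_under_seed(self, toy_uni_uni):
        a = perturb_constants(toy_uni_uni, 0.1, np.random.default_rng(5))
        b = perturb_constants(toy_uni_uni, 0.1, np.random.default_rng(5))
        assert a == b
        assert a != toy_uni_uni

    def test_sample_cv_matches_target(self, rng, toy_uni_uni):
        draws = np.array(
            [
                perturb_constants(toy_uni_uni, 0.1, rng).reactions[0].law.vf
                for _ in range(10_000)
            ]
        )
        cv = draws.std() / draws.mean()
        assert cv == pytest.approx(0.1, abs=0.01)

    def test_initial_noise(self, rng, toy_uni_uni):
        out = perturb_constants(toy_uni_uni, 0.0, rng, initial_cv=0.2)
        assert out.pool("a").initial_concentration != 1.0


class TestSdOverMean:
    def _series(self, values):
        values = np.asarray(values, dtype=float)
        return TimeSeries(
            times=np.arange(1, len(values) + 1.0),
            concentrations=values[:, None],
            pool_ids=["x"],
        )

    def test_constant_trace_is_zero(self):
        assert sd_over_mean_90p(self._series(np.ones(500)), "x", window=50) == 0.0

    def test_percentile_below_max_with_spike(self):
        trace = np.ones(2000)
        trace[1000] = 25.0
        series = self._series(trace)
        stat = sd_over_mean_90p(series, "x", window=100)
        sds = (
            np.lib.stride_tricks.sliding_window_view(trace, 100).std(axis=1, ddof=1)
            / trace.mean()
        )
        assert stat < sds.max()

    def test_iid_normal_oracle(self, rng):
        trace = 1.0 + 0.05 * rng.standard_normal(20_000)
        stat = sd_over_mean_90p(self._series(trace), "x", window=100)
        assert stat == pytest.approx(0.05, rel=0.2)

    def test_zero_mean_rejected(self):
        with pytest.raises(DegenerateSeries):
            sd_over_mean_90p(self._series(np.zeros(500)), "x", window=50)
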