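"""Queueing / kinetic-Monte-Carlo simulation core.

Concentrations are quantized into per-pool packets Delta(C_i); every
reaction's instantaneous Michaelis-Menten velocity is normalized into a
per-time-step firing probability

    mu = |v| * dt / Delta(C)      (arrival when v moves packets in,
                                   service when it moves packets out)

and the state advances on a constant global time step: each reaction and
balancing flow fires independently as a Bernoulli trial with probability mu
(the small-mu regime makes firing counts Poisson and inter-firing gaps
exponential, which is the queueing-theory backing of the scheme).  A firing
moves one packet out of every substrate pool and one packet into every
product pool; firings are applied in a uniformly random order and any firing
that would drive a pool negative is skipped, so counts are non-negative by
construction, never by clamping.

The engine is batch-vectorized: an ensemble of independent cells (or a GA
population with per-cell constants) is stepped as one (cells x events) array.
The batched update applies all of a step's firings at once whenever the
pre-step counts can cover the total demanded consumption — in that regime
every application order yields the same state, so the batch is exactly the
sequential semantics; otherwise the affected cell is replayed sequentially
in a uniformly random order with underflow skipping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateSeries, TimestepConditionViolated
from .network import MetabolicNetwork

_EPS_POSITIVE = 1e-6  # keeps noisy constants strictly positive


# ---------------------------------------------------------------------------
# configuration and state types


@dataclass
class SimulationConfig:
    """Run parameters; times in seconds, cadence in Hz."""

    duration: float
    dt: float = 0.01
    cells: int = 1
    measurements_per_second: float = 5.0
    seed: int = 0
    mu_threshold: float = 0.1
    constant_noise_cv: float = 0.0
    initial_noise_cv: float = 0.0

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError("duration must be > 0")
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if self.cells < 1:
            raise ValueError("cells must be >= 1")
        if not self.measurements_per_second > 0:
            raise ValueError("measurements_per_second must be > 0")
        if not 0 < self.mu_threshold < 1:
            raise ValueError("mu_threshold must lie in (0, 1)")
        if self.constant_noise_cv < 0 or self.initial_noise_cv < 0:
            raise ValueError("noise CVs must be >= 0")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    @property
    def n_measurements(self) -> int:
        return int(math.floor(self.duration * self.measurements_per_second))


@dataclass
class QueueState:
    """Digitized network state: integer packet counts per pool."""

    packet_counts: dict[str, int]
    time: float = 0.0


@dataclass
class StepOutcome:
    """Bernoulli realizations of one step."""

    fired: set[str]
    skipped_underflow: set[str]


@dataclass
class TimeSeries:
    """Recorded concentration matrix (measurement x pool), mmol/L."""

    times: np.ndarray
    concentrations: np.ndarray
    pool_ids: list[str]
    cell_id: int | str = 0

    def column(self, pool_id: str) -> np.ndarray:
        return self.concentrations[:, self.pool_ids.index(pool_id)]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.concentrations, columns=self.pool_ids)
        df.insert(0, "time_s", self.times)
        return df


@dataclass
class TimestepReport:
    """Eq.-2 check: per-(event, pool) normalized rates at the initial state."""

    max_mu: float
    threshold: float
    entries: list[tuple[str, str, float]]  # (event id, pool id, mu), mu desc

    @property
    def passed(self) -> bool:
        return self.max_mu <= self.threshold

    @property
    def violators(self) -> list[tuple[str, str, float]]:
        return [e for e in self.entries if e[2] > self.threshold]


# ---------------------------------------------------------------------------
# rate normalization


def normalize_rate(velocity: float, dt: float, packet_size: float):
    """Normalize a signed velocity into a per-step probability and its role.

    Positive velocities act as arrival rates (packets flowing into the pool
    under consideration), negative ones as service rates.
    """
    mu = abs(velocity) * dt / packet_size
    role = "service" if velocity < 0 else "arrival"
    return mu, role


# ---------------------------------------------------------------------------
# compiled network


class CompiledNetwork:
    """Array form of a network for vectorized stepping."""

    def __init__(self, network: MetabolicNetwork):
        network.validate()
        self.network = network
        self.pool_ids = [p.id for p in network.pools]
        self.index = {pid: i for i, pid in enumerate(self.pool_ids)}
        self.psize = np.array([p.packet_size for p in network.pools])
        self.conc0 = np.array([p.initial_concentration for p in network.pools])

        R = len(network.reactions)
        self.n_reactions = R
        self.s1 = np.zeros(R, dtype=np.intp)
        self.s2 = np.zeros(R, dtype=np.intp)
        self.p1 = np.zeros(R, dtype=np.intp)
        self.p2 = np.zeros(R, dtype=np.intp)
        self.has_s2 = np.zeros(R, dtype=bool)
        self.has_p2 = np.zeros(R, dtype=bool)
        self.ks1 = np.ones(R)
        self.ks2 = np.ones(R)
        self.kp1 = np.ones(R)
        self.kp2 = np.ones(R)
        self.vf = np.zeros(R)
        self.vr = np.zeros(R)
        for j, rxn in enumerate(network.reactions):
            law = rxn.law
            self.s1[j] = self.index[rxn.substrates[0]]
            self.ks1[j] = law.k_s1
            if len(rxn.substrates) == 2:
                self.has_s2[j] = True
                self.s2[j] = self.index[rxn.substrates[1]]
                self.ks2[j] = law.k_s2
            self.p1[j] = self.index[rxn.products[0]]
            self.kp1[j] = law.k_p1
            if len(rxn.products) == 2:
                self.has_p2[j] = True
                self.p2[j] = self.index[rxn.products[1]]
                self.kp2[j] = law.k_p2
            self.vf[j] = law.vf
            self.vr[j] = law.vr

        # reference quantum per reaction: the smallest touched packet size,
        # whose normalized rate is the binding one for the mu << 1 condition
        self.psize_ref = np.empty(R)
        for j, rxn in enumerate(network.reactions):
            touched = [self.index[pid] for pid in rxn.species]
            self.psize_ref[j] = self.psize[touched].min()

        F = len(network.flows)
        self.n_flows = F
        self.flow_pool = np.array(
            [self.index[f.pool_id] for f in network.flows], dtype=np.intp
        )
        self.fcoeff = np.array([f.coefficient for f in network.flows])

        E = R + F
        self.n_events = E
        self.event_ids = [r.id for r in network.reactions] + [f.id for f in network.flows]
        M = np.zeros((E, len(self.pool_ids)))
        for j, rxn in enumerate(network.reactions):
            for pid in rxn.substrates:
                M[j, self.index[pid]] -= 1.0
            for pid in rxn.products:
                M[j, self.index[pid]] += 1.0
        for k in range(F):
            M[R + k, self.flow_pool[k]] = 1.0
        self.M = M
        self.Mpos = np.clip(M, 0.0, None)  # packets produced on forward firing
        self.Mneg = np.clip(-M, 0.0, None)  # packets consumed on forward firing
        # per-event sparse views for the sequential fallback
        self._ev_cons_fwd = [np.nonzero(self.Mneg[e])[0] for e in range(E)]
        self._ev_prod_fwd = [np.nonzero(self.Mpos[e])[0] for e in range(E)]

    # -- rate evaluation -----------------------------------------------------

    def rates(self, conc: np.ndarray, vf=None, vr=None) -> np.ndarray:
        """Batched Michaelis-Menten velocities, shape (cells, reactions)."""
        vf = self.vf if vf is None else vf
        vr = self.vr if vr is None else vr
        rs1 = conc[:, self.s1] / self.ks1
        rp1 = conc[:, self.p1] / self.kp1
        rs2 = np.where(self.has_s2, conc[:, self.s2] / self.ks2, 1.0)
        rp2 = np.where(self.has_p2, conc[:, self.p2] / self.kp2, 1.0)
        num = vf * rs1 * rs2 - vr * rp1 * rp2
        den = (1.0 + rs1 + rp1) * (
            1.0
            + np.where(self.has_s2, rs2, 0.0)
            + np.where(self.has_p2, rp2, 0.0)
        )
        return num / den

    def initial_counts(self) -> np.ndarray:
        return np.round(self.conc0 / self.psize)

    # -- stepping ------------------------------------------------------------

    def step_batch(
        self,
        counts: np.ndarray,
        dt: float,
        rng: np.random.Generator,
        vf=None,
        vr=None,
        fcoeff=None,
        skip_totals: np.ndarray | None = None,
    ) -> np.ndarray:
        """Advance a (cells x pools) count matrix by one time step in place."""
        C = counts.shape[0]
        fcoeff = self.fcoeff if fcoeff is None else fcoeff
        conc = counts * self.psize
        v = self.rates(conc, vf=vf, vr=vr)
        mu_r = np.abs(v) * (dt / self.psize_ref)
        flow_mu = np.abs(fcoeff) * (dt / self.psize[self.flow_pool])
        if flow_mu.ndim == 1:
            flow_mu = np.broadcast_to(flow_mu, (C, self.n_flows))
        mu = np.concatenate([mu_r, flow_mu], axis=1)
        np.clip(mu, 0.0, 1.0, out=mu)

        fired = rng.random((C, self.n_events)) < mu
        sign_f = np.broadcast_to(np.sign(fcoeff), (C, self.n_flows))
        sign = np.concatenate([np.sign(v), sign_f], axis=1)
        sf = np.where(fired, sign, 0.0)

        pos = np.clip(sf, 0.0, None)
        neg = np.clip(-sf, 0.0, None)
        consumption = pos @ self.Mneg + neg @ self.Mpos
        delta = sf @ self.M
        safe = (consumption <= counts).all(axis=1)
        new = counts + delta
        if not safe.all():
            for c in np.nonzero(~safe)[0]:
                new[c] = self._step_sequential(counts[c], sf[c], rng, skip_totals)
        return new

    def _step_sequential(
        self,
        counts_row: np.ndarray,
        sf_row: np.ndarray,
        rng: np.random.Generator,
        skip_totals: np.ndarray | None,
    ) -> np.ndarray:
        """Uniformly random application order with underflow skipping."""
        out = counts_row.copy()
        idx = np.nonzero(sf_row)[0]
        for e in rng.permutation(idx):
            s = sf_row[e]
            cons = self._ev_cons_fwd[e] if s > 0 else self._ev_prod_fwd[e]
            prod = self._ev_prod_fwd[e] if s > 0 else self._ev_cons_fwd[e]
            if (out[cons] < 1.0).any():
                if skip_totals is not None:
                    skip_totals[e] += 1
                continue
            out[cons] -= 1.0
            out[prod] += 1.0
        return out


# ---------------------------------------------------------------------------
# time-step condition


def validate_timestep(
    network: MetabolicNetwork, config: SimulationConfig
) -> TimestepReport:
    """Check mu << 1 for every (reaction-or-flow, touched pool) at t = 0."""
    compiled = CompiledNetwork(network)
    conc0 = compiled.conc0[None, :]
    v = compiled.rates(conc0)[0] if compiled.n_reactions else np.empty(0)
    entries: list[tuple[str, str, float]] = []
    for j, rxn in enumerate(network.reactions):
        for pid in rxn.species:
            mu, _ = normalize_rate(v[j], config.dt, network.pool(pid).packet_size)
            entries.append((rxn.id, pid, mu))
    for flow in network.flows:
        mu, _ = normalize_rate(
            flow.coefficient, config.dt, network.pool(flow.pool_id).packet_size
        )
        entries.append((flow.id, flow.pool_id, mu))
    entries.sort(key=lambda e: e[2], reverse=True)
    max_mu = entries[0][2] if entries else 0.0
    return TimestepReport(max_mu=max_mu, threshold=config.mu_threshold, entries=entries)


# ---------------------------------------------------------------------------
# public stepping / simulation


def step(
    network: MetabolicNetwork,
    state: QueueState,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[QueueState, StepOutcome]:
    """Advance one time step; rates are evaluated from the pre-step state."""
    compiled = CompiledNetwork(network)
    counts = np.array(
        [[float(state.packet_counts[pid]) for pid in compiled.pool_ids]]
    )
    skip_totals = np.zeros(compiled.n_events)
    # replicate step_batch but keep the fired mask for the outcome report
    conc = counts * compiled.psize
    v = compiled.rates(conc)
    mu_r = np.abs(v) * (config.dt / compiled.psize_ref)
    flow_mu = np.abs(compiled.fcoeff) * (
        config.dt / compiled.psize[compiled.flow_pool]
    )
    mu = np.concatenate([mu_r[0], flow_mu])
    np.clip(mu, 0.0, 1.0, out=mu)
    fired = rng.random(compiled.n_events) < mu
    sign = np.concatenate([np.sign(v[0]), np.sign(compiled.fcoeff)])
    sf = np.where(fired, sign, 0.0)
    new = compiled._step_sequential(counts[0], sf, rng, skip_totals)
    fired_ids = {
        compiled.event_ids[e]
        for e in np.nonzero(sf)[0]
        if skip_totals[e] == 0
    }
    skipped_ids = {compiled.event_ids[e] for e in np.nonzero(skip_totals)[0]}
    new_state = QueueState(
        packet_counts={
            pid: int(new[i]) for i, pid in enumerate(compiled.pool_ids)
        },
        time=state.time + config.dt,
    )
    return new_state, StepOutcome(fired=fired_ids, skipped_underflow=skipped_ids)


def _measurement_steps(config: SimulationConfig) -> np.ndarray:
    rows = config.n_measurements
    steps = np.round(
        (np.arange(1, rows + 1) / config.measurements_per_second) / config.dt
    ).astype(np.int64)
    return np.minimum(steps, config.n_steps)


def _noisy(base: np.ndarray, cv: float, shape, rng) -> np.ndarray:
    factors = np.maximum(_EPS_POSITIVE, 1.0 + cv * rng.standard_normal(shape))
    return base * factors


def run_batch(
    compiled: CompiledNetwork,
    config: SimulationConfig,
    rng: np.random.Generator,
    cells: int | None = None,
    vf=None,
    vr=None,
    fcoeff=None,
    counts0: np.ndarray | None = None,
):
    """Step an ensemble and record concentrations at the measurement cadence.

    Returns ``(times, recorded, skip_totals)`` where ``recorded`` has shape
    (cells, measurements, pools).  Constant overrides may be per-cell
    ((cells, reactions) / (cells, flows)) for noisy or GA-parametrized runs.
    """
    C = config.cells if cells is None else cells
    if counts0 is None:
        counts = np.tile(compiled.initial_counts(), (C, 1))
    else:
        counts = np.array(counts0, dtype=float)
    if config.constant_noise_cv > 0 and vf is None:
        vf = _noisy(compiled.vf, config.constant_noise_cv, (C, compiled.n_reactions), rng)
        vr = _noisy(compiled.vr, config.constant_noise_cv, (C, compiled.n_reactions), rng)
    if config.initial_noise_cv > 0 and counts0 is None:
        conc = _noisy(compiled.conc0, config.initial_noise_cv, (C, len(compiled.pool_ids)), rng)
        counts = np.round(conc / compiled.psize)

    measure_at = _measurement_steps(config)
    rows = len(measure_at)
    recorded = np.empty((C, rows, len(compiled.pool_ids)))
    skip_totals = np.zeros(compiled.n_events)

    next_row = 0
    for step_i in range(1, config.n_steps + 1):
        counts = compiled.step_batch(
            counts, config.dt, rng, vf=vf, vr=vr, fcoeff=fcoeff,
            skip_totals=skip_totals,
        )
        while next_row < rows and measure_at[next_row] == step_i:
            recorded[:, next_row, :] = counts * compiled.psize
            next_row += 1
    times = np.arange(1, rows + 1) / config.measurements_per_second
    return times, recorded, skip_totals


def simulate(
    network: MetabolicNetwork,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> TimeSeries:
    """Single-cell run; refuses to start when the time-step condition fails."""
    report = validate_timestep(network, config)
    if not report.passed:
        worst = ", ".join(f"{r}@{p}: mu={m:.3g}" for r, p, m in report.violators[:5])
        raise TimestepConditionViolated(
            f"max mu {report.max_mu:.3g} > threshold {config.mu_threshold}: {worst}"
        )
    rng = np.random.default_rng(config.seed) if rng is None else rng
    compiled = CompiledNetwork(network)
    times, recorded, _ = run_batch(compiled, config, rng, cells=1)
    return TimeSeries(
        times=times, concentrations=recorded[0], pool_ids=compiled.pool_ids, cell_id=0
    )


def simulate_ensemble(
    network: MetabolicNetwork,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    skip_totals_out: dict[str, int] | None = None,
) -> tuple[TimeSeries, list[TimeSeries]]:
    """Independent replicate cells plus their pointwise-average series.

    When ``skip_totals_out`` is given it is filled with the per-event
    underflow-skip totals of the whole ensemble run (for run logs).
    """
    report = validate_timestep(network, config)
    if not report.passed:
        raise TimestepConditionViolated(
            f"max mu {report.max_mu:.3g} > threshold {config.mu_threshold}"
        )
    rng = np.random.default_rng(config.seed) if rng is None else rng
    compiled = CompiledNetwork(network)
    times, recorded, skips = run_batch(compiled, config, rng)
    if skip_totals_out is not None:
        skip_totals_out.update(
            {eid: int(n) for eid, n in zip(compiled.event_ids, skips)}
        )
    per_cell = [
        TimeSeries(
            times=times,
            concentrations=recorded[c],
            pool_ids=compiled.pool_ids,
            cell_id=c,
        )
        for c in range(recorded.shape[0])
    ]
    mean = TimeSeries(
        times=times,
        concentrations=recorded.mean(axis=0),
        pool_ids=compiled.pool_ids,
        cell_id="mean",
    )
    return mean, per_cell


# ---------------------------------------------------------------------------
# constant noise


def perturb_constants(
    network: MetabolicNetwork,
    cv: float,
    rng: np.random.Generator,
    initial_cv: float = 0.0,
) -> MetabolicNetwork:
    """Multiply every kinetic constant by max(eps, 1 + cv*z), z ~ N(0, 1).

    With ``initial_cv`` the same transform is applied to the initial
    concentrations.  ``cv = 0`` (and ``initial_cv = 0``) returns an identical
    copy.
    """
    if cv < 0 or initial_cv < 0:
        raise ValueError("cv must be >= 0")
    import copy

    out = copy.deepcopy(network)
    if cv > 0:
        for rxn in out.reactions:
            law = rxn.law
            for attr in ("vf", "vr", "k_s1", "k_s2", "k_p1", "k_p2"):
                value = getattr(law, attr)
                if value is not None:
                    factor = max(_EPS_POSITIVE, 1.0 + cv * rng.standard_normal())
                    setattr(law, attr, value * factor)
    if initial_cv > 0:
        for pool in out.pools:
            factor = max(_EPS_POSITIVE, 1.0 + initial_cv * rng.standard_normal())
            pool.initial_concentration *= factor
    return out


# ---------------------------------------------------------------------------
# dispersion statistic


def sd_over_mean_90p(series: TimeSeries, pool_id: str, window: int = 100) -> float:
    """90th percentile of sliding-window SDs divided by the overall mean.

    The 90th percentile (rather than the maximum) makes the statistic robust
    to isolated outlier windows such as sudden concentration jumps.
    """
    trace = series.column(pool_id)
    if len(trace) < window:
        raise DegenerateSeries(
            f"series has {len(trace)} rows, fewer than window {window}"
        )
    mean = float(trace.mean())
    if mean <= 0:
        raise DegenerateSeries(f"pool {pool_id!r} has non-positive mean")
    sds = pd.Series(trace).rolling(window).std(ddof=1).to_numpy()[window - 1:]
    return float(np.percentile(sds / mean, 90))


# ---------------------------------------------------------------------------
# output

def write_timeseries_csv(series: TimeSeries, path: str | Path) -> None:
    series.to_dataframe().to_csv(path, index=False, float_format="%.6g")


def write_run_log(
    path: str | Path,
    config: SimulationConfig,
    report: TimestepReport,
    skip_totals: dict[str, int] | None = None,
) -> None:
    lines = [
        f"seed: {config.seed}",
        f"dt_s: {config.dt}",
        f"duration_s: {config.duration}",
        f"cells: {config.cells}",
        f"max_initial_mu: {report.max_mu:.6g}",
        f"mu_threshold: {report.threshold}",
    ]
    if skip_totals:
        lines.append("underflow_skips:")
        for event_id, n in sorted(skip_totals.items()):
            if n:
                lines.append(f"  {event_id}: {n}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
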