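"""Variance-based sensitivity of simulation endpoints to starting values.

One metabolite's starting concentration is swept over a grid; for every grid
value an ensemble of independent simulations is run and each pool's final
concentration recorded.  Two score flavors are computed per measured pool:

* ``variance_ratio`` — the first-order variance-based index
  S = V(E[Y | start]) / V(Y), with the conditional expectation estimated by
  the per-grid-value replicate mean.  It lies in [0, 1] up to estimator
  noise; values near 0 mean the endpoint is insensitive to the start.
* ``endpoint_ratio`` — the mean endpoint at each non-baseline grid value
  divided by the mean endpoint at baseline.  Values near 1 mean robustness;
  this is the flavor whose concatenated distribution is summarized by
  (min, 5th percentile, median, 95th percentile, max) in reports, because a
  bounded variance ratio cannot produce the >1 scores such summaries show.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import CompiledNetwork, SimulationConfig, run_batch
from .errors import EmptyScores, UnknownPool
from .network import MetabolicNetwork

DEFAULT_GRID_MULTIPLIERS = (0.5, 0.75, 1.0, 1.25, 1.5)
QUANTILE_LABELS = ("minimum", "p5", "median", "p95", "maximum")


@dataclass
class SensitivityReport:
    varied_metabolite: str
    grid: list[float]  # starting concentrations, mmol/L
    variance_ratio: dict[str, float]  # pool id -> score
    endpoint_ratio: dict[str, np.ndarray]  # pool id -> per-non-baseline-grid ratios
    quantiles: dict[str, tuple[float, ...]]  # flavor -> five-number summary

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"varied_metabolite": self.varied_metabolite, "flavor": flavor}
            | dict(zip(QUANTILE_LABELS, summary))
            for flavor, summary in self.quantiles.items()
        ]
        return pd.DataFrame(rows)


def vary_and_simulate(
    network: MetabolicNetwork,
    config: SimulationConfig,
    metabolite: str,
    grid,
    replicates: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Endpoint matrix of shape (grid, replicates, pools).

    For each grid value the metabolite's starting concentration is replaced
    (its packet quantum is kept, so firing probabilities stay comparable) and
    `replicates` independent cells are simulated; the final measurement row
    is the endpoint.
    """
    grid = [float(g) for g in grid]
    if any(g < 0 for g in grid):
        raise ValueError("grid values must be >= 0")
    if replicates < 2:
        raise ValueError("need >= 2 replicates")
    network.pool(metabolite)  # raises UnknownPool for bad ids
    rng = np.random.default_rng(config.seed) if rng is None else rng

    endpoints = []
    for value in grid:
        varied = copy.deepcopy(network)
        varied.pool(metabolite).initial_concentration = value
        compiled = CompiledNetwork(varied)
        _, recorded, _ = run_batch(compiled, config, rng, cells=replicates)
        endpoints.append(recorded[:, -1, :])
    return np.stack(endpoints)  # (grid, replicates, pools)


def sensitivity_score(
    endpoints: np.ndarray, baseline_index: int | None = None
) -> tuple[float, np.ndarray]:
    """Both score flavors for one pool's (grid x replicate) endpoint matrix.

    Returns ``(variance_ratio, endpoint_ratios)``; the latter has one entry
    per non-baseline grid value.  A zero pooled variance makes the variance
    ratio 0 by definition (the no-effect case).
    """
    endpoints = np.asarray(endpoints, dtype=float)
    if endpoints.ndim != 2 or endpoints.shape[0] < 2 or endpoints.shape[1] < 2:
        raise ValueError("need >= 2 grid points and >= 2 replicates")
    G = endpoints.shape[0]
    if baseline_index is None:
        baseline_index = G // 2
    group_means = endpoints.mean(axis=1)
    total_var = endpoints.var()
    if total_var == 0:
        variance_ratio = 0.0
    else:
        variance_ratio = abs(float(group_means.var() / total_var))

    baseline_mean = group_means[baseline_index]
    others = np.delete(group_means, baseline_index)
    if baseline_mean == 0:
        # zero baseline: ratios are 1 in the all-zero (no-effect) case and
        # undefined otherwise (empty; the pool is dropped from aggregation)
        ratios = np.ones_like(others) if (others == 0).all() else np.empty(0)
    else:
        ratios = others / baseline_mean
    return variance_ratio, ratios


def aggregate_scores(scores) -> tuple[float, float, float, float, float]:
    """Five-number summary (min, p5, median, p95, max), linear interpolation."""
    arr = np.asarray(list(scores), dtype=float)
    if arr.size == 0:
        raise EmptyScores("no sensitivity scores to aggregate")
    return (
        float(arr.min()),
        float(np.percentile(arr, 5)),
        float(np.percentile(arr, 50)),
        float(np.percentile(arr, 95)),
        float(arr.max()),
    )


def sensitivity_report(
    network: MetabolicNetwork,
    config: SimulationConfig,
    metabolite: str,
    grid_multipliers=DEFAULT_GRID_MULTIPLIERS,
    replicates: int = 10,
    rng: np.random.Generator | None = None,
    measured_pools: list[str] | None = None,
) -> SensitivityReport:
    """Sweep one metabolite's start, score every measured pool, aggregate."""
    multipliers = [float(m) for m in grid_multipliers]
    if len(multipliers) < 2:
        raise ValueError("need >= 2 grid points")
    if 1.0 not in multipliers:
        raise ValueError("the grid must contain the baseline multiplier 1.0")
    baseline_index = multipliers.index(1.0)
    base = network.pool(metabolite).initial_concentration
    grid = [m * base for m in multipliers]

    endpoints = vary_and_simulate(network, config, metabolite, grid, replicates, rng)
    pool_ids = measured_pools or [p.id for p in network.pools]
    index = {p.id: i for i, p in enumerate(network.pools)}
    for pid in pool_ids:
        if pid not in index:
            raise UnknownPool(f"measured pool {pid!r} not in network")

    variance_ratio: dict[str, float] = {}
    endpoint_ratio: dict[str, np.ndarray] = {}
    for pid in pool_ids:
        vr, er = sensitivity_score(endpoints[:, :, index[pid]], baseline_index)
        variance_ratio[pid] = vr
        endpoint_ratio[pid] = er
    quantiles = {
        "variance_ratio": aggregate_scores(list(variance_ratio.values())),
        "endpoint_ratio": aggregate_scores(
            np.concatenate(list(endpoint_ratio.values()))
        ),
    }
    return SensitivityReport(
        varied_metabolite=metabolite,
        grid=grid,
        variance_ratio=variance_ratio,
        endpoint_ratio=endpoint_ratio,
        quantiles=quantiles,
    )
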