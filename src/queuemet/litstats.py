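"""Gaussian treatment of heterogeneous literature concentration data.

Reported metabolite concentrations come as single numbers or closed ranges.
Each metabolite's concentration is modelled as Gaussian; (mean, SD) are the
maximum-likelihood estimates — the arithmetic mean and the population SD
(divisor n).  When ranges are present, one value per range is selected
*jointly* with the distribution so as to maximize the log-likelihood; that
inner selection problem is solved with a small genetic algorithm.  Model
outputs are compared to the fitted distributions through Z-scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import MissingConcentration, TooFewValues

SD_FLOOR = 1e-9  # mmol/L; keeps Z-scores finite for degenerate fits


@dataclass(frozen=True)
class MeasurementRecord:
    """One literature measurement: a point value or a closed range, mmol/L."""

    metabolite: str
    kind: str  # "point" | "range"
    value: float | None = None
    low: float | None = None
    high: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.kind == "point":
            if self.value is None or self.value < 0:
                raise ValueError(f"{self.metabolite}: point value must be >= 0")
        elif self.kind == "range":
            if self.low is None or self.high is None or not 0 <= self.low < self.high:
                raise ValueError(f"{self.metabolite}: range needs 0 <= low < high")
        else:
            raise ValueError(f"{self.metabolite}: unknown record kind {self.kind!r}")


@dataclass
class GaussianEstimate:
    metabolite: str
    mean: float
    sd: float
    mode: str  # "points_only" | "ga_ranges"
    chosen_range_values: dict[tuple[float, float], float] = field(default_factory=dict)

    def log_likelihood(self, values: np.ndarray) -> float:
        n = len(values)
        var = max(self.sd, SD_FLOOR) ** 2
        return float(
            -0.5 * n * math.log(2 * math.pi * var)
            - 0.5 * np.sum((values - self.mean) ** 2) / var
        )


@dataclass
class RangeGAConfig:
    """GA settings for the in-range value selection (mirrors the tuner's)."""

    population_size: int = 100
    elite_count: int = 10
    mutation_probability: float = 0.10
    mutation_amplitude: float = 1.0
    generations: int = 80
    seed: int = 0


def _mle(values: np.ndarray) -> tuple[float, float]:
    mean = float(values.mean())
    sd = float(np.sqrt(np.mean((values - mean) ** 2)))  # population MLE, divisor n
    return mean, max(sd, SD_FLOOR)


def fit_gaussian_points(values, metabolite: str = "") -> GaussianEstimate:
    """Closed-form Gaussian MLE from point measurements only."""
    arr = np.asarray(list(values), dtype=float)
    if len(arr) < 2:
        raise TooFewValues(
            f"{metabolite or 'metabolite'}: need >= 2 values, got {len(arr)}"
        )
    mean, sd = _mle(arr)
    return GaussianEstimate(metabolite=metabolite, mean=mean, sd=sd, mode="points_only")


def fit_gaussian_with_ranges(
    points,
    ranges,
    ga_config: RangeGAConfig | None = None,
    rng: np.random.Generator | None = None,
    metabolite: str = "",
) -> GaussianEstimate:
    """Jointly select one value per range and fit the Gaussian by max likelihood.

    For a Gaussian with its (mean, SD) profiled out in closed form, maximizing
    the log-likelihood over the selected values is equivalent to minimizing
    the population variance of the combined sample; the GA searches the box
    of ranges for that minimizer.  With zero ranges this reduces exactly to
    :func:`fit_gaussian_points`.
    """
    pts = np.asarray(list(points), dtype=float)
    boxes = [(float(lo), float(hi)) for lo, hi in ranges]
    if len(pts) + len(boxes) < 2:
        raise TooFewValues(f"{metabolite or 'metabolite'}: need >= 2 records")
    if not boxes:
        est = fit_gaussian_points(pts, metabolite)
        return GaussianEstimate(
            metabolite=metabolite, mean=est.mean, sd=est.sd, mode="ga_ranges"
        )

    cfg = ga_config or RangeGAConfig()
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    lo = np.array([b[0] for b in boxes])
    hi = np.array([b[1] for b in boxes])

    def variance(pop: np.ndarray) -> np.ndarray:
        # pop: (individuals, ranges); combined sample per row
        combined = np.concatenate(
            [np.tile(pts, (pop.shape[0], 1)), pop], axis=1
        )
        return combined.var(axis=1)

    pop = lo + (hi - lo) * rng.random((cfg.population_size, len(boxes)))
    pop[0] = (lo + hi) / 2.0  # midpoint baseline is always in the search
    for _ in range(cfg.generations):
        fitness = variance(pop)
        order = np.argsort(fitness)
        elite = pop[order[: cfg.elite_count]]
        n_children = cfg.population_size - cfg.elite_count
        parents = rng.integers(0, cfg.elite_count, size=(n_children, 2))
        mix = rng.random((n_children, len(boxes))) < 0.5
        children = np.where(mix, elite[parents[:, 0]], elite[parents[:, 1]])
        mutate = rng.random(children.shape) < cfg.mutation_probability
        noise = rng.standard_normal(children.shape) * (
            cfg.mutation_amplitude * 0.10 * (hi - lo)
        )
        children = np.clip(children + mutate * noise, lo, hi)
        pop = np.concatenate([elite, children], axis=0)
    best = pop[np.argsort(variance(pop))[0]]
    mean, sd = _mle(np.concatenate([pts, best]))
    return GaussianEstimate(
        metabolite=metabolite,
        mean=mean,
        sd=sd,
        mode="ga_ranges",
        chosen_range_values={b: float(v) for b, v in zip(boxes, best)},
    )


def z_score(model_concentration: float, estimate: GaussianEstimate) -> float:
    """Standardized distance of a model concentration from the literature fit."""
    return (model_concentration - estimate.mean) / max(estimate.sd, SD_FLOOR)


def _truncate(x: float, decimals: int) -> float:
    scale = 10.0 ** decimals
    return math.trunc(x * scale) / scale


def fit_metabolite(
    records: list[MeasurementRecord],
    mode: str = "points_only",
    ga_config: RangeGAConfig | None = None,
    rng: np.random.Generator | None = None,
) -> GaussianEstimate:
    """Fit one metabolite from its mixed point/range records."""
    if not records:
        raise TooFewValues("no records")
    metabolite = records[0].metabolite
    points = [r.value for r in records if r.kind == "point"]
    ranges = [(r.low, r.high) for r in records if r.kind == "range"]
    if mode == "points_only":
        return fit_gaussian_points(points, metabolite)
    if mode == "ga_ranges":
        return fit_gaussian_with_ranges(
            points, ranges, ga_config, rng, metabolite=metabolite
        )
    raise ValueError(f"unknown mode {mode!r}")


def literature_report(
    measurements: list[MeasurementRecord],
    model_concentrations: dict[str, float],
    mode: str = "points_only",
    ga_config: RangeGAConfig | None = None,
    rng: np.random.Generator | None = None,
    table_precision: int | None = 4,
) -> pd.DataFrame:
    """Per-metabolite estimated (mean, SD), model concentration and Z-score.

    ``table_precision`` truncates the estimates to the given number of
    decimals before the Z-score is formed — the reporting convention of the
    published comparison table, where Z-scores derive from the printed
    (4-decimal) estimates.  Pass ``None`` for full-precision Z-scores.
    """
    by_met: dict[str, list[MeasurementRecord]] = {}
    for rec in measurements:
        by_met.setdefault(rec.metabolite, []).append(rec)
    rows = []
    for metabolite, records in by_met.items():
        if metabolite not in model_concentrations:
            raise MissingConcentration(
                f"no model concentration for metabolite {metabolite!r}"
            )
        est = fit_metabolite(records, mode=mode, ga_config=ga_config, rng=rng)
        mean, sd = est.mean, est.sd
        if table_precision is not None:
            mean = _truncate(mean, table_precision)
            sd = _truncate(sd, table_precision)
        model = model_concentrations[metabolite]
        z = (model - mean) / max(sd, SD_FLOOR)
        rows.append(
            {
                "metabolite": metabolite,
                "estimated_mean": mean,
                "estimated_sd": sd,
                "model_concentration": model,
                "z_score": z,
                "outside_two_sigma": abs(z) > 2,
                "outside_three_sigma": abs(z) > 3,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TSV interfaces and bundled data


def read_measurements_tsv(path: str | Path) -> list[MeasurementRecord]:
    """Measurement table: metabolite, kind (point|range), value_or_low, high, source."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"metabolite", "kind", "value_or_low"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        kind = row["kind"].strip()
        if kind == "point":
            records.append(
                MeasurementRecord(
                    metabolite=row["metabolite"],
                    kind="point",
                    value=float(row["value_or_low"]),
                    source=row.get("source", ""),
                )
            )
        else:
            records.append(
                MeasurementRecord(
                    metabolite=row["metabolite"],
                    kind="range",
                    low=float(row["value_or_low"]),
                    high=float(row["high"]),
                    source=row.get("source", ""),
                )
            )
    return records


def write_report_tsv(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, sep="\t", index=False, float_format="%.6g")


def bundled_measurements() -> list[MeasurementRecord]:
    """Literature TCA-metabolite measurements shipped with the package."""
    path = resources.files("queuemet.data") / "tca_literature_measurements.tsv"
    return read_measurements_tsv(str(path))


def bundled_model_concentrations() -> dict[str, float]:
    """Modelled TCA concentrations during the glycolytic phase (mmol/L)."""
    path = resources.files("queuemet.data") / "tca_model_concentrations.tsv"
    df = pd.read_csv(str(path), sep="\t")
    return dict(zip(df["metabolite"], df["model_mmol_per_l"].astype(float)))
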