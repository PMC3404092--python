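"""Sweep experiments: maximum sustainable complexity per population size.

For each (population size N, mentor-selection strategy) cell the driver runs
replicate agent-based trajectories over a grid of transmission-inaccuracy
offsets ``alpha`` and reports the largest grid value for which a majority of
replicates sustain the skill — "sustained" meaning the least-squares slope of
mean skill versus generation, after a burn-in prefix, is at least a
tolerance (0 by default).  The resulting alpha* curves are the simulated
counterpart of the analytic critical curves: under pure copy-the-best they
coincide with ``critical_complexity`` to grid resolution, while weakly
selective strategies (random copying, conformity) flatten the population
effect away.

All randomness flows from one master seed through deterministically spawned
substreams, so a sweep is exactly reproducible and every cell's seed is
recorded in the run manifest.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .abm import (
    ABMConfig,
    STRATEGY_KINDS,
    Strategy,
    Trajectory,
    run_generations,
    run_henrich_mode,
)
from .analytic import ErrorSpec
from .distributions import SkillDistributionSpec, matching_normal_sd

#: default population-size grid (desk scale; resolves the plateau above 250)
DEFAULT_N_VALUES = (2, 5, 10, 25, 50, 100, 250, 500, 1000)
#: reduced grid used for the simulated critical-curve figures
REDUCED_N_VALUES = (10, 50, 250, 1000)
DEFAULT_GENERATIONS = 100
DEFAULT_REPLICATES = 10
#: 40-point linear complexity grid (skill units, scale 1)
DEFAULT_ALPHA_GRID = tuple(np.round(np.linspace(0.2, 8.0, 40), 10))


@dataclass(frozen=True)
class SustainabilityCriterion:
    """Operational definition of a sustained trajectory.

    ``burn_in_fraction`` of the generations is discarded before fitting the
    least-squares slope; a trajectory is sustained when the slope is at least
    ``slope_tolerance``; a grid alpha counts as sustainable when at least
    ``required_fraction`` of replicates are sustained.
    """

    burn_in_fraction: float = 0.1
    slope_tolerance: float = 0.0
    required_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in_fraction < 1:
            raise ValueError("burn_in_fraction must be in [0, 1)")
        if not 0 < self.required_fraction <= 1:
            raise ValueError("required_fraction must be in (0, 1]")


@dataclass(frozen=True)
class SweepRecord:
    """One (N, strategy) cell of a sweep."""

    n: int
    strategy: str
    family: str
    alpha_star: float | None
    replicates: int
    sustained_fraction: float
    seed: int


@dataclass
class SweepResult:
    """All cells of one sweep plus the configuration needed to rerun it."""

    records: list[SweepRecord]
    alpha_grid: tuple
    generations: int
    criterion: SustainabilityCriterion
    master_seed: int
    skill_scale: float = 1.0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "strategy": r.strategy,
                    "family": r.family,
                    "n": r.n,
                    "alpha_star": np.nan if r.alpha_star is None else r.alpha_star,
                    "replicates": r.replicates,
                    "sustained_fraction": r.sustained_fraction,
                    "seed": r.seed,
                }
                for r in self.records
            ]
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def manifest(self) -> dict:
        return {
            "alpha_grid": [float(a) for a in self.alpha_grid],
            "generations": self.generations,
            "criterion": asdict(self.criterion),
            "master_seed": self.master_seed,
            "skill_scale": self.skill_scale,
            "cells": [
                {"n": r.n, "strategy": r.strategy, "family": r.family, "seed": r.seed}
                for r in self.records
            ],
        }

    def alpha_stars(self, strategy: str) -> dict[int, float | None]:
        return {r.n: r.alpha_star for r in self.records if r.strategy == strategy}


def is_sustained(trajectory: Trajectory, criterion: SustainabilityCriterion) -> bool:
    """Least-squares slope of mean skill (after burn-in) >= tolerance."""
    y = trajectory.mean_skill
    start = int(np.floor(criterion.burn_in_fraction * trajectory.generations))
    y = y[start:]
    if y.size < 2:
        raise ValueError("trajectory too short after burn-in to fit a slope")
    x = np.arange(y.size, dtype=float)
    x -= x.mean()
    # centred least squares: exactly zero for a constant series
    slope = float(np.dot(x, y - y.mean()) / np.dot(x, x))
    return slope >= criterion.slope_tolerance


def _cell_seed(master_seed: int, *key: int) -> int:
    """Deterministic, loggable sub-seed for one sweep cell."""
    ss = np.random.SeedSequence([int(master_seed), *[int(k) for k in key]])
    return int(ss.generate_state(1, np.uint32)[0]) & 0x7FFFFFFF


def _run_one(
    n: int,
    strategy: Strategy,
    family: str,
    alpha: float,
    generations: int,
    seed: int,
    skill_scale: float,
) -> Trajectory:
    """One replicate trajectory for a sweep cell.

    Strategy kind ``best`` runs the pure copy-the-best validation mode (no
    vertical step, no adoption filter), matching the analytic model; all
    other strategies run the full vertical + oblique loop.
    """
    scale = skill_scale if family == "gumbel" else matching_normal_sd(skill_scale)
    skill = SkillDistributionSpec(family, 0.0, scale)
    spread = skill_scale if family == "gumbel" else scale
    error = ErrorSpec(family if family == "gumbel" else "normal", alpha, spread)
    if strategy.kind == "best":
        rng = np.random.default_rng(seed)
        return run_henrich_mode(n, error, skill, generations, rng)
    config = ABMConfig(
        n=n, generations=generations, skill=skill, error=error,
        strategy=strategy, seed=seed,
    )
    return run_generations(config)


def max_sustainable_alpha(
    n: int,
    strategy: Strategy,
    family: str,
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    replicates: int = DEFAULT_REPLICATES,
    generations: int = DEFAULT_GENERATIONS,
    criterion: SustainabilityCriterion = SustainabilityCriterion(),
    seed: int = 0,
    skill_scale: float = 1.0,
) -> float | None:
    """Largest grid alpha sustained by >= ``required_fraction`` of replicates.

    The reported value is always a grid point (no interpolation); ``None``
    when no grid alpha is sustainable.
    """
    alpha, _ = _max_sustainable_cell(
        n, strategy, family, alpha_grid, replicates, generations,
        criterion, seed, skill_scale,
    )
    return alpha


def _max_sustainable_cell(
    n, strategy, family, alpha_grid, replicates, generations,
    criterion, seed, skill_scale,
):
    grid = [float(a) for a in alpha_grid]
    if not grid:
        raise ValueError("alpha_grid must be non-empty")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("alpha_grid must be strictly increasing")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    # scan from the top: the first sustainable alpha is the largest one
    for i in range(len(grid) - 1, -1, -1):
        sustained = 0
        for j in range(replicates):
            traj = _run_one(
                n, strategy, family, grid[i], generations,
                _cell_seed(seed, i, j), skill_scale,
            )
            if is_sustained(traj, criterion):
                sustained += 1
        fraction = sustained / replicates
        if fraction >= criterion.required_fraction:
            return grid[i], fraction
    return None, 0.0


def critical_curve_abm(
    n_values: Sequence[int],
    strategy: Strategy,
    family: str,
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    replicates: int = DEFAULT_REPLICATES,
    generations: int = DEFAULT_GENERATIONS,
    criterion: SustainabilityCriterion = SustainabilityCriterion(),
    seed: int = 0,
    skill_scale: float = 1.0,
) -> SweepResult:
    """ABM-estimated critical curve: one sustainable-alpha record per N."""
    records = []
    for ni, n in enumerate(n_values):
        cell_seed = _cell_seed(seed, STRATEGY_KINDS.index(strategy.kind), ni)
        alpha_star, fraction = _max_sustainable_cell(
            int(n), strategy, family, alpha_grid, replicates, generations,
            criterion, cell_seed, skill_scale,
        )
        records.append(
            SweepRecord(
                n=int(n), strategy=strategy.kind, family=family,
                alpha_star=alpha_star, replicates=replicates,
                sustained_fraction=fraction, seed=cell_seed,
            )
        )
    return SweepResult(
        records=records, alpha_grid=tuple(alpha_grid), generations=generations,
        criterion=criterion, master_seed=seed, skill_scale=skill_scale,
    )


def sweep_strategies(
    strategies: Sequence[Strategy],
    n_values: Sequence[int] = REDUCED_N_VALUES,
    family: str = "gumbel",
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    replicates: int = DEFAULT_REPLICATES,
    generations: int = DEFAULT_GENERATIONS,
    criterion: SustainabilityCriterion = SustainabilityCriterion(),
    seed: int = 0,
    skill_scale: float = 1.0,
) -> SweepResult:
    """Run :func:`critical_curve_abm` for several strategies into one result."""
    records: list[SweepRecord] = []
    for si, strategy in enumerate(strategies):
        sub = critical_curve_abm(
            n_values, strategy, family, alpha_grid, replicates,
            generations, criterion, _cell_seed(seed, si), skill_scale,
        )
        records.extend(sub.records)
    return SweepResult(
        records=records, alpha_grid=tuple(alpha_grid), generations=generations,
        criterion=criterion, master_seed=seed, skill_scale=skill_scale,
    )


@dataclass(frozen=True)
class PopulationEffectSummary:
    """Summary of how alpha* depends on population size in one sweep."""

    alpha_star_range: float
    slope_per_ln_n: float
    plateau_ratio: float
    excluded_not_sustainable: int


def population_effect_summary(sweep: SweepResult, strategy: str | None = None):
    """Range, log-N slope and plateau ratio of an alpha* curve.

    The plateau ratio is ``(alpha*(N_max) - alpha*(N_mid)) /
    (alpha*(N_mid) - alpha*(N_min))`` with ``N_mid`` the median grid point; a
    value well below 1 means the population effect saturates at large N.
    Cells that sustained nothing are excluded (their count is reported).
    """
    records = [
        r for r in sweep.records if strategy is None or r.strategy == strategy
    ]
    usable = sorted(
        (r for r in records if r.alpha_star is not None), key=lambda r: r.n
    )
    excluded = len(records) - len(usable)
    if len({r.n for r in usable}) < 2:
        raise ValueError("population_effect_summary needs >= 2 population sizes")
    n = np.array([r.n for r in usable], dtype=float)
    a = np.array([r.alpha_star for r in usable], dtype=float)
    slope = float(np.polyfit(np.log(n), a, 1)[0])
    mid = usable[len(usable) // 2]
    lo, hi = usable[0], usable[-1]
    denom = mid.alpha_star - lo.alpha_star
    numer = hi.alpha_star - mid.alpha_star
    ratio = numer / denom if denom != 0 else np.nan  # flat start: undefined
    return PopulationEffectSummary(
        alpha_star_range=float(a.max() - a.min()),
        slope_per_ln_n=slope,
        plateau_ratio=float(ratio),
        excluded_not_sustainable=excluded,
    )


def save_sweep(sweep: SweepResult, csv_path, manifest_path) -> None:
    """Write the sweep CSV and its JSON run manifest side by side."""
    sweep.to_csv(csv_path)
    with open(manifest_path, "w") as fh:
        json.dump(sweep.manifest(), fh, indent=2, sort_keys=True)
        fh.write("\n")
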