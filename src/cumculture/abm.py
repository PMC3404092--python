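"""Agent-based model of vertical and oblique cultural transmission.

Each generation: (1) every adult produces one cultural offspring that copies
its parent's skill through the inaccurate transmission process (a draw from
the error family located at ``parent_z - alpha``); (2) each offspring gets
``oblique_rounds`` opportunities to learn from a non-parent adult chosen by a
mentor-selection strategy, adopting the realized copy only if it improves on
its current skill; (3) the offspring replace the adults and the mean skill is
recorded.

Mentor-selection strategies:

``best``
    the most skilled adult (lowest index on ties).
``payoff_proportional``
    among adults strictly more skilled than the learner, with probability
    proportional to the skill difference; skipped when no adult qualifies.
``random``
    uniform over all adults.
``conformity_interval``
    uniform over adults within two skill-scale units of the adult
    generation's (half-sample) mode, i.e. an interval of four scale units;
    skipped when empty.
``conformity_inverse``
    probability inversely proportional to the distance from the mode
    (softened by a small delta to keep weights finite at the mode).

A pure copy-the-best mode (:func:`run_henrich_mode`) with no vertical step
and no adoption filter is provided to validate the analytic model: under a
Gumbel skill distribution its expected per-generation change in mean skill is
exactly ``-alpha + beta * (euler_gamma + ln N)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .analytic import ErrorSpec
from .distributions import (
    Population,
    SkillDistributionSpec,
    _as_rng,
    empirical_mode,
    sample_population,
)

STRATEGY_KINDS = (
    "best",
    "payoff_proportional",
    "random",
    "conformity_interval",
    "conformity_inverse",
)


@dataclass(frozen=True)
class Strategy:
    """Mentor-selection strategy for the oblique-transmission step.

    ``window_halfwidth_in_scales`` only applies to ``conformity_interval``
    (default 2, i.e. a window of four scale units).  ``softening_delta``
    only applies to ``conformity_inverse``; when ``None`` it defaults to
    ``1e-6 * skill_scale`` at selection time.  ``improvement_filter``
    switches the adopt-only-if-better rule (on by default for every kind).
    """

    kind: str
    window_halfwidth_in_scales: float = 2.0
    softening_delta: float | None = None
    improvement_filter: bool = True

    def __post_init__(self) -> None:
        if self.kind not in STRATEGY_KINDS:
            raise ValueError(
                f"unknown strategy {self.kind!r}; expected one of {STRATEGY_KINDS}"
            )
        if not self.window_halfwidth_in_scales > 0:
            raise ValueError("window_halfwidth_in_scales must be positive")
        if self.softening_delta is not None and not self.softening_delta > 0:
            raise ValueError("softening_delta must be positive")


@dataclass(frozen=True)
class ABMConfig:
    """Full configuration of one agent-based run."""

    n: int
    generations: int
    skill: SkillDistributionSpec
    error: ErrorSpec
    strategy: Strategy
    oblique_rounds: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("oblique transmission needs a population of >= 2")
        if self.generations < 0:
            raise ValueError("generations must be non-negative")
        if self.oblique_rounds < 1:
            raise ValueError("oblique_rounds (kappa) must be >= 1")
        if self.skill.family not in ("gumbel", "normal"):
            raise ValueError("the agent-based model simulates gumbel or normal skills")
        if self.error.family != self.skill.family:
            raise ValueError(
                f"error family {self.error.family!r} does not match skill "
                f"family {self.skill.family!r}"
            )

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "generations": self.generations,
            "skill": {
                "family": self.skill.family,
                "location": self.skill.location,
                "scale": self.skill.scale,
            },
            "error": {
                "family": self.error.family,
                "alpha": self.error.alpha,
                "spread": self.error.spread,
            },
            "strategy": {
                "kind": self.strategy.kind,
                "window_halfwidth_in_scales": self.strategy.window_halfwidth_in_scales,
                "softening_delta": self.strategy.softening_delta,
                "improvement_filter": self.strategy.improvement_filter,
            },
            "oblique_rounds": self.oblique_rounds,
            "seed": self.seed,
        }


@dataclass
class Trajectory:
    """Per-generation mean-skill series, including the initial generation."""

    mean_skill: np.ndarray

    def __post_init__(self) -> None:
        self.mean_skill = np.asarray(self.mean_skill, dtype=float)

    def __len__(self) -> int:
        return int(self.mean_skill.size)

    @property
    def generations(self) -> int:
        return len(self) - 1

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"generation": np.arange(len(self)), "mean_skill": self.mean_skill}
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _error_draws(error: ErrorSpec, size: int, rng: np.random.Generator) -> np.ndarray:
    if error.family == "gumbel":
        return rng.gumbel(-error.alpha, error.spread, size=size)
    return rng.normal(-error.alpha, error.spread, size=size)


def transmit(z_model: float, error: ErrorSpec, rng) -> float:
    """One inaccurate copy of a mentor's skill.

    A draw from the error family located at ``z_model - alpha``:
    Gumbel(mode ``z_model - alpha``, scale spread) or
    Normal(mean ``z_model - alpha``, sd spread).
    """
    gen = _as_rng(rng)
    return float(z_model + _error_draws(error, 1, gen)[0])


def vertical_step(parents: Population, error: ErrorSpec, rng) -> Population:
    """Each parent produces one offspring by inaccurate copying."""
    gen = _as_rng(rng)
    values = parents.values + _error_draws(error, len(parents), gen)
    return Population(values=values, generation=parents.generation + 1)


def _conformity_delta(strategy: Strategy, skill_scale: float) -> float:
    if strategy.softening_delta is not None:
        return strategy.softening_delta
    return 1e-6 * skill_scale


def select_oblique_model(
    learner_z: float,
    adults: Population,
    strategy: Strategy,
    skill_scale: float,
    rng,
) -> int | None:
    """Index of the adult chosen as oblique mentor, or ``None`` (step skipped)."""
    gen = _as_rng(rng)
    z = adults.values
    if strategy.kind == "best":
        return int(np.argmax(z))
    if strategy.kind == "random":
        return int(gen.integers(0, z.size))
    if strategy.kind == "payoff_proportional":
        diff = z - learner_z
        mask = diff > 0
        if not mask.any():
            return None
        w = np.where(mask, diff, 0.0)
        return int(gen.choice(z.size, p=w / w.sum()))
    mode = empirical_mode(z)
    if strategy.kind == "conformity_interval":
        half = strategy.window_halfwidth_in_scales * skill_scale
        pool = np.flatnonzero(np.abs(z - mode) <= half)
        if pool.size == 0:
            return None
        return int(pool[gen.integers(0, pool.size)])
    # conformity_inverse
    w = 1.0 / (np.abs(z - mode) + _conformity_delta(strategy, skill_scale))
    return int(gen.choice(z.size, p=w / w.sum()))


def _select_many(
    learner_z: np.ndarray,
    adult_values: np.ndarray,
    strategy: Strategy,
    skill_scale: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized mentor selection; returns -1 where the step is skipped."""
    n = learner_z.size
    m = adult_values.size
    if strategy.kind == "best":
        return np.full(n, int(np.argmax(adult_values)))
    if strategy.kind == "random":
        return rng.integers(0, m, size=n)
    if strategy.kind == "payoff_proportional":
        return _select_payoff(learner_z, adult_values, rng)
    mode = empirical_mode(adult_values)
    if strategy.kind == "conformity_interval":
        half = strategy.window_halfwidth_in_scales * skill_scale
        pool = np.flatnonzero(np.abs(adult_values - mode) <= half)
        if pool.size == 0:
            return np.full(n, -1)
        return pool[rng.integers(0, pool.size, size=n)]
    # conformity_inverse: weights shared by all learners
    w = 1.0 / (np.abs(adult_values - mode) + _conformity_delta(strategy, skill_scale))
    cdf = np.cumsum(w)
    cdf /= cdf[-1]
    return np.searchsorted(cdf, rng.random(n), side="right").clip(0, m - 1)


def _select_payoff(
    learner_z: np.ndarray, adult_values: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Payoff-proportional selection for all learners at once.

    Works on the sorted adult values with prefix sums: for a learner at z the
    total weight over qualified adults (those with value > z) is
    ``(S_M - S_k) - (M - k) * z`` and the cumulative weight is monotone in the
    sorted index, so each learner's draw is located by a vectorized binary
    search instead of an N x N weight matrix.
    """
    m = adult_values.size
    order = np.argsort(adult_values, kind="stable")
    s = adult_values[order]
    prefix = np.concatenate(([0.0], np.cumsum(s)))
    k = np.searchsorted(s, learner_z, side="right")
    total = (prefix[m] - prefix[k]) - (m - k) * learner_z
    has = total > 0
    t = rng.random(learner_z.size) * total
    # first sorted index j (k <= j < m) whose cumulative weight reaches t
    lo = k + 1
    hi = np.full(learner_z.size, m)
    steps = max(1, int(np.ceil(np.log2(max(m, 2)))) + 1)
    for _ in range(steps):
        active = lo < hi
        if not active.any():
            break
        mid = (lo + hi) // 2
        cum = (prefix[mid] - prefix[k]) - (mid - k) * learner_z
        go_left = active & (cum >= t)
        hi = np.where(go_left, mid, hi)
        lo = np.where(active & ~go_left, mid + 1, lo)
    chosen = order[np.clip(lo - 1, 0, m - 1)]
    return np.where(has, chosen, -1)


def oblique_step(
    offspring: Population,
    adults: Population,
    error: ErrorSpec,
    strategy: Strategy,
    oblique_rounds: int = 1,
    rng=None,
    skill_scale: float | None = None,
) -> Population:
    """Oblique-transmission step: select, copy, adopt-if-better.

    Each offspring gets ``oblique_rounds`` (kappa) successive opportunities;
    within each, a mentor is selected, the copy is realized through the error
    model, and (when the strategy's improvement filter is on) adopted only if
    it strictly exceeds the offspring's current skill.  ``skill_scale`` sets
    the conformity window width; it defaults to the error spread (the two
    scales coincide in the standard parameterization).
    """
    if len(offspring) != len(adults):
        raise ValueError("offspring and adult populations must be the same size")
    gen = _as_rng(rng)
    current = offspring.values.copy()
    if skill_scale is None:
        skill_scale = error.spread
    for _ in range(oblique_rounds):
        idx = _select_many(current, adults.values, strategy, skill_scale, gen)
        selected = idx >= 0
        realized = np.where(
            selected,
            adults.values[np.clip(idx, 0, None)] + _error_draws(error, current.size, gen),
            -np.inf,
        )
        if strategy.improvement_filter:
            adopt = selected & (realized > current)
        else:
            adopt = selected
        current = np.where(adopt, realized, current)
    return Population(values=current, generation=offspring.generation)


def run_generations(config: ABMConfig) -> Trajectory:
    """Run the full vertical + oblique + replacement loop.

    Bit-reproducible given ``config.seed``; records the mean skill of every
    generation including the initial one.
    """
    rng = np.random.default_rng(config.seed)
    pop = sample_population(config.skill, config.n, rng)
    means = [pop.mean]
    for _ in range(config.generations):
        offspring = vertical_step(pop, config.error, rng)
        offspring = oblique_step(
            offspring, pop, config.error, config.strategy,
            config.oblique_rounds, rng, skill_scale=config.skill.scale,
        )
        pop = offspring
        means.append(pop.mean)
    return Trajectory(mean_skill=np.asarray(means))


def run_henrich_mode(
    n: int,
    error: ErrorSpec,
    skill: SkillDistributionSpec,
    generations: int,
    rng,
    keep_populations: bool = False,
):
    """Pure copy-the-best dynamics: every learner copies the current maximum.

    No vertical step and no adoption filter; under Gumbel skills the
    population stays Gumbel with unchanged scale and the expected
    per-generation change in mean skill equals the analytic ``delta_zbar``.
    With ``keep_populations`` the full per-generation populations are
    returned alongside the trajectory (for distribution-shape diagnostics).
    """
    if n < 1:
        raise ValueError("population size must be >= 1")
    gen = _as_rng(rng)
    pop = sample_population(skill, n, gen)
    means = [pop.mean]
    populations = [pop]
    for _ in range(generations):
        zh = pop.max
        values = zh + _error_draws(error, n, gen)
        pop = Population(values=values, generation=pop.generation + 1)
        means.append(pop.mean)
        if keep_populations:
            populations.append(pop)
    trajectory = Trajectory(mean_skill=np.asarray(means))
    if keep_populations:
        return trajectory, populations
    return trajectory
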