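"""Agent-based model: transmission steps, mentor selection, full runs."""

import math

import numpy as np
import pytest

from cumculture.abm import (
    ABMConfig,
    Strategy,
    _select_many,
    oblique_step,
    run_generations,
    run_henrich_mode,
    select_oblique_model,
    transmit,
    vertical_step,
)
from cumculture.analytic import ErrorSpec
from cumculture.distributions import (
    EULER_GAMMA,
    Population,
    SkillDistributionSpec,
)

GUMBEL_SKILL = SkillDistributionSpec("gumbel", 0, 1)


class TestTransmit:
    @pytest.mark.parametrize("family", ["gumbel", "normal"])
    def test_degenerate_spread_gives_model_minus_alpha(self, family, rng):
        got = transmit(5.0, ErrorSpec(family, 1.0, 1e-12), rng)
        assert got == pytest.approx(4.0, abs=1e-9)

    def test_gumbel_error_mean_worked_example(self, rng):
        """alpha=0.1, beta=0.1: expected imitation error is about -0.042."""
        draws = np.array(
            [transmit(0.0, ErrorSpec("gumbel", 0.1, 0.1), rng) for _ in range(2000)]
        )
        # scalar path sanity at 3 SE; the tight check runs on the vector path
        se = draws.std(ddof=1) / math.sqrt(draws.size)
        assert abs(draws.mean() - (-0.1 + 0.1 * EULER_GAMMA)) < 3 * se

    def test_normal_error_mean_is_minus_alpha(self, rng):
        pop = Population(np.zeros(100_000))
        out = vertical_step(pop, ErrorSpec("normal", 0.5, 1.0), rng)
        se = out.values.std(ddof=1) / math.sqrt(len(out))
        assert abs(out.values.mean() + 0.5) < 3 * se


class TestVerticalStep:
    def test_single_parent_degenerate(self, rng):
        out = vertical_step(Population([3.0]), ErrorSpec("gumbel", 1.0, 1e-12), rng)
        assert out.values[0] == pytest.approx(2.0, abs=1e-9)

    def test_mean_shift_matches_error_mean(self, rng):
        pop = Population(rng.normal(size=100_000))
        error = ErrorSpec("gumbel", 1.0, 1.0)
        out = vertical_step(pop, error, rng)
        diff = out.values - pop.values
        se = diff.std(ddof=1) / math.sqrt(diff.size)
        assert abs(diff.mean() - error.mean) < 3 * se

    @pytest.mark.parametrize("n", [1, 7, 100])
    def test_size_and_generation(self, n, rng):
        pop = Population(np.zeros(n), generation=4)
        out = vertical_step(pop, ErrorSpec("gumbel", 1.0, 1.0), rng)
        assert len(out) == n and out.generation == 5


class TestSelectObliqueModel:
    def test_payoff_single_candidate_is_certain(self, rng):
        adults = Population([1.0, 2.0, 3.0])
        got = select_oblique_model(2.5, adults, Strategy("payoff_proportional"), 1.0, rng)
        assert got == 2

    def test_payoff_no_candidate_skips(self, rng):
        adults = Population([1.0, 2.0, 3.0])
        assert (
            select_oblique_model(5.0, adults, Strategy("payoff_proportional"), 1.0, rng)
            is None
        )

    def test_best_is_argmax_first_on_ties(self, rng):
        adults = Population([1.0, 7.0, 7.0, 2.0])
        assert select_oblique_model(0.0, adults, Strategy("best"), 1.0, rng) == 1

    def test_random_is_uniform(self, rng):
        adults = np.array([1.0, 2.0, 3.0])
        idx = _select_many(np.zeros(100_000), adults, Strategy("random"), 1.0, rng)
        freqs = np.bincount(idx, minlength=3) / idx.size
        se = math.sqrt((1 / 3) * (2 / 3) / idx.size)
        assert np.all(np.abs(freqs - 1 / 3) < 3 * se)

    def test_conformity_inverse_rarely_picks_outlier(self, rng):
        """Weight ratio delta/(10+delta) bounds the outlier frequency."""
        adults = np.array([0.0, 0.0, 0.0, 10.0])
        strategy = Strategy("conformity_inverse", softening_delta=1e-6)
        idx = _select_many(np.zeros(100_000), adults, strategy, 1.0, rng)
        assert np.mean(idx == 3) < 1e-5

    def test_conformity_interval_restricts_to_window(self, rng):
        # mode of the adults is 0; window is +/- 2 scales
        adults = Population([0.0, 0.0, 0.1, 1.9, 2.5, 30.0])
        for _ in range(50):
            got = select_oblique_model(
                0.0, adults, Strategy("conformity_interval"), 1.0, rng
            )
            assert got in {0, 1, 2, 3}

    def test_scalar_and_vector_payoff_agree_in_distribution(self, rng):
        adults = np.array([0.0, 1.0, 2.0, 4.0])
        learner = 0.5
        vec = _select_many(
            np.full(50_000, learner), adults, Strategy("payoff_proportional"), 1.0, rng
        )
        w = np.clip(adults - learner, 0, None)
        expected = w / w.sum()
        freqs = np.bincount(vec, minlength=4) / vec.size
        se = np.sqrt(expected * (1 - expected) / vec.size)
        assert np.all(np.abs(freqs - expected) <= 3 * se + 1e-12)


class TestObliqueStep:
    def test_forced_adoption_from_best(self, rng):
        offspring = Population(np.zeros(3), generation=1)
        adults = Population([1.0, 10.0, 2.0])
        out = oblique_step(
            offspring, adults, ErrorSpec("gumbel", 1.0, 1e-12), Strategy("best"), 1, rng
        )
        np.testing.assert_allclose(out.values, 9.0, atol=1e-9)

    def test_unqualified_pool_leaves_offspring_unchanged(self, rng):
        offspring = Population([5.0, 6.0])
        adults = Population([1.0, 2.0])
        out = oblique_step(
            offspring, adults, ErrorSpec("gumbel", 1.0, 1.0),
            Strategy("payoff_proportional"), 1, rng,
        )
        np.testing.assert_array_equal(out.values, offspring.values)

    @pytest.mark.parametrize("kind", [
        "best", "payoff_proportional", "random",
        "conformity_interval", "conformity_inverse",
    ])
    def test_adoption_never_lowers_skill(self, kind, rng):
        offspring = Population(rng.normal(size=200))
        adults = Population(rng.normal(size=200))
        out = oblique_step(
            offspring, adults, ErrorSpec("gumbel", 1.0, 1.0), Strategy(kind), 3, rng
        )
        assert np.all(out.values >= offspring.values)

    def test_filter_off_can_lower_skill(self, rng):
        offspring = Population(np.full(500, 10.0))
        adults = Population(np.zeros(500))
        strategy = Strategy("random", improvement_filter=False)
        out = oblique_step(
            offspring, adults, ErrorSpec("gumbel", 1.0, 0.1), strategy, 1, rng
        )
        assert np.all(out.values < offspring.values)

    def test_size_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            oblique_step(
                Population([1.0]), Population([1.0, 2.0]),
                ErrorSpec("gumbel", 1.0, 1.0), Strategy("random"), 1, rng,
            )


class TestRunGenerations:
    def _config(self, **kwargs):
        base = dict(
            n=50, generations=20, skill=GUMBEL_SKILL,
            error=ErrorSpec("gumbel", 1.0, 1.0),
            strategy=Strategy("payoff_proportional"), seed=11,
        )
        base.update(kwargs)
        return ABMConfig(**base)

    def test_zero_generations_records_initial_mean(self):
        traj = run_generations(self._config(generations=0))
        assert len(traj) == 1

    def test_identical_seeds_identical_trajectories(self):
        a = run_generations(self._config())
        b = run_generations(self._config())
        np.testing.assert_array_equal(a.mean_skill, b.mean_skill)

    def test_distinct_seeds_differ(self):
        a = run_generations(self._config())
        b = run_generations(self._config(seed=12))
        assert not np.array_equal(a.mean_skill, b.mean_skill)

    def test_best_strategy_accumulates_below_critical(self):
        """alpha=1 is far below the N=250 critical value (~6.1): the mean
        skill trend is positive in at least 9 of 10 replicates."""
        rising = 0
        for seed in range(10):
            cfg = self._config(
                n=250, generations=50, strategy=Strategy("best"), seed=seed
            )
            traj = run_generations(cfg)
            slope = np.polyfit(np.arange(len(traj)), traj.mean_skill, 1)[0]
            rising += slope > 0
        assert rising >= 9

    def test_config_validation(self):
        with pytest.raises(ValueError):
            self._config(n=1)
        with pytest.raises(ValueError):
            self._config(skill=SkillDistributionSpec("logistic"))
        with pytest.raises(ValueError):
            self._config(error=ErrorSpec("normal", 1.0, 1.0))
        with pytest.raises(ValueError):
            self._config(oblique_rounds=0)

    def test_kappa_two_never_below_kappa_one_on_average(self):
        """Doubling oblique opportunities cannot hurt mean final skill."""
        finals = {}
        for kappa in (1, 2):
            vals = [
                run_generations(
                    self._config(oblique_rounds=kappa, seed=s, generations=30)
                ).mean_skill[-1]
                for s in range(12)
            ]
            finals[kappa] = np.mean(vals)
        assert finals[2] >= finals[1]

    def test_trajectory_csv_roundtrip(self, tmp_path):
        traj = run_generations(self._config(generations=5))
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        assert path.read_text().splitlines()[0] == "generation,mean_skill"
        assert len(path.read_text().splitlines()) == 7  # header + 6 rows


class TestRunHenrichMode:
    def test_mean_change_matches_closed_form(self):
        rng = np.random.default_rng(5)
        error = ErrorSpec("gumbel", 3.0, 1.0)
        traj = run_henrich_mode(100, error, GUMBEL_SKILL, 2000, rng)
        d = np.diff(traj.mean_skill)
        se = d.std(ddof=1) / math.sqrt(d.size)
        expected = -3.0 + EULER_GAMMA + math.log(100)
        assert abs(d.mean() - expected) < 3 * se

    def test_critical_alpha_gives_zero_drift(self):
        rng = np.random.default_rng(6)
        alpha = math.log(100) + EULER_GAMMA
        traj = run_henrich_mode(
            100, ErrorSpec("gumbel", alpha, 1.0), GUMBEL_SKILL, 4000, rng
        )
        d = np.diff(traj.mean_skill)
        se = d.std(ddof=1) / math.sqrt(d.size)
        assert abs(d.mean()) < 3 * se

    def test_population_keeps_gumbel_scale(self):
        """Copying the max re-creates a Gumbel of unchanged scale: the
        moment-based scale estimate shows no drift across 100 generations."""
        rng = np.random.default_rng(7)
        n, beta = 400, 1.0
        skill = SkillDistributionSpec("gumbel", 0, beta)
        error = ErrorSpec("gumbel", 2.0, beta)
        _, pops = run_henrich_mode(n, error, skill, 100, rng, keep_populations=True)
        scales = np.asarray(
            [p.values.std(ddof=1) * math.sqrt(6) / math.pi for p in pops[1:]]
        )
        first, last = scales[:50], scales[50:]
        se = math.sqrt(first.var(ddof=1) / 50 + last.var(ddof=1) / 50)
        assert abs(first.mean() - last.mean()) < 3 * se
        assert abs(scales.mean() - beta) < 0.05


class TestStrategyDominance:
    def test_best_beats_payoff_beats_random(self):
        """Mean final skill orders best >= payoff-proportional >= random,
        each gap significant at 3 SE over 30 replicates."""
        finals = {}
        for kind in ("best", "payoff_proportional", "random"):
            vals = []
            for seed in range(30):
                cfg = ABMConfig(
                    n=60, generations=30, skill=GUMBEL_SKILL,
                    error=ErrorSpec("gumbel", 1.0, 1.0),
                    strategy=Strategy(kind), seed=seed,
                )
                vals.append(run_generations(cfg).mean_skill[-1])
            finals[kind] = (np.mean(vals), np.var(vals, ddof=1) / len(vals))

        # each gap tested at 3 SE of the difference of replicate means
        for hi, lo in (
            ("best", "payoff_proportional"),
            ("payoff_proportional", "random"),
        ):
            gap = finals[hi][0] - finals[lo][0]
            se = math.sqrt(finals[hi][1] + finals[lo][1])
            assert gap > 3 * se
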