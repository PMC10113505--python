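"""Optimizer tests: update equations vs a literal transcription oracle,
bound preservation, monotone best-ever tracking, seeded reproducibility,
checkpoint resume, and equal-budget dominance over random search."""

import numpy as np
import pytest

from sparrowtune.fixtures import benchmark_objective
from sparrowtune.spasa import (
    Population,
    SpaSAConfig,
    SparrowSearchOptimizer,
    UpdateRandoms,
    full_update,
    initialize_population,
    optimize,
    sort_and_extract,
    update_discoverers,
    update_followers,
    update_scouts,
)


def reference_full_update(solutions, scores, cfg, t, R):
    """Independent, literal loop transcription of the three update phases.

    Written scalar-by-scalar from the published pseudocode: sort is assumed
    done (solutions best-first), best/worst/optimal extracted up front,
    producers then followers then scouts updated in place, everything
    clamped into [0, 1].
    """
    sol = [np.array(row, dtype=float) for row in solutions]
    n = len(sol)
    d = len(sol[0])
    pd = max(1, round(cfg.producer_ratio * n))
    sd = max(1, round(cfg.scout_ratio * n))
    best = sol[0].copy()
    worst = sol[n - 1].copy()
    optimal = sol[0].copy()
    best_score = scores[0]
    worst_score = scores[n - 1]
    clamp = lambda v: np.minimum(1.0, np.maximum(0.0, v))
    i = 1
    while i <= pd:
        if R.r2 < cfg.safety_threshold:
            sol[i - 1] = sol[i - 1] * np.exp(
                -t / (R.alphas[i - 1] * cfg.max_iterations)
            )
        else:
            sol[i - 1] = sol[i - 1] + R.q_producers[i - 1]
        sol[i - 1] = clamp(sol[i - 1])
        i += 1
    k = 1
    while k <= n - pd:
        i = pd + k  # population position of this follower
        if i > 0.5 * n:
            sol[i - 1] = R.q_followers[k - 1] * np.exp(
                (worst - sol[i - 1]) / (i * i)
            )
        else:
            sol[i - 1] = optimal + np.abs(sol[i - 1] - optimal) * (
                R.a_signs[k - 1] / d
            )
        sol[i - 1] = clamp(sol[i - 1])
        k += 1
    j = 0
    while j < sd:
        idx = R.scout_indices[j]
        if scores[idx] != best_score:
            sol[idx] = best + R.betas[j] * np.abs(sol[idx] - best)
        else:
            sol[idx] = sol[idx] + R.ks[j] * (
                np.abs(sol[idx] - worst) / ((scores[idx] - worst_score) + cfg.epsilon)
            )
        sol[idx] = clamp(sol[idx])
        j += 1
    return np.array(sol)


def _sorted_population(rng, n, d, maximize=True):
    pop = Population(solutions=rng.uniform(0, 1, (n, d)))
    pop.scores = rng.uniform(0, 1, n)
    return sort_and_extract(pop, maximize)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"population_size": 1},
            {"max_iterations": 0},
            {"producer_ratio": 0.0},
            {"producer_ratio": 0.7, "scout_ratio": 0.5},
            {"safety_threshold": 0.4},
            {"epsilon": 0.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SpaSAConfig(**kwargs)


class TestInitialization:
    def test_shape_and_range(self):
        cfg = SpaSAConfig(population_size=10, seed=0)
        pop = initialize_population(cfg, 15)
        assert pop.solutions.shape == (10, 15)
        assert np.all(pop.solutions >= 0) and np.all(pop.solutions <= 1)

    def test_seeded_determinism(self):
        cfg = SpaSAConfig(population_size=5, seed=42)
        a = initialize_population(cfg, 7)
        b = initialize_population(cfg, 7)
        np.testing.assert_array_equal(a.solutions, b.solutions)

    def test_matches_independent_rng_stream(self):
        # N=2, D=1: entries must equal a direct re-draw of the same stream
        cfg = SpaSAConfig(population_size=2, seed=123)
        pop = initialize_population(cfg, 1)
        expected = np.random.default_rng(123).uniform(0, 1, (2, 1))
        np.testing.assert_array_equal(pop.solutions, expected)

    def test_invalid_dimension(self):
        with pytest.raises(ValueError):
            initialize_population(SpaSAConfig(seed=0), 0)


class TestSortAndExtract:
    def test_three_element_sort(self):
        pop = Population(solutions=np.array([[0.1], [0.2], [0.3]]))
        pop.scores = np.array([0.2, 0.9, 0.5])
        out = sort_and_extract(pop, maximize=True)
        np.testing.assert_array_equal(out.scores, [0.9, 0.5, 0.2])
        assert out.best_score == 0.9 and out.worst_score == 0.2
        np.testing.assert_array_equal(out.best, [0.2])
        np.testing.assert_array_equal(out.worst, [0.1])

    def test_stable_on_ties(self):
        pop = Population(solutions=np.arange(4)[:, None] / 4.0)
        pop.scores = np.full(4, 0.5)
        out = sort_and_extract(pop, maximize=True)
        np.testing.assert_array_equal(out.solutions, pop.solutions)

    def test_first_equals_bruteforce_max(self, rng):
        pop = Population(solutions=rng.uniform(0, 1, (20, 3)))
        pop.scores = rng.uniform(0, 1, 20)
        out = sort_and_extract(pop, maximize=True)
        assert out.best_score == max(pop.scores)
        assert out.worst_score == min(pop.scores)

    def test_missing_scores_is_state_error(self):
        pop = Population(solutions=np.zeros((3, 2)))
        with pytest.raises(RuntimeError):
            sort_and_extract(pop)


class TestUpdateBranches:
    """Closed-form checks on individual update branches."""

    def _randoms(self, cfg, d, rng):
        return UpdateRandoms.draw(rng, cfg, d)

    def test_discoverers_unchanged_when_alarm_high_and_q_zero(self, rng):
        cfg = SpaSAConfig(population_size=10, max_iterations=5, seed=0)
        pop = _sorted_population(rng, 10, 4)
        R = self._randoms(cfg, 4, rng)
        R.r2 = 0.99  # >= ST: relocation branch
        R.q_producers[:] = 0.0
        out = update_discoverers(pop, cfg, t=1, randoms=R)
        np.testing.assert_array_equal(out.solutions, pop.solutions)

    def test_discoverer_decay_closed_form(self, rng):
        cfg = SpaSAConfig(population_size=10, max_iterations=7, seed=0)
        pop = _sorted_population(rng, 10, 4)
        R = self._randoms(cfg, 4, rng)
        R.r2 = 0.0  # < ST
        R.alphas[:] = 1.0
        out = update_discoverers(pop, cfg, t=7, randoms=R)
        n_prod = cfg.n_producers
        np.testing.assert_allclose(
            out.solutions[:n_prod], pop.solutions[:n_prod] * np.exp(-1.0)
        )
        np.testing.assert_array_equal(out.solutions[n_prod:], pop.solutions[n_prod:])

    def test_follower_at_optimal_is_fixed_point(self, rng):
        cfg = SpaSAConfig(population_size=10, seed=0)
        pop = _sorted_population(rng, 10, 4)
        n_prod = cfg.n_producers
        pop.solutions[n_prod] = pop.producer_best  # first follower (i <= N/2)
        R = self._randoms(cfg, 4, rng)
        out = update_followers(pop, cfg, randoms=R)
        np.testing.assert_allclose(out.solutions[n_prod], pop.producer_best)

    def test_follower_exponent_zero_case(self, rng):
        # for i > N/2 and worst == solution, the update is the clamped Q draw
        cfg = SpaSAConfig(population_size=10, seed=0)
        pop = _sorted_population(rng, 10, 4)
        pop.solutions[9] = pop.worst
        R = self._randoms(cfg, 4, rng)
        out = update_followers(pop, cfg, randoms=R)
        expected = np.clip(R.q_followers[9 - cfg.n_producers], 0, 1)
        np.testing.assert_allclose(out.solutions[9], expected)

    def test_scout_zero_beta_jumps_to_best(self, rng):
        cfg = SpaSAConfig(population_size=10, seed=0)
        pop = _sorted_population(rng, 10, 4)
        R = self._randoms(cfg, 4, rng)
        R.betas[:] = 0.0
        R.scout_indices = np.array([5, 7])[: cfg.n_scouts]
        out = update_scouts(pop, cfg, randoms=R)
        for idx in R.scout_indices:
            np.testing.assert_allclose(out.solutions[idx], pop.best)

    def test_scout_at_best_with_flat_scores_stays_in_bounds(self, rng):
        # f_i == f_w: step magnitude |X - worst| K / eps, clamp dominates
        cfg = SpaSAConfig(population_size=10, seed=0)
        pop = Population(solutions=rng.uniform(0, 1, (10, 4)))
        pop.scores = np.full(10, 0.3)
        pop = sort_and_extract(pop, True)
        R = self._randoms(cfg, 4, rng)
        out = update_scouts(pop, cfg, randoms=R)
        assert np.all(out.solutions >= 0) and np.all(out.solutions <= 1)


class TestOracleEquivalence:
    """Each full update agrees with the literal transcription on random
    instances (producers, followers and scouts all exercised)."""

    @pytest.mark.parametrize("case", range(100))
    def test_full_update_matches_transcription(self, case):
        rng = np.random.default_rng(1000 + case)
        n = int(rng.integers(4, 16))
        d = int(rng.integers(2, 16))
        cfg = SpaSAConfig(
            population_size=n,
            max_iterations=int(rng.integers(1, 20)),
            producer_ratio=float(rng.uniform(0.1, 0.4)),
            scout_ratio=float(rng.uniform(0.1, 0.4)),
            safety_threshold=float(rng.uniform(0.5, 1.0)),
        )
        t = int(rng.integers(1, cfg.max_iterations + 1))
        pop = _sorted_population(rng, n, d)
        R = UpdateRandoms.draw(rng, cfg, d)
        ours = full_update(pop, cfg, t, R)
        ref = reference_full_update(pop.solutions, pop.scores, cfg, t, R)
        np.testing.assert_allclose(ours.solutions, ref, atol=1e-12)


class TestInvariants:
    def test_bound_preservation_fuzzed(self):
        """All elements stay in [0, 1] over 1,000 fuzzed update calls."""
        rng = np.random.default_rng(7)
        for _ in range(1000):
            n = int(rng.integers(4, 12))
            d = int(rng.integers(1, 10))
            cfg = SpaSAConfig(population_size=n, max_iterations=10)
            pop = _sorted_population(rng, n, d)
            t = int(rng.integers(1, 11))
            out = full_update(pop, cfg, t, UpdateRandoms.draw(rng, cfg, d))
            assert np.all(out.solutions >= 0.0)
            assert np.all(out.solutions <= 1.0)

    def test_best_ever_monotone(self):
        obj = benchmark_objective("rastrigin", 6)
        cfg = SpaSAConfig(population_size=10, max_iterations=30, seed=3, maximize=False)
        res = optimize(obj, cfg, 6)
        assert all(b <= a for a, b in zip(res.history, res.history[1:]))

    def test_seeded_history_bitwise_identical(self):
        obj = benchmark_objective("sphere", 5)
        cfg = SpaSAConfig(population_size=8, max_iterations=15, seed=9, maximize=False)
        r1 = optimize(obj, cfg, 5)
        r2 = optimize(obj, cfg, 5)
        assert r1.history == r2.history
        np.testing.assert_array_equal(r1.best_solution, r2.best_solution)

    def test_equal_budget_dominance(self):
        """Median final value over 20 seeds beats uniform random search with
        the same evaluation budget, on sphere and Rastrigin (D=10, N=20,
        T=100, 2,000 evaluations each)."""
        for name in ("sphere", "rastrigin"):
            obj = benchmark_objective(name, 10)
            spasa_final, rs_final = [], []
            for seed in range(20):
                cfg = SpaSAConfig(
                    population_size=20, max_iterations=100, seed=seed, maximize=False
                )
                spasa_final.append(optimize(obj, cfg, 10).best_score)
                rs_rng = np.random.default_rng(10_000 + seed)
                rs_final.append(
                    min(obj(x) for x in rs_rng.uniform(0, 1, (2000, 10)))
                )
            assert np.median(spasa_final) <= np.median(rs_final)


class TestOptimize:
    def test_constant_fitness(self):
        cfg = SpaSAConfig(population_size=5, max_iterations=3, seed=0)
        res = optimize(lambda x: 0.7, cfg, 4)
        assert res.best_score == 0.7
        assert res.n_evaluations == 15

    def test_target_vector_convergence(self):
        """Median over 10 seeds of the worst coordinate error is within
        0.15 of the target (and must not lose to equal-budget random
        search)."""
        obj = benchmark_objective("target-vector", 5)
        errs, spasa_best, rs_best = [], [], []
        for seed in range(10):
            cfg = SpaSAConfig(
                population_size=20, max_iterations=50, seed=seed, maximize=True
            )
            res = optimize(obj, cfg, 5)
            errs.append(np.abs(res.best_solution - obj.optimum_location).max())
            spasa_best.append(res.best_score)
            rs_rng = np.random.default_rng(20_000 + seed)
            rs_best.append(max(obj(x) for x in rs_rng.uniform(0, 1, (1000, 5))))
        assert np.median(errs) <= 0.15
        assert np.median(spasa_best) >= np.median(rs_best)

    def test_minimization_improves_over_initial(self):
        obj = benchmark_objective("sphere", 10)
        cfg = SpaSAConfig(population_size=10, max_iterations=20, seed=4, maximize=False)
        res = optimize(obj, cfg, 10)
        assert res.best_score <= res.history[0]

    def test_fitness_error_reports_context(self):
        def bad(x):
            raise ValueError("boom")

        cfg = SpaSAConfig(population_size=4, max_iterations=2, seed=0)
        with pytest.raises(RuntimeError, match="iteration 1, solution index 0"):
            optimize(bad, cfg, 3)


class TestCheckpointResume:
    def test_resume_reproduces_uninterrupted_run(self):
        obj = benchmark_objective("rastrigin", 8)
        cfg = SpaSAConfig(population_size=10, max_iterations=20, seed=21, maximize=False)
        full = SparrowSearchOptimizer(cfg, 8).run(obj)

        opt = SparrowSearchOptimizer(cfg, 8)
        for _ in range(7):
            opt.step(obj)
        payload = opt.to_json()
        resumed = SparrowSearchOptimizer.from_json(payload).run(obj)
        assert resumed.history == full.history
        np.testing.assert_array_equal(resumed.best_solution, full.best_solution)
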