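import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hmaxga import (
    GAConfig,
    init_population,
    mutate,
    rank_select,
    run_ga,
    uniform_crossover,
)

from _oracles import exhaustive_best_subset


def additive_fitness(weights):
    """Separable fitness: F = 0.5 + sum(w_i b_i); minimum at {i : w_i < 0}."""
    weights = np.asarray(weights, dtype=float)

    def fitness(bits):
        return float(0.5 + (weights * bits).sum())

    return fitness


class TestInitPopulation:
    def test_default_geometry_20_by_200(self):
        pop = init_population(200, GAConfig(seed=0))
        assert pop.shape == (20, 200)
        assert set(np.unique(pop)) <= {0, 1}

    def test_seed_reproducibility(self):
        a = init_population(50, GAConfig(seed=7))
        b = init_population(50, GAConfig(seed=7))
        c = init_population(50, GAConfig(seed=8))
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_no_all_zero_individuals(self):
        # tiny chromosomes + low density make all-zero draws likely
        cfg = GAConfig(seed=3, init_density=0.05, pop_size=50)
        pop = init_population(3, cfg)
        assert (pop.sum(axis=1) >= 1).all()

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            init_population(0, GAConfig())


class TestRankSelect:
    def test_frequencies_match_linear_rank_weights(self, rng):
        pop = np.eye(5, dtype=np.uint8)
        fits = [0.1, 0.5, 0.3, 0.9, 0.7]  # ranks: 0 best ... 3 worst
        n_draws = 10_000
        parents = rank_select(pop, fits, n_draws, rng)
        counts = np.zeros(5)
        for p in parents:
            counts[int(np.argmax(p))] += 1
        weights = np.array([5, 3, 4, 1, 2], dtype=float)
        expected = weights / weights.sum()
        freq = counts / n_draws
        sd = np.sqrt(expected * (1 - expected) / n_draws)
        assert (np.abs(freq - expected) < 4 * sd).all()
        assert counts[0] == counts.max()

    def test_equal_fitness_is_near_uniform(self, rng):
        pop = np.eye(4, dtype=np.uint8)
        parents = rank_select(pop, [0.5] * 4, 8000, rng)
        counts = np.zeros(4)
        for p in parents:
            counts[int(np.argmax(p))] += 1
        assert (np.abs(counts / 8000 - 0.25) < 0.03).all()

    def test_returns_k_copies(self, rng):
        pop = np.ones((3, 6), dtype=np.uint8)
        parents = rank_select(pop, [0.1, 0.2, 0.3], 5, rng)
        assert len(parents) == 5
        parents[0][0] = 0
        assert pop[0, 0] == 1  # copies, not views


class TestUniformCrossover:
    def test_identical_parents_unchanged(self, rng):
        a = np.array([1, 0, 1, 1, 0], dtype=np.uint8)
        ca, cb = uniform_crossover(a, a.copy(), rng)
        assert np.array_equal(ca, a) and np.array_equal(cb, a)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(bits=st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)),
                         min_size=1, max_size=64),
           seed=st.integers(0, 2**20))
    def test_per_position_bits_conserved(self, bits, seed):
        a = np.array([p[0] for p in bits], dtype=np.uint8)
        b = np.array([p[1] for p in bits], dtype=np.uint8)
        ca, cb = uniform_crossover(a, b, np.random.default_rng(seed))
        assert np.array_equal(ca + cb, a + b)

    def test_zero_swap_probability_copies_parents(self, rng):
        a = np.array([1, 1, 0, 0], dtype=np.uint8)
        b = np.array([0, 1, 1, 0], dtype=np.uint8)
        ca, cb = uniform_crossover(a, b, rng, p_swap=0.0)
        assert np.array_equal(ca, a) and np.array_equal(cb, b)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            uniform_crossover(np.zeros(3, dtype=np.uint8),
                              np.zeros(4, dtype=np.uint8), rng)


class TestMutate:
    def test_rate_zero_is_identity(self, rng):
        c = np.array([1, 0, 1], dtype=np.uint8)
        assert np.array_equal(mutate(c, 0.0, rng), c)

    def test_rate_one_complements(self, rng):
        c = np.array([1, 0, 1, 0], dtype=np.uint8)
        assert np.array_equal(mutate(c, 1.0, rng), 1 - c)

    def test_all_zero_guard(self, rng):
        c = np.array([1], dtype=np.uint8)
        out = mutate(c, 1.0, rng)  # complement would be all-zero; re-mutated
        assert out.any()

    def test_expected_flip_count_binomial(self):
        rng = np.random.default_rng(99)
        n, rate, trials = 200, 1 / 200, 10_000
        base = np.zeros(n, dtype=np.uint8)
        base[:100] = 1
        flips = np.empty(trials)
        for t in range(trials):
            flips[t] = int((mutate(base, rate, rng) != base).sum())
        mean = flips.mean()
        se = flips.std(ddof=1) / np.sqrt(trials)
        assert abs(mean - 1.0) < 3 * se + 1e-9


class TestRunGA:
    def test_matches_exhaustive_search_on_separable_problem(self):
        weights = np.random.default_rng(17).uniform(-0.03, 0.03, 10)
        fitness = additive_fitness(weights)
        best_f, _ = exhaustive_best_subset(10, fitness)
        cfg = GAConfig(seed=5, max_generations=80, stagnation_patience=25)
        result = run_ga(10, fitness, cfg)
        assert abs(result.best_fitness - best_f) < 1e-12

    def test_elitist_history_non_increasing(self):
        fitness = additive_fitness(
            np.random.default_rng(2).uniform(-0.05, 0.05, 30))
        result = run_ga(30, fitness, GAConfig(seed=1, max_generations=40))
        hist = np.array(result.fitness_history)
        assert (np.diff(hist) <= 0).all()
        assert result.best_fitness == hist[-1]

    def test_same_seed_identical_results(self):
        fitness = additive_fitness(
            np.random.default_rng(3).uniform(-0.05, 0.05, 25))
        cfg = GAConfig(seed=11, max_generations=30)
        a = run_ga(25, fitness, cfg)
        b = run_ga(25, fitness, cfg)
        assert np.array_equal(a.best_chromosome, b.best_chromosome)
        assert a.fitness_history == b.fitness_history
        assert np.array_equal(a.final_population, b.final_population)

    def test_population_size_constant_and_no_empty_individuals(self):
        fitness = additive_fitness(
            np.random.default_rng(4).uniform(-0.05, 0.05, 15))
        result = run_ga(15, fitness, GAConfig(seed=2, max_generations=20))
        assert result.final_population.shape == (20, 15)
        assert result.initial_population.shape == (20, 15)
        assert (result.final_population.sum(axis=1) >= 1).all()

    def test_stagnation_stops_early(self):
        result = run_ga(8, lambda bits: 0.5,
                        GAConfig(seed=0, max_generations=100,
                                 stagnation_patience=5))
        assert result.n_generations == 5
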