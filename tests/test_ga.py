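import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaselect import ConfigurationError, GAConfig, Population, run_ga
from gaselect.fitness import FitnessSpec
from gaselect.ga import (
    GARandomStreams,
    crossover_pair,
    double_point_crossover,
    init_population,
    mutate,
    next_generation,
    select_parents,
    selection_probabilities,
    single_point_crossover,
)


def _streams(seed=0):
    return GARandomStreams.from_master_seed(seed)


class TestInitPopulation:
    def test_shape_and_binary(self):
        pop = init_population(10, 100, np.random.default_rng(0))
        assert pop.members.shape == (100, 10)
        assert set(np.unique(pop.members)) <= {0, 1}

    def test_fair_coin_bits(self):
        # binomial(d, 1/2) oracle on the mean popcount
        d, n = 20, 10_000
        pop = init_population(d, n, np.random.default_rng(1))
        mean_popcount = pop.members.sum(axis=1).mean()
        se = np.sqrt(d * 0.25 / n)
        assert abs(mean_popcount - d / 2) < 3 * se

    def test_deterministic(self):
        a = init_population(8, 30, np.random.default_rng(5))
        b = init_population(8, 30, np.random.default_rng(5))
        np.testing.assert_array_equal(a.members, b.members)

    def test_zero_length_rejected(self):
        with pytest.raises(ConfigurationError):
            init_population(0, 10, np.random.default_rng(0))


class TestSelectionProbabilities:
    def test_proportionality_hand_computed(self):
        np.testing.assert_allclose(
            selection_probabilities([0.6, 0.9, 0.5]), [0.30, 0.45, 0.25]
        )

    def test_symmetry(self):
        np.testing.assert_allclose(
            selection_probabilities([0.8] * 4), [0.25] * 4
        )

    def test_single_member(self):
        np.testing.assert_allclose(selection_probabilities([0.73]), [1.0])

    def test_all_zero_fallback_uniform(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="gaselect.ga"):
            p = selection_probabilities([0.0, 0.0, 0.0])
        np.testing.assert_allclose(p, [1 / 3] * 3)
        assert caplog.records

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=50)
    )
    @settings(deadline=None, max_examples=200)
    def test_sums_to_one_and_order_preserved(self, fitnesses):
        p = selection_probabilities(fitnesses)
        assert abs(p.sum() - 1.0) < 1e-12
        assert np.all(p >= 0)
        f = np.asarray(fitnesses)
        if f.sum() > 0:
            # probabilities ordered identically to fitnesses
            for i in range(len(f)):
                for j in range(len(f)):
                    if f[i] < f[j]:
                        assert p[i] < p[j] or np.isclose(p[i], p[j])


class TestSelectParents:
    def test_degenerate_distribution(self):
        pop = Population(np.array([[1, 1], [0, 0]], dtype=np.uint8))
        rng = np.random.default_rng(0)
        for _ in range(10):
            a, b = select_parents(pop, np.array([1.0, 0.0]), rng)
            np.testing.assert_array_equal(a, [1, 1])
            np.testing.assert_array_equal(b, [1, 1])

    def test_empirical_frequencies(self):
        pop = Population(np.eye(3, dtype=np.uint8))
        probs = np.array([0.3, 0.45, 0.25])
        rng = np.random.default_rng(2)
        n = 50_000
        counts = np.zeros(3)
        for _ in range(n):
            a, b = select_parents(pop, probs, rng)
            counts[int(np.argmax(a))] += 1
            counts[int(np.argmax(b))] += 1
        freq = counts / (2 * n)
        se = np.sqrt(probs * (1 - probs) / (2 * n))
        assert np.all(np.abs(freq - probs) < 3 * se + 1e-9)

    def test_deterministic(self):
        pop = Population(np.eye(4, dtype=np.uint8))
        probs = np.full(4, 0.25)
        seq1 = [select_parents(pop, probs, np.random.default_rng(9))
                for _ in range(1)]
        seq2 = [select_parents(pop, probs, np.random.default_rng(9))
                for _ in range(1)]
        for (a1, b1), (a2, b2) in zip(seq1, seq2):
            np.testing.assert_array_equal(a1, a2)
            np.testing.assert_array_equal(b1, b2)


class TestCrossover:
    def test_single_point_splice_example(self):
        p1 = np.array([1, 1, 1, 1, 0], dtype=np.uint8)
        p2 = np.array([0, 0, 0, 0, 1], dtype=np.uint8)
        c1, c2 = single_point_crossover(p1, p2, 2)
        np.testing.assert_array_equal(c1, [1, 1, 0, 0, 1])
        np.testing.assert_array_equal(c2, [0, 0, 1, 1, 0])

    def test_identical_parents_fixed_point(self):
        p = np.array([1, 0, 1, 0, 1, 1], dtype=np.uint8)
        cfg = GAConfig(population_size=4, crossover_rate=1.0, master_seed=0)
        rng = np.random.default_rng(3)
        for _ in range(20):
            c1, c2 = crossover_pair(p, p, cfg, rng)
            np.testing.assert_array_equal(c1, p)
            np.testing.assert_array_equal(c2, p)

    def test_rate_zero_returns_copies(self):
        cfg = GAConfig(population_size=4, crossover_rate=0.0)
        p1 = np.array([1, 0, 1], dtype=np.uint8)
        p2 = np.array([0, 1, 0], dtype=np.uint8)
        c1, c2 = crossover_pair(p1, p2, cfg, np.random.default_rng(0))
        np.testing.assert_array_equal(c1, p1)
        np.testing.assert_array_equal(c2, p2)
        assert c1 is not p1  # copies, not views

    def test_exhaustive_positionwise_conservation_length6(self):
        # every cut choice, both operators, all parent pairs of length 6
        d = 6
        bits = list(itertools.product([0, 1], repeat=d))
        pairs = list(itertools.product(bits[:8], bits))  # representative slice
        for b1, b2 in pairs:
            p1 = np.array(b1, dtype=np.uint8)
            p2 = np.array(b2, dtype=np.uint8)
            for cut in range(1, d):
                c1, c2 = single_point_crossover(p1, p2, cut)
                expected1 = np.concatenate([p1[:cut], p2[cut:]])
                np.testing.assert_array_equal(c1, expected1)
                assert all(
                    {c1[i], c2[i]} == {p1[i], p2[i]} for i in range(d)
                )
            for ca, cb in itertools.combinations(range(1, d), 2):
                c1, c2 = double_point_crossover(p1, p2, ca, cb)
                assert all(
                    {c1[i], c2[i]} == {p1[i], p2[i]} for i in range(d)
                )

    def test_random_crossover_conserves_multiset(self):
        cfg = GAConfig(population_size=4, crossover_rate=1.0)
        rng = np.random.default_rng(7)
        for _ in range(200):
            p1 = rng.integers(0, 2, 12, dtype=np.uint8)
            p2 = rng.integers(0, 2, 12, dtype=np.uint8)
            c1, c2 = crossover_pair(p1, p2, cfg, rng)
            np.testing.assert_array_equal(
                np.sort(np.stack([c1, c2]), axis=0),
                np.sort(np.stack([p1, p2]), axis=0),
            )


class TestMutate:
    def test_rate_zero_identity(self):
        c = np.array([1, 0, 1, 1], dtype=np.uint8)
        out = mutate(c, 0.0, np.random.default_rng(0))
        np.testing.assert_array_equal(out, c)

    def test_rate_one_complement(self):
        c = np.array([1, 0, 1, 1, 0], dtype=np.uint8)
        out = mutate(c, 1.0, np.random.default_rng(0))
        np.testing.assert_array_equal(out, 1 - c)

    def test_flip_count_statistics(self):
        # binomial(20, 0.05) oracle: mean flips 1.0
        d, rate, n = 20, 0.05, 20_000
        rng = np.random.default_rng(4)
        c = np.zeros(d, dtype=np.uint8)
        flips = sum(int(mutate(c, rate, rng).sum()) for _ in range(n))
        mean = flips / n
        se = np.sqrt(d * rate * (1 - rate) / n)
        assert abs(mean - 1.0) < 3 * se

    def test_single_point_mode_flips_at_most_one(self):
        rng = np.random.default_rng(1)
        c = np.zeros(10, dtype=np.uint8)
        for _ in range(100):
            out = mutate(c, 0.5, rng, mode="single_point")
            assert out.sum() <= 1


class TestNextGeneration:
    def _pop(self, seed=0, x=10, d=6):
        return init_population(d, x, np.random.default_rng(seed))

    def test_size_invariant(self):
        pop = self._pop()
        fits = np.linspace(0.1, 0.9, pop.size)
        out = next_generation(
            pop, fits, GAConfig(population_size=pop.size), _streams(1)
        )
        assert out.size == pop.size
        assert out.generation_index == pop.generation_index + 1

    def test_unique_best_member_survives_verbatim(self):
        pop = self._pop(seed=3)
        fits = np.full(pop.size, 0.5)
        fits[4] = 0.99
        out = next_generation(
            pop, fits, GAConfig(population_size=pop.size), _streams(2)
        )
        assert any(
            np.array_equal(m, pop.members[4]) for m in out.members
        )

    def test_operator_noops_give_pure_resampling(self):
        pop = self._pop(seed=5)
        fits = np.full(pop.size, 0.7)
        cfg = GAConfig(
            population_size=pop.size, crossover_rate=0.0, mutation_rate=0.0
        )
        out = next_generation(pop, fits, cfg, _streams(3))
        originals = {tuple(m) for m in pop.members}
        assert all(tuple(m) in originals for m in out.members)

    def test_elite_tiebreak_prefers_fewer_bits(self):
        members = np.array(
            [[1, 1, 1, 1], [1, 0, 0, 0], [0, 1, 1, 0], [1, 1, 0, 0]],
            dtype=np.uint8,
        )
        pop = Population(members)
        fits = np.array([0.9, 0.9, 0.9, 0.5])
        cfg = GAConfig(population_size=4, n_elites=2,
                       crossover_rate=0.0, mutation_rate=0.0)
        out = next_generation(pop, fits, cfg, _streams(0))
        # elites: index 1 (popcount 1) then index 2 (popcount 2)
        np.testing.assert_array_equal(out.members[0], members[1])
        np.testing.assert_array_equal(out.members[1], members[2])


class TestRunGA:
    def test_invalid_candidates(self, separable_table):
        cfg = GAConfig(population_size=6, n_generations=1)
        with pytest.raises(ConfigurationError):
            run_ga(["sep"], separable_table, cfg,
                   FitnessSpec("svm", n_folds=2, n_repeats=1))

    def test_trajectory_nondecreasing_and_deterministic(self, separable_table):
        cfg = GAConfig(population_size=8, n_generations=5, master_seed=17)
        spec = FitnessSpec("svm", n_folds=3, n_repeats=1)
        names = separable_table.feature_names[:6]
        r1 = run_ga(names, separable_table, cfg, spec)
        r2 = run_ga(names, separable_table, cfg, spec)
        best = r1.trajectory_best
        assert all(a <= b for a, b in zip(best, best[1:]))
        assert r1.best_fitness == max(best)
        assert r1.trajectory_best == r2.trajectory_best
        np.testing.assert_array_equal(r1.best_chromosome, r2.best_chromosome)
        assert r1.selected_feature_names == r2.selected_feature_names

    def test_selected_names_match_chromosome(self, separable_table):
        cfg = GAConfig(population_size=6, n_generations=2, master_seed=3)
        names = separable_table.feature_names[:5]
        r = run_ga(names, separable_table, cfg,
                   FitnessSpec("svm", n_folds=3, n_repeats=1))
        expected = tuple(
            n for n, b in zip(names, r.best_chromosome) if b
        )
        assert r.selected_feature_names == expected
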