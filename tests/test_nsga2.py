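"""Genetic-algorithm primitives and the evolutionary loop."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from paretosig.nsga2 import (
    GAConfig,
    Individual,
    bitflip_mutate,
    crowding_distance,
    dominates,
    evolve,
    fast_nondominated_sort,
    initialize_population,
    single_point_crossover,
    tournament_select,
    tournament_winner,
)

from oracles import brute_force_fronts


class FakeRng:
    """Scripted random source for deterministic operator tests."""

    def __init__(self, randoms=(), integers=()):
        self._randoms = list(randoms)
        self._integers = list(integers)

    def random(self, size=None):
        if size is None:
            return self._randoms.pop(0)
        return np.array([self._randoms.pop(0) for _ in range(size)])

    def integers(self, low, high=None, size=None):
        assert size is None
        return self._integers.pop(0)


class TestInitialization:
    def test_expected_set_fraction(self):
        cfg = GAConfig(population_size=200, seed=42)
        pop = initialize_population(100, cfg)
        frac = np.mean([b.mean() for b in pop])
        # 20,000 Bernoulli(0.1) bits; 5 sigma ~ 0.0106
        assert abs(frac - 0.10) < 5 * np.sqrt(0.1 * 0.9 / 20000)

    def test_full_fraction_gives_all_ones(self):
        cfg = GAConfig(population_size=10, init_set_fraction=1.0, seed=0)
        pop = initialize_population(5, cfg)
        assert all(b.all() for b in pop)

    def test_seed_reproducibility(self):
        cfg = GAConfig(population_size=20, seed=3)
        a = initialize_population(30, cfg)
        b = initialize_population(30, GAConfig(population_size=20, seed=3))
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_no_all_zero_chromosomes(self):
        cfg = GAConfig(population_size=200, init_set_fraction=0.01, seed=1)
        pop = initialize_population(5, cfg)
        assert all(b.any() for b in pop)


class TestDominance:
    @pytest.mark.parametrize("a,b,expect", [
        ((1, -0.7, 0.5), (2, -0.6, 0.5), True),
        ((1, -0.7, 0.5), (1, -0.7, 0.5), False),   # no strict improvement
        ((1, -0.8, 2.0), (2, -0.7, 1.0), False),   # incomparable
    ])
    def test_examples(self, a, b, expect):
        assert dominates(a, b) is expect

    @given(st.lists(st.tuples(*[st.integers(0, 3)] * 3), min_size=1, max_size=12))
    def test_irreflexive_and_asymmetric(self, objs):
        for a, b in itertools.product(objs, objs):
            assert not (dominates(a, b) and dominates(b, a))
            if a == b:
                assert not dominates(a, b)


class TestNonDominatedSort:
    def test_hand_example(self):
        objs = [(1, 1, 1), (2, 2, 2), (1, 2, 1)]
        fronts = fast_nondominated_sort(objs)
        assert fronts == [[0], [2], [1]]

    def test_identical_points_single_front(self):
        fronts = fast_nondominated_sort([(1.0, 2.0)] * 7)
        assert fronts == [list(range(7))]

    @given(st.integers(0, 10_000))
    def test_matches_brute_force_on_random_sets(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 50))
        objs = rng.integers(0, 6, size=(n, 3)).astype(float)
        assert ([sorted(f) for f in fast_nondominated_sort(objs)]
                == [sorted(f) for f in brute_force_fronts(objs)])


class TestCrowdingDistance:
    def test_small_fronts_all_infinite(self):
        assert np.all(np.isinf(crowding_distance([(1, 2, 3)])))
        assert np.all(np.isinf(crowding_distance([(1, 2, 3), (3, 2, 1)])))

    def test_collinear_equally_spaced_middle_is_two(self):
        objs = [(0.0, 0.0), (1.0, 1.0), (2.0, 2.0)]
        d = crowding_distance(objs)
        assert np.isinf(d[0]) and np.isinf(d[2])
        assert d[1] == pytest.approx(2.0)

    def test_interior_duplicate_gets_zero(self):
        objs = [(0.0, 0.0), (1.0, 1.0), (1.0, 1.0), (1.0, 1.0), (2.0, 2.0)]
        d = crowding_distance(objs)
        assert d[2] == 0.0  # surrounded by identical vectors on both sides

    def test_zero_range_objective_contributes_nothing(self):
        objs = [(0.0, 5.0), (1.0, 5.0), (2.0, 5.0)]
        d = crowding_distance(objs)
        assert d[1] == pytest.approx(1.0)  # only the first objective counts


def _pop(ranks_crowding):
    pop = []
    for r, c in ranks_crowding:
        ind = Individual(bits=np.array([1], dtype=np.uint8))
        ind.rank, ind.crowding = r, c
        pop.append(ind)
    return pop


class TestTournament:
    def test_lower_front_wins(self):
        entrants = _pop([(1, 0.0)] + [(3, np.inf)] * 4)
        assert tournament_winner(entrants, np.random.default_rng(0)).rank == 1

    def test_crowding_breaks_front_ties(self):
        entrants = _pop([(1, 0.5), (1, 2.0), (1, 1.0), (1, 0.1), (1, 0.0)])
        assert tournament_winner(entrants, np.random.default_rng(0)).crowding == 2.0

    def test_selection_pressure(self):
        pop = _pop([(1, 1.0)] * 10 + [(2, 1.0)] * 10)
        cfg = GAConfig(population_size=2, tournament_size=5, seed=0)
        rng = np.random.default_rng(1)
        wins_front1 = sum(tournament_select(pop, cfg, rng).rank == 1
                          for _ in range(10_000))
        # front-1 individuals win unless the whole tournament is front-2:
        # expected rate 1 - 0.5^5 ~ 0.969
        assert wins_front1 > 9_000


class TestVariation:
    def test_crossover_disabled_returns_copies(self):
        cfg = GAConfig(population_size=2, crossover_prob=0.0, seed=0)
        a = np.array([1, 1, 1, 1], dtype=np.uint8)
        b = np.array([0, 0, 0, 0], dtype=np.uint8)
        c1, c2 = single_point_crossover(a, b, cfg, np.random.default_rng(0))
        assert np.array_equal(c1, a) and np.array_equal(c2, b)
        assert c1 is not a

    def test_forced_cut_point(self):
        cfg = GAConfig(population_size=2, crossover_prob=0.8, seed=0)
        a = np.array([1, 1, 1, 1], dtype=np.uint8)
        b = np.array([0, 0, 0, 0], dtype=np.uint8)
        rng = FakeRng(randoms=[0.0], integers=[2])
        c1, c2 = single_point_crossover(a, b, cfg, rng)
        assert list(c1) == [1, 1, 0, 0]
        assert list(c2) == [0, 0, 1, 1]

    @given(st.integers(0, 1000))
    def test_crossover_conserves_bits_per_position(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 2, size=12).astype(np.uint8)
        b = rng.integers(0, 2, size=12).astype(np.uint8)
        cfg = GAConfig(population_size=2, crossover_prob=1.0, seed=0)
        c1, c2 = single_point_crossover(a, b, cfg, rng)
        for i in range(12):
            assert sorted([a[i], b[i]]) == sorted([c1[i], c2[i]])

    def test_mutation_prob_zero_is_identity(self):
        cfg = GAConfig(population_size=2, mutation_prob=0.0, seed=0)
        bits = np.array([1, 0, 1], dtype=np.uint8)
        assert np.array_equal(bitflip_mutate(bits, cfg, np.random.default_rng(0)), bits)

    def test_mutation_prob_one_is_complement(self):
        cfg = GAConfig(population_size=2, mutation_prob=1.0, seed=0)
        bits = np.array([1, 0, 1], dtype=np.uint8)
        out = bitflip_mutate(bits, cfg, np.random.default_rng(0))
        assert np.array_equal(out, 1 - bits)

    def test_observed_flip_fraction(self):
        cfg = GAConfig(population_size=2, mutation_prob=0.02, seed=0)
        rng = np.random.default_rng(5)
        flips = 0
        for _ in range(1000):
            bits = np.zeros(100, dtype=np.uint8)
            flips += bitflip_mutate(bits, cfg, rng).sum()
        rate = flips / 100_000
        assert abs(rate - 0.02) < 5 * np.sqrt(0.02 * 0.98 / 100_000)


def _toy_objective(bits):
    """Planted 2-bit optimum: minimize size, maximize planted-bit count."""
    return (int(bits.sum()), -float(2 * bits[0] + bits[1]), 0.0)


class TestEvolve:
    def test_constant_objective_terminates_immediately(self):
        cfg = GAConfig(population_size=10, stagnation_generations=1,
                       max_generations=100, seed=0)
        result = evolve(lambda bits: (1.0, 1.0, 1.0), 8, cfg)
        assert result.terminated_by == "stagnation"
        assert result.generations <= 2

    def test_population_size_invariant_and_determinism(self):
        cfg = GAConfig(population_size=20, stagnation_generations=5,
                       max_generations=30, seed=11)
        r1 = evolve(_toy_objective, 10, cfg)
        r2 = evolve(_toy_objective, 10, cfg)
        assert len(r1.population) == 20
        assert r1.generations == r2.generations
        assert [i.key for i in r1.population] == [i.key for i in r2.population]

    def test_front_matches_exhaustive_enumeration_on_planted_optimum(self):
        cfg = GAConfig(population_size=40, stagnation_generations=10,
                       max_generations=200, seed=2)
        result = evolve(_toy_objective, 10, cfg)
        # exhaustive truth over all non-empty chromosomes
        patterns = [np.array(p, dtype=np.uint8)
                    for p in itertools.product([0, 1], repeat=10)]
        patterns = [p for p in patterns if p.any()]
        objs = [_toy_objective(p) for p in patterns]
        true_front = {objs[i] for front in [brute_force_fronts(objs)[0]]
                      for i in front}
        got = {ind.objectives for ind in result.front}
        assert got == true_front

    def test_elitism_no_front_regression(self):
        """No vector ever evaluated dominates a final first-front vector."""
        seen = []

        def recording(bits):
            out = _toy_objective(bits)
            seen.append(out)
            return out

        cfg = GAConfig(population_size=20, stagnation_generations=5,
                       max_generations=50, seed=4)
        result = evolve(recording, 10, cfg)
        for ind in result.front:
            assert not any(dominates(v, ind.objectives) for v in seen)

    def test_history_tracks_front(self):
        cfg = GAConfig(population_size=20, stagnation_generations=3,
                       max_generations=30, seed=6)
        result = evolve(_toy_objective, 10, cfg)
        assert len(result.history) == result.generations + 1
        assert result.history[-1].front_size == len(result.front)
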