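"""Genetic-algorithm operators, the full GA loop, and the SA baseline."""

import numpy as np
import pytest

from pathga import (
    Chromosome,
    Compendium,
    GAConfig,
    GeneSet,
    SAConfig,
    apply_elitism,
    crossover,
    feasible_space_size,
    init_population,
    mutate,
    run_ga,
    run_sa,
    tournament_select,
    validate_orderings,
)
from pathga.evolve import FitnessCache, Population
from pathga.evaluate import exhaustive_oracle
from pathga.synthetic import small_compendium_suite


def _pop(fitnesses):
    members = [
        Chromosome(((f"s{i}", f"t{i}"),), fitness=f) for i, f in enumerate(fitnesses)
    ]
    return Population(members)


class TestTournament:
    def test_better_member_always_wins(self, rng):
        pop = _pop([-1.0, -2.0])
        pool = tournament_select(pop, rng)
        assert len(pool) == 2
        assert all(c.fitness == -1.0 for c in pool)

    def test_identical_population_passes_through(self, rng):
        pop = _pop([-3.0] * 4)
        pool = tournament_select(pop, rng)
        assert [c.orderings for c in pool] != []  # s copies drawn
        assert all(c.fitness == -3.0 for c in pool)

    def test_pool_mean_dominates_population_mean(self, rng):
        fitnesses = list(np.linspace(-10, -1, 10))
        pop = _pop(fitnesses)
        means = []
        for _ in range(1000):
            pool = tournament_select(pop, rng)
            means.append(np.mean([c.fitness for c in pool]))
        assert np.mean(means) > np.mean(fitnesses)


class TestCrossover:
    def test_identical_parents_yield_identical_children(self, rng, three_set_compendium):
        from pathga import random_feasible_orderings

        o = random_feasible_orderings(three_set_compendium, rng)
        pool = [Chromosome(o, -1.0), Chromosome(o, -1.0)]
        out = crossover(pool, p_C=1.0, c_N=1, rng=rng)
        assert all(c.orderings == o for c in out)

    def test_zero_probability_is_identity(self, rng, three_set_compendium):
        from pathga import random_feasible_orderings

        pool = [
            Chromosome(random_feasible_orderings(three_set_compendium, rng), -1.0)
            for _ in range(4)
        ]
        before = [c.orderings for c in pool]
        out = crossover(pool, p_C=0.0, c_N=1, rng=rng)
        assert sorted(c.orderings for c in out) == sorted(before)

    def test_exchanges_exactly_c_n_matching_slots(self, three_set_compendium):
        rng = np.random.default_rng(0)
        a = (("a", "b", "c", "d"), ("a", "c", "b", "e"), ("f", "b", "c", "d"))
        b = (("a", "c", "b", "d"), ("a", "b", "c", "e"), ("f", "c", "b", "d"))
        out = crossover([Chromosome(a, -1.0), Chromosome(b, -2.0)], p_C=1.0, c_N=1, rng=rng)
        ca, cb = out[0].orderings, out[1].orderings
        swapped = [i for i in range(3) if ca[i] != a[i] or cb[i] != b[i]]
        # exactly one slot exchanged, and it is the same slot in both children
        assert len(swapped) == 1
        i = swapped[0]
        assert {ca[i], cb[i]} == {a[i], b[i]}
        assert out[0].fitness is None and out[1].fitness is None

    def test_c_n_larger_than_m_rejected(self, rng, three_set_compendium):
        from pathga import random_feasible_orderings

        pool = [
            Chromosome(random_feasible_orderings(three_set_compendium, rng), -1.0)
            for _ in range(2)
        ]
        with pytest.raises(ValueError, match="c_N"):
            crossover(pool, p_C=1.0, c_N=4, rng=rng)


class TestMutation:
    def test_zero_rate_is_identity(self, rng, three_set_compendium):
        from pathga import random_feasible_orderings

        pool = [
            Chromosome(random_feasible_orderings(three_set_compendium, rng), -1.0)
            for _ in range(4)
        ]
        before = [c.orderings for c in pool]
        assert [c.orderings for c in mutate(pool, 0.0, rng)] == before

    def test_length_three_sets_cannot_change(self, rng):
        c = Compendium((GeneSet("p", ("a", "b", "c")),))
        pool = [Chromosome((("a", "b", "c"),), -1.0) for _ in range(4)]
        out = mutate(pool, 1.0, rng)
        assert all(ch.orderings == (("a", "b", "c"),) for ch in out)

    def test_redraw_is_uniform_at_length_four(self, rng):
        # a forced re-draw of a 2-intermediate path lands on either
        # arrangement with probability 1/2 (identity permitted)
        start = (("a", "b", "c", "d"),)
        swapped = 0
        draws = 2000
        for _ in range(draws):
            (out,) = mutate([Chromosome(start, -1.0)], 1.0, rng)
            swapped += out.orderings[0] == ("a", "c", "b", "d")
        assert abs(swapped / draws - 0.5) < 0.05

    def test_per_chromosome_scope_changes_one_path(self, rng, three_set_compendium):
        from pathga import random_feasible_orderings

        o = random_feasible_orderings(three_set_compendium, rng)
        changed_slots = set()
        for _ in range(200):
            (out,) = mutate([Chromosome(o, -1.0)], 1.0, rng, scope="per_chromosome")
            diff = [i for i in range(3) if out.orderings[i] != o[i]]
            assert len(diff) <= 1  # one path re-drawn (identity possible)
            changed_slots.update(diff)
        assert changed_slots  # some mutation actually happened


class TestElitism:
    def test_full_elitism_reproduces_population(self, rng):
        pop = _pop([-1.0, -5.0, -3.0, -2.0])
        pool = [Chromosome((("x", "y"),), -9.0) for _ in range(4)]
        nxt = apply_elitism(pop, pool, p_E=1.0, rng=rng)
        assert sorted(c.fitness for c in nxt.members) == [-5.0, -3.0, -2.0, -1.0]

    def test_zero_elitism_keeps_pool(self, rng):
        pop = _pop([-1.0, -5.0, -3.0, -2.0])
        pool = [Chromosome((("x", "y"),), -9.0) for _ in range(4)]
        nxt = apply_elitism(pop, pool, p_E=0.0, rng=rng)
        assert all(c.fitness == -9.0 for c in nxt.members)

    def test_elite_count_is_floored(self, rng):
        pop = _pop([-1.0, -5.0, -3.0, -2.0])
        pool = [Chromosome((("x", "y"),), -9.0) for _ in range(4)]
        nxt = apply_elitism(pop, pool, p_E=0.25, rng=rng)  # floor(1.0) = 1 elite
        fits = sorted(c.fitness for c in nxt.members)
        assert fits.count(-1.0) == 1 and fits.count(-9.0) == 3


class TestRunGA:
    def test_determinism(self, three_set_compendium):
        cfg = GAConfig(s=10, J=30, seed=99)
        r1 = run_ga(three_set_compendium, cfg)
        r2 = run_ga(three_set_compendium, cfg)
        np.testing.assert_array_equal(r1.trace_best, r2.trace_best)
        np.testing.assert_array_equal(r1.trace_mean, r2.trace_mean)
        np.testing.assert_array_equal(r1.best_so_far_trace, r2.best_so_far_trace)
        assert r1.best_orderings == r2.best_orderings

    def test_trivial_search_space_gives_constant_traces(self):
        c = Compendium((GeneSet("p1", ("a", "b", "c")), GeneSet("p2", ("b", "c"))))
        assert feasible_space_size(c) == 1
        res = run_ga(c, GAConfig(s=6, J=20, seed=0))
        assert np.all(res.trace_best == res.trace_best[0])
        assert res.best_orderings == (("a", "b", "c"), ("b", "c"))

    def test_feasibility_closure_every_generation(self, three_set_compendium):
        res = run_ga(
            three_set_compendium, GAConfig(s=10, J=20, seed=3), check_invariants=True
        )
        validate_orderings(three_set_compendium, res.best_orderings)

    def test_elitism_makes_best_trace_monotone(self, three_set_compendium):
        res = run_ga(three_set_compendium, GAConfig(s=10, J=50, seed=5, p_E=0.2))
        assert np.all(np.diff(res.trace_best) >= -1e-12)
        assert np.all(np.diff(res.best_so_far_trace) >= 0)

    def test_reaches_global_maximum_on_small_instance(self):
        bundle = small_compendium_suite(seed=7, count=1)[0]
        f_star, _ = exhaustive_oracle(bundle.compendium)
        res = run_ga(bundle.compendium, GAConfig(J=200, seed=1))
        assert res.best_fitness <= f_star + 1e-9
        assert res.best_fitness == pytest.approx(f_star, abs=1e-9)

    def test_population_scoring_is_cached(self, three_set_compendium):
        cache = FitnessCache(three_set_compendium)
        rng = np.random.default_rng(0)
        pop = init_population(three_set_compendium, GAConfig(s=10, J=1), rng, cache)
        misses = cache.misses
        cache.score_all([c.copy() for c in pop.members])
        assert cache.misses == misses  # verbatim copies re-score for free


class TestRunSA:
    def test_requires_a_movable_gene_set(self):
        c = Compendium((GeneSet("p", ("a", "b", "c")),))
        with pytest.raises(ValueError, match="length >= 4"):
            run_sa(c, SAConfig(iterations=10, seed=0))

    def test_determinism_and_monotone_best(self, three_set_compendium):
        cfg = SAConfig(iterations=300, seed=11)
        r1 = run_sa(three_set_compendium, cfg)
        r2 = run_sa(three_set_compendium, cfg)
        np.testing.assert_array_equal(r1.trace_best, r2.trace_best)
        assert np.all(np.diff(r1.best_so_far_trace) >= 0)

    def test_never_exceeds_global_maximum(self):
        bundle = small_compendium_suite(seed=13, count=1)[0]
        f_star, _ = exhaustive_oracle(bundle.compendium)
        hits = 0
        for seed in range(5):
            res = run_sa(bundle.compendium, SAConfig(iterations=1000, seed=seed))
            assert res.best_fitness <= f_star + 1e-9
            hits += res.best_fitness >= f_star - 1e-9
        assert hits >= 3  # equality in most seeded runs

    def test_improving_moves_always_accepted(self, three_set_compendium):
        # a long run must end with best == current-best over the trace, and
        # the running best can only improve when a proposal was accepted
        res = run_sa(three_set_compendium, SAConfig(iterations=200, seed=2))
        assert res.best_fitness == res.best_so_far_trace[-1]
        assert res.best_fitness >= res.trace_best[0]
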