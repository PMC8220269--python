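"""GA operators, convergence detection and full runs."""

import numpy as np
import pytest

from _utils import history_from_fitness
from envdesign.env_space import Environment
from envdesign.ga_engine import (
    ConvergenceCriteria,
    EvaluatedMember,
    FAILURE_FITNESS,
    GAConfig,
    check_convergence,
    initialize_population,
    make_offspring,
    mutate,
    mutate_environment,
    rank_population,
    run_ga,
    run_random_search,
    select_parents,
)
from envdesign.objectives import Objective


class TestInitialization:
    def test_reproducible_population_of_ten(self, space):
        a = initialize_population(space, 10, np.random.default_rng(3))
        b = initialize_population(space, 10, np.random.default_rng(3))
        assert a == b
        assert len(a) == 10

    def test_all_sizes_within_bounds(self, space):
        rng = np.random.default_rng(0)
        for env in initialize_population(space, 1000, rng):
            assert 1 <= len(env) <= space.max_nutrients

    def test_degenerate_single_member_population(self, space):
        assert len(initialize_population(space, 1, np.random.default_rng(0))) == 1


class TestSelection:
    def make_pop(self, space, fitness):
        ids = space.pool.ids
        members = [
            EvaluatedMember(Environment.from_ids([ids[i]]), f, f)
            for i, f in enumerate(fitness)
        ]
        return rank_population(members, space)

    def test_top_sigma_selected_in_rank_order(self, space):
        pop = self.make_pop(space, [1.0, 5.0, 3.0])
        parents = select_parents(pop, 2)
        assert [p.sorted_ids[0] for p in parents] == ["fru", "gal"]  # fitness 5, 3

    def test_sigma_equal_p_returns_whole_population(self, space):
        pop = self.make_pop(space, [1.0, 2.0, 3.0])
        assert len(select_parents(pop, 3)) == 3

    def test_ties_broken_canonically_and_stable(self, space):
        pop1 = self.make_pop(space, [2.0, 2.0, 2.0])
        pop2 = self.make_pop(space, [2.0, 2.0, 2.0])
        assert select_parents(pop1, 2) == select_parents(pop2, 2)
        # canonical order: pool index of the single nutrient
        assert select_parents(pop1, 3) == sorted(
            select_parents(pop1, 3), key=lambda e: space.pool.index_of(e.sorted_ids[0])
        )


class TestOffspring:
    def test_pure_crossover_offspring_contained_in_parent_union(self, space):
        parents = [Environment.from_ids(["glc", "fru"]), Environment.from_ids(["cit", "ala"])]
        union = {"glc", "fru", "cit", "ala"}
        for seed in range(30):
            rng = np.random.default_rng(seed)
            for child in make_offspring(parents, 10, 2, 1.0, 3, space, rng):
                assert child.nutrient_ids <= union
                assert 1 <= len(child) <= 3

    def test_no_crossover_falls_back_to_fresh_environments(self, space):
        parents = [Environment.from_ids(["glc"])]
        rng = np.random.default_rng(0)
        children = make_offspring(parents, 50, 1, 0.0, 3, space, rng)
        used = set().union(*(c.nutrient_ids for c in children))
        assert used - {"glc"}  # fresh draws reach beyond the parent pool

    def test_identical_singleton_parents_force_that_offspring(self, space):
        parents = [Environment.from_ids(["glc"]), Environment.from_ids(["glc"])]
        rng = np.random.default_rng(1)
        children = make_offspring(parents, 8, 2, 1.0, 3, space, rng)
        assert all(c == Environment.from_ids(["glc"]) for c in children)


class TestMutation:
    def test_zero_rate_is_identity(self, space):
        rng = np.random.default_rng(0)
        pop = initialize_population(space, 10, rng)
        assert mutate(pop, 0.0, space, rng) == pop

    def test_full_rate_replaces_every_slot_without_duplicates(self, space):
        rng = np.random.default_rng(0)
        for _ in range(50):
            env = initialize_population(space, 1, rng)[0]
            mutated = mutate_environment(env, 1.0, space, rng)
            assert len(mutated) == len(env)
            assert len(mutated.nutrient_ids) == len(set(mutated.nutrient_ids))
            assert space.is_admissible(mutated)

    def test_top_ranked_environment_never_touched(self, space):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            pop = initialize_population(space, 6, rng)
            assert mutate(pop, 0.45, space, rng)[0] == pop[0]

    def test_exhausted_pool_leaves_slot_unchanged(self):
        from envdesign.env_space import EnvironmentSpace, Nutrient, NutrientPool

        tiny = EnvironmentSpace(
            NutrientPool((Nutrient("a", "a", 1), Nutrient("b", "b", 1))), 2
        )
        env = Environment.from_ids(["a", "b"])  # contains the whole pool
        assert mutate_environment(env, 1.0, tiny, np.random.default_rng(0)) == env


class TestConvergence:
    def test_constant_fitness_for_eleven_generations_converges(self):
        history = history_from_fitness([[3.0] * 10] * 11)
        converged, flags = check_convergence(history, ConvergenceCriteria())
        assert converged and all(flags.values())

    def test_strictly_improving_best_does_not_converge(self):
        gens = [[float(g)] * 10 for g in range(1, 16)]
        history = history_from_fitness(gens)
        converged, flags = check_convergence(history, ConvergenceCriteria())
        assert not converged
        assert not flags["no_improvement"]

    def test_wide_population_spread_fails_internal_consistency(self):
        # best stalled at 10 but the population mean is far below it
        gens = [[10.0] + [1.0] * 9] * 12
        history = history_from_fitness(gens)
        converged, flags = check_convergence(history, ConvergenceCriteria())
        assert not flags["internal_consistency"]
        assert flags["reached_maximum"] and flags["no_improvement"]
        assert not converged

    def test_zero_fitness_plateau_handled_by_shift(self):
        history = history_from_fitness([[0.0] * 10] * 11)
        converged, _ = check_convergence(history, ConvergenceCriteria())
        assert converged

    def test_too_few_generations_cannot_satisfy_stall_criterion(self):
        history = history_from_fitness([[1.0] * 10] * 5)
        _, flags = check_convergence(history, ConvergenceCriteria())
        assert not flags["no_improvement"]


class TestRuns:
    def test_same_seed_identical_histories(self, space, mapping, objectives):
        cfg = GAConfig(N=3, G=20, seed=11)
        ev = mapping.evaluator()
        h1 = run_ga(space, ev, objectives["entropy"], cfg)
        h2 = run_ga(space, ev, objectives["entropy"], cfg)
        assert h1.generations == h2.generations
        assert h1.best_so_far == h2.best_so_far
        r1 = run_random_search(space, ev, objectives["entropy"], cfg)
        r2 = run_random_search(space, ev, objectives["entropy"], cfg)
        assert r1.generations == r2.generations

    def test_sigma_equals_p_with_no_mutation_is_static(self, space, mapping, objectives):
        cfg = GAConfig(N=3, P=6, sigma=6, pM=0.0, G=5, seed=4)
        h = run_ga(space, mapping.evaluator(), objectives["entropy"], cfg)
        first = set(h.generations[0].environments())
        for gen in h.generations[1:]:
            assert set(gen.environments()) == first

    def test_elitism_monotone_closure_and_memo(self, space, mapping, objectives):
        cfg = GAConfig(N=3, G=25, seed=2)
        h = run_ga(space, mapping.evaluator(), objectives["exchanges"], cfg)
        trace = np.array(h.best_so_far)
        assert (np.diff(trace) >= 0).all()
        proposed = {e for gen in h.generations for e in gen.environments()}
        assert all(space.is_admissible(e) for e in proposed)
        assert h.unique_evaluations == len(proposed)
        assert h.unique_evaluations <= h.total_evaluations

    def test_failing_evaluator_degrades_gracefully(self, space, mapping, objectives):
        poison = Environment.from_ids(["glc"])

        def evaluator(env):
            if env == poison:
                raise RuntimeError("boom")
            return mapping.lookup(env)

        cfg = GAConfig(N=3, G=10, seed=0)
        h = run_ga(space, evaluator, objectives["entropy"], cfg)
        assert h.n_generations >= 1
        if h.failures:
            assert h.failures[0][0] == poison
            failed = [
                m.fitness
                for gen in h.generations
                for m in gen.members
                if m.env == poison
            ]
            assert all(f == FAILURE_FITNESS for f in failed)

    def test_single_generation_ga_and_random_search_coincide(
        self, space, mapping, objectives
    ):
        cfg = GAConfig(N=3, G=1, seed=9)
        ev = mapping.evaluator()
        h_ga = run_ga(space, ev, objectives["entropy"], cfg)
        h_rs = run_random_search(space, ev, objectives["entropy"], cfg)
        assert h_ga.generations == h_rs.generations

    def test_ga_finds_enumerated_optimum_on_small_space(
        self, space, mapping, objectives, references
    ):
        hits = 0
        for seed in range(10):
            cfg = GAConfig(N=3, G=100, seed=seed)
            h = run_ga(space, mapping.evaluator(), objectives["entropy"], cfg)
            hits += h.best_fitness == references["entropy"].maximum
        assert hits >= 9

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            GAConfig(N=3, P=10, sigma=11)
        with pytest.raises(ValueError):
            GAConfig(N=3, pM=0.5)
        with pytest.raises(ValueError):
            GAConfig(N=3, pC=1.5)
        with pytest.raises(ValueError):
            GAConfig(N=3, G=0)
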