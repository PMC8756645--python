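import math

import numpy as np
import pytest

from fluxevolve.evolution import (
    BoundsMutation,
    FitnessSpec,
    Individual,
    MutationLimits,
    MutationParams,
    fitness_from_deviations,
    identify_key_reaction,
    mutate,
    mutation_limits,
    mutation_scale,
)
from fluxevolve.synthetic import ToyModelSpec, make_expression_tables, make_fitness_spec, make_toy_model
from fluxevolve.expression import apply_expression_switch
from fluxevolve.evolution import FluxBoundEvolution, reference_fluxes_from_targets
from fluxevolve.pipeline import reaction_fold_changes

from conftest import build_model, make_evolution


class TestFitness:
    def test_single_small_deviation(self):
        assert fitness_from_deviations([0.01]) == pytest.approx(4.0, abs=1e-12)

    def test_two_deviations(self):
        assert fitness_from_deviations([0.1, 0.1]) == pytest.approx(-math.log10(0.02), abs=1e-12)

    def test_perfect_fit_capped_above_threshold(self):
        assert fitness_from_deviations([0.0, 0.0, 0.0]) == 12.0
        assert fitness_from_deviations([0.0]) > 6.0

    def test_cap_applies_to_tiny_deviations(self):
        assert fitness_from_deviations([1e-13]) == 12.0

    def test_evaluator_matches_independent_reimplementation(self, evaluator, fitness_spec):
        """Eq-style score recomputed independently from the achieved fluxes."""
        mut = BoundsMutation("cit_exp", "constrain", 0.5, 0.0, 0.5)
        fitness, achieved = evaluator.evaluate({"cit_exp": mut})
        independent = -math.log10(
            sum((fitness_spec.targets[r] - achieved[r]) ** 2 for r in fitness_spec.targets)
        )
        assert fitness == pytest.approx(min(12.0, independent), abs=1e-12)

    def test_infeasible_is_sentinel(self, evaluator):
        # constraining glycolysis to zero starves the fixed biomass target
        mut = BoundsMutation("glyc", "constrain", 0.0, 0.0, 0.0)
        fitness, achieved = evaluator.evaluate({"glyc": mut})
        assert fitness == float("-inf")
        assert achieved == {}


class TestMutationScale:
    @pytest.mark.parametrize("B, b", [(0.5, 0.005), (0.0, 0.001), (-2.0, 0.02), (1.0, 0.01)])
    def test_scale_rule(self, B, b):
        assert mutation_scale(B) == pytest.approx(b, abs=1e-15)

    def test_laplace_moments(self):
        rng = np.random.default_rng(42)
        b = mutation_scale(1.0)
        n = 100_000
        draws = rng.laplace(0.0, b, size=n)
        se_mean = b * math.sqrt(2.0 / n)
        assert abs(draws.mean()) < 3 * se_mean
        # E|x| = b for Laplace(0, b); Var(|x|) = b^2
        se_abs = b / math.sqrt(n)
        assert abs(np.abs(draws).mean() - b) < 3 * se_abs


class TestMutationLimits:
    def test_constrain_limit_is_flux_over_fold(self, toy_model):
        lim = mutation_limits("cit_exp", "constrain", 4.0, 2.0, 1.0, toy_model)
        assert lim.lo == pytest.approx(0.5)  # |larger flux| / fold
        assert lim.hi == pytest.approx(2.0)
        assert lim.direction == 1

    def test_force_needs_clear_direction(self):
        model = build_model(
            [("EX_A", "A <==>", -1000, 1000), ("shuttle", "A <==> B", -1000, 1000),
             ("EX_B", "B <==>", -1000, 1000)]
        )
        with pytest.raises(ValueError, match="clear direction"):
            mutation_limits("shuttle", "force", 4.0, 1.0, 1.0, model)

    def test_force_capped_by_variability_maximum(self, chain_model):
        lim = mutation_limits("r1", "force", 4.0, 5.0, 8.0, chain_model)
        assert lim.hi == pytest.approx(10.0)   # FVA max of the capped chain
        assert lim.lo == pytest.approx(10.0)   # min(|smaller flux| * fold, max) clipped
        assert lim.direction == 1

    def test_zero_reference_cannot_constrain(self, toy_model):
        with pytest.raises(ValueError, match="zero reference"):
            mutation_limits("resp", "constrain", 4.0, 0.0, 0.0, toy_model)


class TestMutate:
    def limits(self):
        return MutationLimits("cit_exp", "constrain", 0.26, 1.03, 1)

    def test_initial_mutation_uniform_within_interval(self, toy_model):
        lim = self.limits()
        rng = np.random.default_rng(0)
        for _ in range(50):
            ind = mutate(Individual(), "cit_exp", rng, lim, toy_model)
            B = ind.mutations["cit_exp"].bound
            assert lim.lo <= B <= lim.hi
            assert ind.mutations["cit_exp"].ub == pytest.approx(B)

    def test_seeded_sequences_reproducible(self, toy_model):
        lim = self.limits()
        seqs = []
        for _ in range(2):
            rng = np.random.default_rng(7)
            ind = Individual()
            seq = []
            for _ in range(10):
                ind = mutate(ind, "cit_exp", rng, lim, toy_model)
                seq.append(ind.mutations["cit_exp"].bound)
            seqs.append(seq)
        assert seqs[0] == seqs[1]

    def test_steps_clipped_to_interval(self, toy_model):
        lim = MutationLimits("cit_exp", "constrain", 0.26, 0.2601, 1)  # razor-thin interval
        rng = np.random.default_rng(1)
        ind = Individual()
        for _ in range(100):
            ind = mutate(ind, "cit_exp", rng, lim, toy_model)
            assert lim.lo <= ind.mutations["cit_exp"].bound <= lim.hi

    def test_constrain_on_reversible_moves_both_bounds(self):
        model = build_model(
            [("EX_A", "A <==>", -1000, 1000), ("rev", "A <==> B", -1000, 1000),
             ("EX_B", "B <==>", -1000, 1000)]
        )
        lim = MutationLimits("rev", "constrain", 0.5, 2.0, 1)
        rng = np.random.default_rng(3)
        ind = mutate(Individual(), "rev", rng, lim, model)
        m = ind.mutations["rev"]
        assert m.ub == pytest.approx(m.bound)
        assert m.lb == pytest.approx(-m.bound)


class TestKeyReaction:
    class FakeEvaluator:
        def __init__(self, table):
            self.table = table

        def fitness(self, mutations):
            return self.table[frozenset(mutations)]

    def test_single_mutation_is_key(self):
        mut = {"rA": BoundsMutation("rA", "constrain", 1, 0, 1)}
        ev = self.FakeEvaluator({frozenset(["rA"]): 7.0, frozenset(): 1.0})
        assert identify_key_reaction(mut, ev) == "rA"

    def test_largest_drop_wins(self):
        mut = {r: BoundsMutation(r, "constrain", 1, 0, 1) for r in ("rA", "rB")}
        ev = self.FakeEvaluator(
            {frozenset(["rA", "rB"]): 8.0, frozenset(["rA"]): 7.9, frozenset(["rB"]): 2.0}
        )
        # removing rB barely matters; removing rA collapses fitness -> rA is key
        assert identify_key_reaction(mut, ev) == "rA"

    def test_tie_breaks_lexicographically(self):
        mut = {r: BoundsMutation(r, "constrain", 1, 0, 1) for r in ("rB", "rA")}
        ev = self.FakeEvaluator(
            {frozenset(["rA", "rB"]): 8.0, frozenset(["rA"]): 3.0, frozenset(["rB"]): 3.0}
        )
        assert identify_key_reaction(mut, ev) == "rA"

    def test_planted_fixture_brute_force(self, fitted_results, evaluator):
        for sol in fitted_results.solutions:
            mutations = {m.reaction_id: m for m in sol.mutations}
            full = evaluator.fitness(mutations)
            drops = {
                rid: full - evaluator.fitness({k: v for k, v in mutations.items() if k != rid})
                for rid in mutations
            }
            best = max(sorted(drops), key=lambda r: drops[r])
            assert sol.key_reaction == best


class TestEvolve:
    def test_planted_bottleneck_recovered(self, fitted_results):
        assert len(fitted_results.solutions) == 3
        for sol in fitted_results.solutions:
            assert sol.fitness >= 6.0
            assert sol.key_reaction == "cit_exp"

    def test_mutated_bounds_inside_allowed_intervals(self, fitted_results, evolution):
        for sol in fitted_results.solutions:
            for m in sol.mutations:
                lim = evolution.limits[m.reaction_id]
                assert lim.lo - 1e-12 <= m.bound <= lim.hi + 1e-12

    def test_seed_determinism(self, switched_model, fitness_spec, truth, fold_changes,
                              reference_fluxes):
        runs = []
        for _ in range(2):
            evo = make_evolution(switched_model, fitness_spec, truth, fold_changes,
                                 reference_fluxes)
            res = evo.fit(seed=5, generations=2000, n_runs=2, max_solutions=1)
            runs.append([s.to_dict() for s in res.solutions])
        assert runs[0] == runs[1]

    def test_blocking_drives_distinct_solutions(self, tables):
        spec2 = ToyModelSpec(n_bottlenecks=2)
        model, truth = make_toy_model(spec2)
        profiles, de = make_expression_tables(spec2)
        switched = apply_expression_switch(model, profiles["T2"])
        fs = make_fitness_spec(truth)
        refs = reference_fluxes_from_targets(switched, fs)
        folds = reaction_fold_changes(switched, de, profiles, ("T1-T2", "T2-T3"))
        evo = FluxBoundEvolution(switched, fs, truth.eligible, folds, refs,
                                 MutationParams(population_size=16))
        res = evo.fit(seed=3, generations=6000, n_runs=1, max_solutions=2)
        sols = res.solutions
        assert len(sols) >= 2
        keys = [s.key_reaction for s in sols]
        assert set(keys) >= {"cit_exp", "cit_syn"}
        # once blocked, a key reaction never reappears in later mutation sets
        for i, sol in enumerate(sols):
            blocked = {s.key_reaction for s in sols[:i]}
            assert blocked.isdisjoint({m.reaction_id for m in sol.mutations})
        # capture generations are non-decreasing within the run
        gens = [s.generation for s in sols]
        assert gens == sorted(gens)

    def test_empty_eligible_set_raises(self, switched_model, fitness_spec, reference_fluxes):
        with pytest.raises(ValueError, match="nothing to evolve"):
            FluxBoundEvolution(switched_model, fitness_spec, {}, {}, reference_fluxes)

    def test_solution_roundtrip(self, fitted_results):
        from fluxevolve.evolution import Solution

        for sol in fitted_results.solutions:
            assert Solution.from_dict(sol.to_dict()) == sol
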