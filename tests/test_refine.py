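import math

import pytest

from fluxevolve.evolution import BoundsMutation, MutationLimits
from fluxevolve.refine import (
    RefinedSolution,
    aggregate_targets,
    citric_percent_increase,
    extract_key_set,
    optimise_bounds,
    prune_solution,
    rank_mutations,
    refine_results,
    targets_to_dataframe,
)


def constrain(rid, B):
    return BoundsMutation(rid, "constrain", B, 0.0, B)


def force(rid, B):
    return BoundsMutation(rid, "force", B, B, 1000.0)


@pytest.fixture()
def near_perfect(evaluator):
    """A hand-built solution: exporter constrained almost exactly to target,
    plus a redundant neutral mutation on the futile cycle."""
    return {
        "cit_exp": constrain("cit_exp", 0.4001),
        "cycle_a": force("cycle_a", 5.0),
    }


class TestPrune:
    def test_redundant_mutation_removed(self, evaluator, near_perfect):
        refined = prune_solution(near_perfect, evaluator)
        assert set(refined.mutations) == {"cit_exp"}
        assert refined.fitness >= 6.0

    def test_minimal_solution_unchanged(self, evaluator):
        minimal = {"cit_exp": constrain("cit_exp", 0.4001)}
        refined = prune_solution(minimal, evaluator)
        assert set(refined.mutations) == {"cit_exp"}

    def test_fitness_threshold_never_violated(self, evaluator, fitted_results):
        for sol in fitted_results.solutions:
            refined = prune_solution(sol, evaluator)
            assert refined.fitness >= 6.0


class TestOptimise:
    def limits(self):
        return {"cit_exp": MutationLimits("cit_exp", "constrain", 0.263, 1.033, 1)}

    def test_displaced_bound_recovered(self, evaluator):
        start = {"cit_exp": constrain("cit_exp", 0.42)}  # 5% off the optimum at 0.4
        refined = RefinedSolution(None, start, evaluator.fitness(start))
        improved = optimise_bounds(refined, evaluator, self.limits())
        assert improved.fitness > refined.fitness
        assert abs(improved.mutations["cit_exp"].bound - 0.4) < abs(0.42 - 0.4)

    def test_one_dimensional_scan_agrees(self, evaluator):
        # the hill climb should land within one step of the scan's argmax
        scan = {B: evaluator.fitness({"cit_exp": constrain("cit_exp", B)})
                for B in [0.39, 0.395, 0.4, 0.405, 0.41]}
        best_scan = max(scan, key=scan.get)
        start = {"cit_exp": constrain("cit_exp", 0.41)}
        refined = RefinedSolution(None, start, evaluator.fitness(start))
        improved = optimise_bounds(refined, evaluator, self.limits())
        assert improved.fitness >= scan[best_scan] - 1e-6 or (
            abs(improved.mutations["cit_exp"].bound - best_scan) < 0.005
        )

    def test_fitness_never_decreases(self, evaluator, fitted_results):
        for sol in fitted_results.solutions:
            refined = prune_solution(sol, evaluator)
            improved = optimise_bounds(refined, evaluator, self.limits())
            assert improved.fitness >= refined.fitness - 1e-12


class TestRanking:
    def test_contributions_match_brute_force(self, evaluator, near_perfect):
        refined = RefinedSolution(None, dict(near_perfect), evaluator.fitness(near_perfect))
        ranking = rank_mutations(refined, evaluator)
        full = evaluator.fitness(near_perfect)
        for rid, contribution in ranking:
            rest = {k: v for k, v in near_perfect.items() if k != rid}
            assert contribution == pytest.approx(full - evaluator.fitness(rest), abs=1e-9)
        assert ranking[0][0] == "cit_exp"  # dominant mutation ranked first

    def test_single_mutation_list_of_one(self, evaluator):
        muts = {"cit_exp": constrain("cit_exp", 0.4001)}
        refined = RefinedSolution(None, muts, evaluator.fitness(muts))
        assert len(rank_mutations(refined, evaluator)) == 1


class TestKeySet:
    def test_planted_bottleneck_is_key_set(self, evaluator, truth, near_perfect):
        refined = RefinedSolution(None, dict(near_perfect), evaluator.fitness(near_perfect))
        refined.ranking = rank_mutations(refined, evaluator)
        key = extract_key_set(refined, evaluator, truth.unconstrained_citrate)
        assert key == ["cit_exp"]

    def test_already_unconstrained_returns_empty(self, evaluator, truth):
        refined = RefinedSolution(None, {}, evaluator.fitness({}))
        assert extract_key_set(refined, evaluator, truth.unconstrained_citrate) == []

    def test_key_set_subset_of_mutations(self, evaluator, truth, fitted_results):
        for sol in fitted_results.solutions:
            refined = prune_solution(sol, evaluator)
            refined.ranking = rank_mutations(refined, evaluator)
            key = extract_key_set(refined, evaluator, truth.unconstrained_citrate)
            assert set(key) <= set(refined.mutations)


class TestPercentIncrease:
    def test_matches_two_lp_oracle(self, evaluator, near_perfect):
        refined = RefinedSolution(None, dict(near_perfect), evaluator.fitness(near_perfect))
        pct = citric_percent_increase(refined, "cit_exp", evaluator)
        mutated = evaluator.citrate_flux(near_perfect)
        restored = evaluator.citrate_flux({"cycle_a": near_perfect["cycle_a"]})
        assert pct == pytest.approx(100.0 * (restored - mutated) / mutated)
        # restoring the exporter should roughly recover the 2.6x gap (~158%)
        assert pct == pytest.approx(158.0, abs=2.0)

    def test_zero_contribution_mutation_is_zero_percent(self, evaluator, near_perfect):
        refined = RefinedSolution(None, dict(near_perfect), evaluator.fitness(near_perfect))
        assert citric_percent_increase(refined, "cycle_a", evaluator) == pytest.approx(0.0)

    def test_unknown_reaction_raises(self, evaluator, near_perfect):
        refined = RefinedSolution(None, dict(near_perfect), evaluator.fitness(near_perfect))
        with pytest.raises(KeyError):
            citric_percent_increase(refined, "glyc", evaluator)


def refined_stub(run_id, key_set, percents, kinds=None):
    muts = {
        rid: BoundsMutation(rid, (kinds or {}).get(rid, "constrain"), 1.0, 0.0, 1.0)
        for rid in key_set
    }
    sol = RefinedSolution(None, muts, 7.0)
    sol.key_set = list(key_set)
    sol.percent_increase = dict(percents)
    sol.run_id_override = run_id
    return sol


class TestAggregate:
    def hand_tally_runs(self):
        return {
            0: [refined_stub(0, ["rA", "rB"], {"rA": 160.0, "rB": 80.0})],
            1: [refined_stub(1, ["rA"], {"rA": 150.0})],
            2: [refined_stub(2, ["rA", "rC"], {"rA": 140.0, "rC": 20.0},
                             kinds={"rC": "force"})],
        }

    def agg_model(self):
        from conftest import build_model

        return build_model(
            [("rA", "A -> B", 0, 1), ("rB", "A -> B", 0, 1), ("rC", "A -> B", 0, 1),
             ("EX_A", "A <==>", -1, 0), ("EX_B", "B <==>", 0, 1)]
        )

    def test_three_run_hand_tally(self):
        table = aggregate_targets(self.hand_tally_runs(), self.agg_model())
        by_id = {t.reaction_id: t for t in table}
        assert by_id["rA"].frequency == 3
        assert by_id["rB"].frequency == 1
        assert by_id["rC"].frequency == 1
        assert by_id["rA"].citric_percent_increase == pytest.approx(160.0)  # max across runs
        # sorted by (frequency desc, percent desc)
        assert [t.reaction_id for t in table] == ["rA", "rB", "rC"]

    def test_direction_flip_involution(self):
        table = aggregate_targets(self.hand_tally_runs(), self.agg_model())
        by_id = {t.reaction_id: t for t in table}
        assert by_id["rA"].direction == "up-regulate"    # constrained in silico
        assert by_id["rC"].direction == "down-regulate"  # forced in silico
        back = {"up-regulate": "constrain", "down-regulate": "force"}
        assert back[by_id["rA"].direction] == "constrain"
        assert back[by_id["rC"].direction] == "force"

    def test_prominence_filter_excludes_weak_target(self):
        table = aggregate_targets(self.hand_tally_runs(), self.agg_model(),
                                  prominent_only=True, min_increase=50.0)
        ids = {t.reaction_id for t in table}
        assert "rC" not in ids          # 20% effect decoy dropped
        assert {"rA", "rB"} <= ids

    def test_frequency_na_mode(self):
        table = aggregate_targets(self.hand_tally_runs(), self.agg_model(),
                                  frequency_na=True)
        assert all(t.frequency is None for t in table)

    def test_dataframe_columns(self):
        df = targets_to_dataframe(aggregate_targets(self.hand_tally_runs(), self.agg_model()))
        assert list(df.columns) == [
            "reaction_id", "name", "equation", "target", "frequency",
            "citric_percent_increase",
        ]


class TestFullRefinement:
    def test_refine_results_end_to_end(self, fitted_results, truth):
        refinement = refine_results(fitted_results)
        table = refinement.targets()
        assert [t.reaction_id for t in table][0] == "cit_exp"
        assert table[0].frequency == len(fitted_results.runs)
        assert table[0].direction == "up-regulate"
        true_pct = 100.0 * (truth.unconstrained_citrate - truth.constrained_citrate) / truth.constrained_citrate
        assert table[0].citric_percent_increase == pytest.approx(true_pct, rel=0.02)
        matrix = refinement.membership_matrix()
        assert matrix.loc["cit_exp"].sum() == len(fitted_results.runs)
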