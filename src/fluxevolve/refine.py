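"""Post-processing of evolved solutions into a ranked target table.

Captured solutions are simplified (mutations removed while the fitness stays
over the threshold), micro-optimised (coordinate-wise hill climb on each
bound), and their mutations ranked by fitness contribution under single-bound
complementation.  Walking the ranked list and cumulatively restoring original
bounds until a *revised* fitness — the same least-squares score with the
product target replaced by the unconstrained optimum — crosses its threshold
yields each solution's key reaction set.  Key sets are aggregated across
independent runs into intervention suggestions: the direction is the opposite
of the in-silico mutation (a constrained reaction is an up-regulation target),
the frequency counts runs supporting the reaction, and the percent increase
is the gain in maximal product flux when that reaction's bounds are restored
while all other mutations are retained.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from .evolution import (
    BoundsMutation,
    EvolutionResults,
    FitnessSpec,
    MutationLimits,
    Solution,
    SolutionEvaluator,
    _build_mutation,
)
from .model import MetabolicModel, format_equation

__all__ = [
    "RefinedSolution",
    "TargetSuggestion",
    "RefinementResults",
    "prune_solution",
    "optimise_bounds",
    "rank_mutations",
    "extract_key_set",
    "citric_percent_increase",
    "aggregate_targets",
    "refine_results",
]

logger = logging.getLogger(__name__)

REVISED_THRESHOLD = 3.5
PROMINENCE_PERCENT = 50.0

_DIRECTION_FLIP = {"constrain": "up-regulate", "force": "down-regulate"}


@dataclass
class RefinedSolution:
    """A pruned, optimised solution with ranked mutations and its key set."""

    parent: Solution
    mutations: dict[str, BoundsMutation]
    fitness: float
    ranking: list[tuple[str, float]] = field(default_factory=list)  # (rid, contribution), desc
    key_set: list[str] = field(default_factory=list)
    percent_increase: dict[str, float] = field(default_factory=dict)

    @property
    def run_id(self) -> int:
        return self.parent.run_id


@dataclass(frozen=True)
class TargetSuggestion:
    """One row of the aggregated target table."""

    reaction_id: str
    name: str
    equation: str
    direction: Literal["up-regulate", "down-regulate"]
    frequency: int | None  # None for targets from an exclude-previous-targets run
    citric_percent_increase: float


# ---------------------------------------------------------------------------
# Per-solution refinement


def _contributions(
    mutations: Mapping[str, BoundsMutation], evaluator: SolutionEvaluator
) -> dict[str, float]:
    full = evaluator.fitness(mutations)
    out = {}
    for rid in mutations:
        rest = {k: v for k, v in mutations.items() if k != rid}
        out[rid] = full - evaluator.fitness(rest)
    return out


def prune_solution(
    solution: Solution | Mapping[str, BoundsMutation],
    evaluator: SolutionEvaluator,
    threshold: float | None = None,
) -> RefinedSolution:
    """Remove mutations greedily while the fitness stays over the threshold.

    Candidates are tried in ascending order of contribution (ties by id) and
    the pass repeats until no removal succeeds; removing low-contribution
    mutations first maximises the number of removals.
    """
    threshold = evaluator.spec.threshold if threshold is None else threshold
    if isinstance(solution, Solution):
        parent, mutations = solution, {m.reaction_id: m for m in solution.mutations}
    else:
        parent, mutations = None, dict(solution)
    changed = True
    while changed:
        changed = False
        order = sorted(_contributions(mutations, evaluator).items(), key=lambda kv: (kv[1], kv[0]))
        for rid, _ in order:
            trial = {k: v for k, v in mutations.items() if k != rid}
            if evaluator.fitness(trial) >= threshold:
                logger.debug("pruned mutation on %s", rid)
                mutations = trial
                changed = True
                break
    return RefinedSolution(parent, mutations, evaluator.fitness(mutations))


def optimise_bounds(
    refined: RefinedSolution,
    evaluator: SolutionEvaluator,
    limits: Mapping[str, MutationLimits],
    step_fraction: float = 0.01,
    max_sweeps: int = 20,
) -> RefinedSolution:
    """Coordinate-wise hill climb on each surviving bound.

    Steps of ``step_fraction`` x |B| (the zero-bound Laplace scale at B = 0)
    in both directions, accepting only fitness-improving moves inside the
    allowed interval; at most ``max_sweeps`` passes.  Fitness never decreases.
    """
    mutations = dict(refined.mutations)
    model = evaluator.model
    best = evaluator.fitness(mutations)
    for _ in range(max_sweeps):
        improved = False
        for rid in sorted(mutations):
            lim = limits.get(rid)
            if lim is None:
                continue
            B = mutations[rid].bound
            step = step_fraction * abs(B) if B != 0 else 0.001
            for candidate in (B + step, B - step):
                candidate = min(max(candidate, lim.lo), lim.hi)
                trial = dict(mutations)
                trial[rid] = _build_mutation(lim, candidate, model)
                f = evaluator.fitness(trial)
                if f > best:
                    mutations, best, improved = trial, f, True
                    break
        if not improved:
            break
    return RefinedSolution(refined.parent, mutations, best)


def rank_mutations(
    refined: RefinedSolution, evaluator: SolutionEvaluator
) -> list[tuple[str, float]]:
    """Mutations ranked by fitness contribution (descending; ties by id)."""
    contribs = _contributions(refined.mutations, evaluator)
    return sorted(contribs.items(), key=lambda kv: (-kv[1], kv[0]))


def revised_evaluator(
    evaluator: SolutionEvaluator, unconstrained_citrate: float
) -> SolutionEvaluator:
    """The same fitness with the product target replaced by its unconstrained optimum."""
    spec = evaluator.spec
    targets = dict(spec.targets)
    targets[spec.citrate_id] = unconstrained_citrate
    return SolutionEvaluator(evaluator.model, replace(spec, targets=targets))


def extract_key_set(
    refined: RefinedSolution,
    evaluator: SolutionEvaluator,
    unconstrained_citrate: float,
    revised_threshold: float = REVISED_THRESHOLD,
) -> list[str]:
    """Key reactions: the ranked prefix whose cumulative restoration recovers
    near-unconstrained product output (revised fitness >= threshold)."""
    revised = revised_evaluator(evaluator, unconstrained_citrate)
    ranking = refined.ranking or rank_mutations(refined, evaluator)
    mutations = dict(refined.mutations)
    restored: list[str] = []
    if revised.fitness(mutations) >= revised_threshold:
        return restored
    for rid, _ in ranking:
        del mutations[rid]
        restored.append(rid)
        if revised.fitness(mutations) >= revised_threshold:
            return restored
    logger.warning(
        "revised fitness never reached %.2f; returning all %d mutations",
        revised_threshold,
        len(restored),
    )
    return restored


def citric_percent_increase(
    refined: RefinedSolution, reaction_id: str, evaluator: SolutionEvaluator
) -> float:
    """Percent rise in maximal product flux when one reaction's bounds are
    restored while the other mutations are retained.  NaN when the mutated
    product flux is zero (excluded from ranking)."""
    if reaction_id not in refined.mutations:
        raise KeyError(f"{reaction_id} not mutated in this solution")
    mutated = evaluator.citrate_flux(refined.mutations)
    rest = {k: v for k, v in refined.mutations.items() if k != reaction_id}
    restored = evaluator.citrate_flux(rest)
    if mutated == 0 or math.isnan(mutated):
        return float("nan")
    return 100.0 * (restored - mutated) / mutated


# ---------------------------------------------------------------------------
# Aggregation across runs


def aggregate_targets(
    refined_by_run: Mapping[int, Sequence[RefinedSolution]],
    model: MetabolicModel,
    min_increase: float = PROMINENCE_PERCENT,
    prominent_only: bool = False,
    frequency_na: bool = False,
) -> list[TargetSuggestion]:
    """Aggregate key sets across runs into a ranked target table.

    Frequency counts the runs whose key sets contain the reaction; the percent
    increase is the highest across solutions containing the reaction; rows are
    sorted by (frequency desc, percent increase desc).  With
    ``prominent_only`` rows below ``min_increase`` percent are dropped; with
    ``frequency_na`` frequencies are reported as missing (for
    exclude-previous-targets runs).
    """
    freq: dict[str, int] = {}
    best_pct: dict[str, float] = {}
    kind: dict[str, str] = {}
    for run_id, sols in refined_by_run.items():
        run_rids: set[str] = set()
        for sol in sols:
            for rid in sol.key_set:
                run_rids.add(rid)
                pct = sol.percent_increase.get(rid, float("nan"))
                if not math.isnan(pct):
                    best_pct[rid] = max(best_pct.get(rid, -math.inf), pct)
                kind[rid] = sol.mutations[rid].kind if rid in sol.mutations else kind.get(rid, "constrain")
        for rid in run_rids:
            freq[rid] = freq.get(rid, 0) + 1
    rows: list[TargetSuggestion] = []
    for rid in freq:
        pct = best_pct.get(rid, float("nan"))
        if math.isnan(pct):
            continue
        if prominent_only and pct < min_increase:
            continue
        rxn = model.reactions[rid]
        rows.append(
            TargetSuggestion(
                reaction_id=rid,
                name=rxn.name,
                equation=format_equation(rxn),
                direction=_DIRECTION_FLIP[kind[rid]],
                frequency=None if frequency_na else freq[rid],
                citric_percent_increase=pct,
            )
        )
    rows.sort(key=lambda t: (-(t.frequency or 0), -t.citric_percent_increase, t.reaction_id))
    return rows


def targets_to_dataframe(targets: Iterable[TargetSuggestion]) -> pd.DataFrame:
    rows = [
        {
            "reaction_id": t.reaction_id,
            "name": t.name,
            "equation": t.equation,
            "target": t.direction,
            "frequency": t.frequency,
            "citric_percent_increase": t.citric_percent_increase,
        }
        for t in targets
    ]
    return pd.DataFrame(
        rows,
        columns=["reaction_id", "name", "equation", "target", "frequency", "citric_percent_increase"],
    )


class RefinementResults:
    """Refined solutions, per-run key sets and the aggregated target table."""

    def __init__(
        self,
        refined_by_run: dict[int, list[RefinedSolution]],
        model: MetabolicModel,
        min_increase: float = PROMINENCE_PERCENT,
    ) -> None:
        self.refined_by_run = refined_by_run
        self.model = model
        self.min_increase = min_increase

    @property
    def refined(self) -> list[RefinedSolution]:
        return [s for sols in self.refined_by_run.values() for s in sols]

    def targets(self, prominent_only: bool = False, frequency_na: bool = False) -> list[TargetSuggestion]:
        return aggregate_targets(
            self.refined_by_run,
            self.model,
            min_increase=self.min_increase,
            prominent_only=prominent_only,
            frequency_na=frequency_na,
        )

    def summary(self, prominent_only: bool = False) -> pd.DataFrame:
        return targets_to_dataframe(self.targets(prominent_only=prominent_only))

    def membership_matrix(self) -> pd.DataFrame:
        """Per-run 0/1 membership of each targeted reaction (plain-table view
        of the multi-run comparison)."""
        all_rids = sorted({rid for s in self.refined for rid in s.key_set})
        data = {}
        for run_id, sols in sorted(self.refined_by_run.items()):
            members = {rid for s in sols for rid in s.key_set}
            data[f"run_{run_id}"] = [int(rid in members) for rid in all_rids]
        return pd.DataFrame(data, index=pd.Index(all_rids, name="reaction_id"))


def refine_results(
    results: EvolutionResults,
    unconstrained_citrate: float | None = None,
    revised_threshold: float = REVISED_THRESHOLD,
    min_increase: float = PROMINENCE_PERCENT,
    optimise: bool = True,
) -> RefinementResults:
    """Full refinement of an :class:`EvolutionResults`: prune, optimise, rank,
    key-set extraction and percent-increase computation per solution."""
    evo = results.model_obj
    evaluator = evo.evaluator
    if unconstrained_citrate is None:
        unconstrained_citrate = evaluator.citrate_flux({})
    refined_by_run: dict[int, list[RefinedSolution]] = {}
    for run_id, sols in results.runs.items():
        refined_list = []
        for sol in sols:
            refined = prune_solution(sol, evaluator)
            if optimise:
                refined = optimise_bounds(refined, evaluator, evo.limits)
            refined.ranking = rank_mutations(refined, evaluator)
            refined.key_set = extract_key_set(
                refined, evaluator, unconstrained_citrate, revised_threshold
            )
            refined.percent_increase = {
                rid: citric_percent_increase(refined, rid, evaluator)
                for rid in refined.mutations
            }
            refined_list.append(refined)
        refined_by_run[run_id] = refined_list
    return RefinementResults(refined_by_run, evo.model, min_increase=min_increase)
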