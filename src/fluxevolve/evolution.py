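"""Transcriptome-guided evolution of flux bounds.

The estimation problem: find sets of flux-bound changes ("mutations") on
differentially expressed reactions that make the model's maximal product flux
reproduce an observed (constrained) value while key exchange fluxes — carbon
inputs, phosphate and growth — stay at their reference values.  Fit quality is
a least-squares score over five tracked exchange fluxes,

    F = -log10 sum_i (f_t,i - f_a,i)^2,

capped at a finite value for perfect fits.  Down-regulated reactions may be
*constrained* (bounds tightened toward zero, no tighter than reference flux /
fold change) and up-regulated reactions *forced* (a minimum flux imposed, up
to the flux-variability maximum); bounds evolve under a genetic algorithm
whose mutation steps are Laplace-distributed with scale b = 0.01|B| (b = 0.001
at B = 0).  Whenever an individual crosses the fitness threshold the solution
is captured, its key reaction (largest fitness contribution under
single-bound complementation) is reset across the population and blocked, and
evolution continues — driving multiple distinct solutions per run.

Exposed in a model-fitting shape: build a :class:`FluxBoundEvolution` from a
metabolic model plus fitness/eligibility inputs, call :meth:`fit`, and read
the captured solutions off the returned :class:`EvolutionResults`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import MetabolicModel, flux_variability, solve_fba

__all__ = [
    "FitnessSpec",
    "MutationParams",
    "MutationLimits",
    "BoundsMutation",
    "Individual",
    "Solution",
    "SolutionEvaluator",
    "fitness_from_deviations",
    "mutation_scale",
    "mutation_limits",
    "mutate",
    "identify_key_reaction",
    "reference_fluxes_from_targets",
    "FluxBoundEvolution",
    "EvolutionResults",
]

logger = logging.getLogger(__name__)

FITNESS_CAP = 12.0
FITNESS_THRESHOLD = 6.0
NEG_INF = float("-inf")


@dataclass(frozen=True)
class FitnessSpec:
    """Target exchange fluxes for the least-squares fitness.

    ``tracked`` maps role labels (internal_phosphate, glucose, xylose,
    biomass, citrate) to reaction ids; ``targets`` gives the target flux f_t
    per reaction id.  The citrate target is the constrained (observed) value;
    the others are the model's unconstrained reference values.
    """

    tracked: Mapping[str, str]
    targets: Mapping[str, float]
    citrate_id: str
    cap: float = FITNESS_CAP
    threshold: float = FITNESS_THRESHOLD

    def __post_init__(self) -> None:
        if self.citrate_id not in self.targets:
            raise ValueError("citrate_id must have a target flux")
        missing = set(self.tracked.values()) - set(self.targets)
        if missing:
            raise ValueError(f"tracked exchanges without targets: {missing}")


@dataclass
class MutationParams:
    """Mutation-operator and GA driver parameters (all configurable)."""

    laplace_location: float = 0.0
    scale_factor: float = 0.01     # b = scale_factor * |B| for |B| > 0
    zero_scale: float = 0.001      # b at B = 0
    fold_threshold: float = 2.0
    generations: int = 150_000
    fitness_threshold: float = FITNESS_THRESHOLD
    population_size: int = 50
    tournament_size: int = 2
    elitism: int = 1
    mutation_probability: float = 0.3


@dataclass(frozen=True)
class MutationLimits:
    """Allowed interval for the evolved bound magnitude B of one reaction.

    ``kind='constrain'``: B ranges from the constraint limit (|reference
    flux| / fold change) up to the original flux magnitude and caps the
    reaction's flux.  ``kind='force'``: B ranges from the minimum forced flux
    up to the flux-variability maximum and raises the reaction's minimum flux.
    ``direction`` is the sign of the reaction's flux.
    """

    reaction_id: str
    kind: Literal["constrain", "force"]
    lo: float
    hi: float
    direction: int  # +1 or -1

    def __post_init__(self) -> None:
        if self.lo < 0 or self.hi < self.lo:
            raise ValueError(f"degenerate limits for {self.reaction_id}: [{self.lo}, {self.hi}]")


@dataclass(frozen=True)
class BoundsMutation:
    """One evolved flux-bound change: the controlled magnitude B plus the
    (lb, ub) actually applied to the model."""

    reaction_id: str
    kind: Literal["constrain", "force"]
    bound: float  # B, the evolved magnitude (>= 0)
    lb: float
    ub: float


@dataclass
class Individual:
    """A set of flux-bound mutations with its fitness under the LP."""

    mutations: dict[str, BoundsMutation] = field(default_factory=dict)
    fitness: float = NEG_INF
    achieved: dict[str, float] = field(default_factory=dict)

    def copy(self) -> "Individual":
        return Individual(dict(self.mutations), self.fitness, dict(self.achieved))


@dataclass(frozen=True)
class Solution:
    """A captured evolved solution (fitness >= threshold at capture time)."""

    run_id: int
    seed: int
    generation: int
    fitness: float
    mutations: tuple[BoundsMutation, ...]
    key_reaction: str
    achieved: Mapping[str, float]

    def to_dict(self) -> dict:
        return {
            "run_id": self.run_id,
            "seed": self.seed,
            "generation": self.generation,
            "fitness": self.fitness,
            "key_reaction": self.key_reaction,
            "achieved": dict(self.achieved),
            "mutations": [
                {
                    "reaction_id": m.reaction_id,
                    "kind": m.kind,
                    "bound": m.bound,
                    "lb": m.lb,
                    "ub": m.ub,
                }
                for m in self.mutations
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "Solution":
        return cls(
            run_id=data["run_id"],
            seed=data["seed"],
            generation=data["generation"],
            fitness=data["fitness"],
            key_reaction=data["key_reaction"],
            achieved=data.get("achieved", {}),
            mutations=tuple(
                BoundsMutation(m["reaction_id"], m["kind"], m["bound"], m["lb"], m["ub"])
                for m in data["mutations"]
            ),
        )


# ---------------------------------------------------------------------------
# Fitness


def fitness_from_deviations(deviations: Sequence[float], cap: float = FITNESS_CAP) -> float:
    """F = -log10 sum d_i^2, capped; the cap replaces the divergence at 0."""
    total = float(sum(d * d for d in deviations))
    if total <= 0.0:
        return cap
    return min(cap, -math.log10(total))


class SolutionEvaluator:
    """Evaluates mutation sets against a model and fitness spec.

    The actual fluxes f_a are read from an LP maximising the product (citrate)
    exchange with the other tracked exchanges fixed at their targets and the
    mutation bounds applied.  Results are memoised on the frozen mutation set.
    """

    def __init__(self, model: MetabolicModel, spec: FitnessSpec) -> None:
        self.model = model
        self.spec = spec
        self._fixed = {
            rid: (t, t) for rid, t in spec.targets.items() if rid != spec.citrate_id
        }
        self._cache: dict[tuple, tuple[float, dict[str, float]]] = {}

    def base_constraints(self) -> dict[str, tuple[float, float]]:
        return dict(self._fixed)

    def _key(self, mutations: Mapping[str, BoundsMutation]) -> tuple:
        return tuple(sorted((m.reaction_id, m.lb, m.ub) for m in mutations.values()))

    def solve(self, mutations: Mapping[str, BoundsMutation]):
        bounds = self.base_constraints()
        for m in mutations.values():
            bounds[m.reaction_id] = (m.lb, m.ub)
        return solve_fba(
            self.model, objective=self.spec.citrate_id, sense="max", extra_constraints=bounds
        )

    def evaluate(self, mutations: Mapping[str, BoundsMutation]) -> tuple[float, dict[str, float]]:
        key = self._key(mutations)
        if key in self._cache:
            return self._cache[key]
        state = self.solve(mutations)
        if not state.ok:
            result = (NEG_INF, {})
        else:
            achieved = {rid: state.fluxes[rid] for rid in self.spec.targets}
            devs = [self.spec.targets[rid] - achieved[rid] for rid in self.spec.targets]
            result = (fitness_from_deviations(devs, self.spec.cap), achieved)
        self._cache[key] = result
        return result

    def fitness(self, mutations: Mapping[str, BoundsMutation]) -> float:
        return self.evaluate(mutations)[0]

    def citrate_flux(self, mutations: Mapping[str, BoundsMutation]) -> float:
        """Maximal citrate flux under the mutation set (nan if infeasible)."""
        state = self.solve(mutations)
        return state.objective_value if state.ok else float("nan")

    def refresh(self, individual: Individual) -> None:
        individual.fitness, individual.achieved = self.evaluate(individual.mutations)


def reference_fluxes_from_targets(
    model: MetabolicModel, spec: FitnessSpec
) -> dict[str, float]:
    """Reference flux per reaction from the unconstrained product-maximising LP
    with the tracked exchanges fixed at their targets."""
    fixed = {rid: (t, t) for rid, t in spec.targets.items() if rid != spec.citrate_id}
    state = solve_fba(model, objective=spec.citrate_id, sense="max", extra_constraints=fixed)
    if not state.ok:
        raise RuntimeError(f"reference LP not optimal: {state.status}")
    return state.fluxes


# ---------------------------------------------------------------------------
# Mutation operator


def mutation_scale(B: float, params: MutationParams | None = None) -> float:
    """Laplace scale for a mutation applied to bound B: 0.01|B|, or 0.001 at 0."""
    params = params or MutationParams()
    return params.scale_factor * abs(B) if B != 0 else params.zero_scale


def mutation_limits(
    reaction_id: str,
    kind: Literal["constrain", "force"],
    fold_change: float,
    flux_t1: float,
    flux_t3: float,
    model: MetabolicModel,
    base_constraints: Mapping[str, tuple[float, float]] | None = None,
    assignment: Literal["larger_constrain", "t1_constrain"] = "larger_constrain",
) -> MutationLimits:
    """Allowed interval for the evolved bound, from fold change and reference fluxes.

    Constraining may tighten no further than |reference| / fold_change, the
    reference being the larger-magnitude of the two timepoint fluxes (or the
    T1 flux under ``assignment='t1_constrain'``).  Forcing must impose at
    least |reference| * fold_change using the other timepoint's flux, and
    never beyond the flux-variability maximum; forcing is disallowed for
    reactions without a clear direction of flux (variability straddling zero).
    """
    if fold_change < 1.0:
        raise ValueError(f"{reaction_id}: fold change {fold_change} < 1")
    if assignment == "larger_constrain":
        ref_constrain, ref_force = sorted((flux_t1, flux_t3), key=abs)[::-1]
    else:
        ref_constrain, ref_force = flux_t1, flux_t3
    if kind == "constrain":
        ref = abs(ref_constrain)
        if ref == 0.0:
            raise ValueError(f"{reaction_id}: zero reference flux, nothing to constrain")
        direction = 1 if ref_constrain >= 0 else -1
        return MutationLimits(reaction_id, "constrain", ref / fold_change, ref, direction)
    # force
    vmin, vmax = flux_variability(model, reaction_id, fixed=base_constraints)
    if vmin < -1e-9 and vmax > 1e-9:
        raise ValueError(
            f"{reaction_id}: no clear direction of flux (variability [{vmin:.4g}, {vmax:.4g}])"
        )
    direction = 1 if vmax > 1e-9 else -1
    max_allowable = vmax if direction == 1 else -vmin
    min_forced = min(abs(ref_force) * fold_change, max_allowable)
    return MutationLimits(reaction_id, "force", min_forced, max_allowable, direction)


def _build_mutation(limits: MutationLimits, B: float, model: MetabolicModel) -> BoundsMutation:
    rxn = model.reactions[limits.reaction_id]
    B = min(max(B, limits.lo), limits.hi)
    if limits.kind == "constrain":
        if limits.direction >= 0:
            ub = B
            lb = -B if rxn.reversible else max(rxn.lower_bound, -B)
        else:
            lb = -B
            ub = B if rxn.reversible else min(rxn.upper_bound, B)
        # both bounds move toward zero, never past the original box
        lb = max(lb, rxn.lower_bound)
        ub = min(ub, rxn.upper_bound)
    else:  # force: raise the minimum flux magnitude
        if limits.direction >= 0:
            lb, ub = B, rxn.upper_bound
        else:
            lb, ub = rxn.lower_bound, -B
    return BoundsMutation(limits.reaction_id, limits.kind, B, lb, ub)


def mutate(
    individual: Individual,
    reaction_id: str,
    rng: np.random.Generator,
    limits: MutationLimits,
    model: MetabolicModel,
    params: MutationParams | None = None,
) -> Individual:
    """Return a copy with a new or perturbed mutation on ``reaction_id``.

    First mutation on a reaction: uniform draw over the allowed interval.
    Subsequent mutations: a Laplace(0, b(B)) step added to the existing bound,
    clipped to the interval.
    """
    params = params or MutationParams()
    new = individual.copy()
    if reaction_id in new.mutations:
        B = new.mutations[reaction_id].bound
        B = B + rng.laplace(params.laplace_location, mutation_scale(B, params))
    else:
        B = rng.uniform(limits.lo, limits.hi)
    new.mutations[reaction_id] = _build_mutation(limits, B, model)
    return new


# ---------------------------------------------------------------------------
# Key-reaction identification


def identify_key_reaction(
    mutations: Mapping[str, BoundsMutation], evaluator: SolutionEvaluator
) -> str:
    """The mutated reaction whose reversion to original bounds costs the most
    fitness (complementation).  Deterministic lexicographic tie-break."""
    if not mutations:
        raise ValueError("no mutations to analyse")
    full = evaluator.fitness(mutations)
    best_rid, best_drop = None, -math.inf
    for rid in sorted(mutations):
        rest = {k: v for k, v in mutations.items() if k != rid}
        drop = full - evaluator.fitness(rest)
        if drop > best_drop:
            best_rid, best_drop = rid, drop
    return best_rid


# ---------------------------------------------------------------------------
# The GA driver, model-fitting style


class FluxBoundEvolution:
    """Evolutionary fit of flux-bound mutations to target exchange fluxes.

    Parameters
    ----------
    model
        The (expression-switched) metabolic model.
    spec
        Fitness targets for the five tracked exchanges.
    eligibility
        reaction id -> "constrain" | "force", from differential expression.
    fold_changes
        reaction id -> reaction-level fold change (>= the eligibility
        threshold) for every eligible reaction.
    reference_fluxes
        reaction id -> (flux_T1, flux_T3) pairs; a plain float is used for
        both timepoints.
    params
        GA and mutation-operator parameters.
    """

    def __init__(
        self,
        model: MetabolicModel,
        spec: FitnessSpec,
        eligibility: Mapping[str, str],
        fold_changes: Mapping[str, float],
        reference_fluxes: Mapping[str, float | tuple[float, float]],
        params: MutationParams | None = None,
        limit_assignment: Literal["larger_constrain", "t1_constrain"] = "larger_constrain",
    ) -> None:
        if not eligibility:
            raise ValueError("nothing to evolve: eligible reaction set is empty")
        self.model = model
        self.spec = spec
        self.params = params or MutationParams()
        self.evaluator = SolutionEvaluator(model, spec)
        self.limits: dict[str, MutationLimits] = {}
        base = self.evaluator.base_constraints()
        for rid, kind in eligibility.items():
            refs = reference_fluxes.get(rid, 0.0)
            f1, f3 = refs if isinstance(refs, tuple) else (refs, refs)
            try:
                self.limits[rid] = mutation_limits(
                    rid, kind, fold_changes[rid], f1, f3, model,
                    base_constraints=base, assignment=limit_assignment,
                )
            except ValueError as err:
                logger.info("reaction %s excluded from evolution: %s", rid, err)
        if not self.limits:
            raise ValueError("nothing to evolve: all eligible reactions have degenerate limits")

    # -- single run ------------------------------------------------------

    def _run(
        self,
        run_id: int,
        seed: int,
        generations: int,
        max_solutions: int | None,
    ) -> list[Solution]:
        rng = np.random.default_rng(seed)
        p = self.params
        population = [Individual() for _ in range(p.population_size)]
        for ind in population:
            self.evaluator.refresh(ind)
        blocked: set[str] = set()
        solutions: list[Solution] = []
        available = sorted(self.limits)

        for gen in range(1, generations + 1):
            open_rids = [r for r in available if r not in blocked]
            if not open_rids:
                break
            # selection with elitism
            order = sorted(range(len(population)), key=lambda i: population[i].fitness, reverse=True)
            new_pop = [population[order[i]].copy() for i in range(p.elitism)]
            while len(new_pop) < p.population_size:
                i, j = rng.integers(0, len(population), size=2)
                winner = population[i] if population[i].fitness >= population[j].fitness else population[j]
                new_pop.append(winner.copy())
            # mutation
            for idx in range(p.elitism, len(new_pop)):
                if rng.random() < p.mutation_probability:
                    rid = open_rids[rng.integers(0, len(open_rids))]
                    new_pop[idx] = mutate(new_pop[idx], rid, rng, self.limits[rid], self.model, p)
                    self.evaluator.refresh(new_pop[idx])
            population = new_pop
            # capture
            best = max(population, key=lambda ind: ind.fitness)
            if best.fitness >= p.fitness_threshold and best.mutations:
                key = identify_key_reaction(best.mutations, self.evaluator)
                sol = Solution(
                    run_id=run_id,
                    seed=seed,
                    generation=gen,
                    fitness=best.fitness,
                    mutations=tuple(best.mutations[r] for r in sorted(best.mutations)),
                    key_reaction=key,
                    achieved=dict(best.achieved),
                )
                solutions.append(sol)
                logger.info(
                    "run %d gen %d: captured solution F=%.3f key=%s", run_id, gen, sol.fitness, key
                )
                blocked.add(key)
                for ind in population:
                    if key in ind.mutations:
                        del ind.mutations[key]
                        self.evaluator.refresh(ind)
                if max_solutions is not None and len(solutions) >= max_solutions:
                    break
        return solutions

    def fit(
        self,
        seed: int,
        generations: int | None = None,
        n_runs: int = 1,
        max_solutions: int | None = None,
    ) -> "EvolutionResults":
        """Run ``n_runs`` independent evolutions and collect captured solutions.

        Per-run seeds are spawned deterministically from ``seed`` via
        ``SeedSequence(seed, run_index)``.
        """
        generations = generations if generations is not None else self.params.generations
        runs: dict[int, list[Solution]] = {}
        run_seeds: dict[int, int] = {}
        for run_id in range(n_runs):
            run_seed = int(np.random.SeedSequence((seed, run_id)).generate_state(1)[0] % (2**31))
            run_seeds[run_id] = run_seed
            runs[run_id] = self._run(run_id, run_seed, generations, max_solutions)
        return EvolutionResults(self, runs, run_seeds, seed, generations)


class EvolutionResults:
    """Captured solutions from one or more evolutionary runs."""

    def __init__(
        self,
        model_obj: FluxBoundEvolution,
        runs: dict[int, list[Solution]],
        run_seeds: dict[int, int],
        master_seed: int,
        generations: int,
    ) -> None:
        self.model_obj = model_obj
        self.runs = runs
        self.run_seeds = run_seeds
        self.master_seed = master_seed
        self.generations = generations

    @property
    def solutions(self) -> list[Solution]:
        return [sol for run in self.runs.values() for sol in run]

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "run_id": s.run_id,
                "generation": s.generation,
                "fitness": s.fitness,
                "key_reaction": s.key_reaction,
                "n_mutations": len(s.mutations),
            }
            for s in self.solutions
        ]
        return pd.DataFrame(rows, columns=["run_id", "generation", "fitness", "key_reaction", "n_mutations"])

    def refine(self, unconstrained_citrate: float | None = None, **kwargs):
        """Post-process the captured solutions; see :mod:`fluxevolve.refine`."""
        from .refine import refine_results

        return refine_results(self, unconstrained_citrate=unconstrained_citrate, **kwargs)
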