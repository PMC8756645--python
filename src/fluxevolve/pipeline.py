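"""End-to-end orchestration: expression switch -> eligibility -> evolution ->
refinement -> target table, with a manifest tying every output to the master
seed."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import pathlib
from dataclasses import dataclass
from typing import Any, Mapping

import yaml

from . import __version__
from .dfba import CultureState, DfbaProblem, KineticParameters, simulate
from .evolution import (
    FluxBoundEvolution,
    FitnessSpec,
    MutationParams,
    reference_fluxes_from_targets,
)
from .expression import (
    eligible_reactions,
    reaction_differential,
    read_de_tsv,
    read_expression_tsv,
    apply_expression_switch,
    FOLD_THRESHOLD,
    Q_THRESHOLD,
)
from .model import MetabolicModel, read_model_tsv
from .refine import RefinementResults

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "reaction_fold_changes"]


@dataclass
class RunConfig:
    """Configuration of one full pipeline run.

    Defaults follow the study conventions: citrate target from the config,
    fitness threshold 6, revised threshold 3.5, 2-fold eligibility,
    150,000 generations, 8 independent runs, 50% prominence cutoff.
    """

    model: str
    expression: str
    de: str
    tracked: dict[str, str]
    targets: dict[str, float]
    citrate_id: str
    comparisons: tuple[str, str] = ("T1-T2", "T2-T3")
    switch_timepoint: str = "T2"
    fold_threshold: float = FOLD_THRESHOLD
    q_threshold: float = Q_THRESHOLD
    eligibility_mode: str = "union"
    fitness_threshold: float = 6.0
    revised_threshold: float = 3.5
    min_increase: float = 50.0
    generations: int = 150_000
    population_size: int = 50
    mutation_probability: float = 0.3
    runs: int = 8
    seed: int = 0
    max_solutions: int | None = None
    exclude_previous_targets: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data, base=pathlib.Path(path).parent)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any], base: pathlib.Path | None = None) -> "RunConfig":
        data = dict(data)
        if base is not None:
            for key in ("model", "expression", "de"):
                p = pathlib.Path(data[key])
                data[key] = str(p if p.is_absolute() else base / p)
        if "comparisons" in data:
            data["comparisons"] = tuple(data["comparisons"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        for key in ("model", "expression", "de"):
            if not pathlib.Path(getattr(self, key)).exists():
                raise FileNotFoundError(f"config {key} file not found: {getattr(self, key)}")
        for name in ("fitness_threshold", "revised_threshold", "fold_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def reaction_fold_changes(
    model: MetabolicModel,
    de_tables: Mapping[str, Any],
    profiles: Mapping[str, Any],
    comparisons: tuple[str, str],
    q_threshold: float = Q_THRESHOLD,
) -> dict[str, float]:
    """Reaction-level fold change per reaction: the largest q-supported
    |log2FC| across the two comparisons, expressed as 2^|log2FC|."""
    out: dict[str, float] = {}
    for rxn in model.reactions.values():
        if rxn.association is None:
            continue
        best = 0.0
        for token in comparisons:
            de = de_tables[token]
            call = reaction_differential(
                rxn.association,
                de,
                profiles[de.comparison[0]],
                profiles[de.comparison[1]],
                log2fc_threshold=0.0,
                q_threshold=q_threshold,
            )
            if call.significant:
                best = max(best, abs(call.log2fc))
        if best > 0:
            out[rxn.id] = 2.0 ** best
    return out


def _sha256(path: pathlib.Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _dump_json(obj, path: pathlib.Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig, outdir) -> pathlib.Path:
    """Run the full workflow and write all outputs (plus a manifest) to ``outdir``."""
    config.validate()
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "stages": {},
    }

    def fail(stage: str, err: Exception):
        manifest["stages"][stage] = {"status": "failed", "error": str(err)}
        _dump_json(manifest, outdir / "manifest.json")
        raise err

    # stage: load
    try:
        model = read_model_tsv(
            config.model, objective_id=config.citrate_id, biomass_id=config.tracked.get("biomass")
        )
        profiles = read_expression_tsv(config.expression)
        de_tables = read_de_tsv(config.de)
        manifest["stages"]["load"] = {"status": "ok", "n_reactions": len(model.reactions)}
    except Exception as err:  # noqa: BLE001
        fail("load", err)

    # stage: expression integration
    try:
        switched = apply_expression_switch(model, profiles[config.switch_timepoint])
        de_first = de_tables[config.comparisons[0]]
        de_second = de_tables[config.comparisons[1]]
        eligibility = eligible_reactions(
            switched, de_first, de_second, profiles,
            fold_threshold=config.fold_threshold,
            q_threshold=config.q_threshold,
            mode=config.eligibility_mode,
        )
        folds = reaction_fold_changes(
            switched, de_tables, profiles, config.comparisons, config.q_threshold
        )
        manifest["stages"]["expression"] = {
            "status": "ok",
            "eligible": dict(sorted(eligibility.items())),
        }
    except Exception as err:  # noqa: BLE001
        fail("expression", err)

    # stage: evolution
    try:
        spec = FitnessSpec(
            tracked=config.tracked,
            targets=config.targets,
            citrate_id=config.citrate_id,
            threshold=config.fitness_threshold,
        )
        refs = reference_fluxes_from_targets(switched, spec)
        params = MutationParams(
            generations=config.generations,
            fitness_threshold=config.fitness_threshold,
            population_size=config.population_size,
            mutation_probability=config.mutation_probability,
        )
        evo = FluxBoundEvolution(switched, spec, eligibility, folds, refs, params)
        results = evo.fit(
            config.seed,
            generations=config.generations,
            n_runs=config.runs,
            max_solutions=config.max_solutions,
        )
        for run_id, sols in results.runs.items():
            _dump_json(
                {"run_id": run_id, "seed": results.run_seeds[run_id],
                 "solutions": [s.to_dict() for s in sols]},
                outdir / f"solutions_run{run_id}.json",
            )
        manifest["stages"]["evolution"] = {
            "status": "ok",
            "run_seeds": results.run_seeds,
            "n_solutions": {rid: len(s) for rid, s in results.runs.items()},
        }
    except Exception as err:  # noqa: BLE001
        fail("evolution", err)

    # stage: refinement and aggregation
    try:
        refinement: RefinementResults = results.refine(
            revised_threshold=config.revised_threshold, min_increase=config.min_increase
        )
        refined_payload = {
            str(run_id): [
                {
                    "mutations": {rid: dataclasses.asdict(m) for rid, m in sol.mutations.items()},
                    "fitness": sol.fitness,
                    "ranking": sol.ranking,
                    "key_set": sol.key_set,
                    "percent_increase": {
                        k: (None if math.isnan(v) else v) for k, v in sol.percent_increase.items()
                    },
                }
                for sol in sols
            ]
            for run_id, sols in refinement.refined_by_run.items()
        }
        _dump_json(refined_payload, outdir / "refined_solutions.json")
        table = refinement.summary()
        if config.exclude_previous_targets:
            table["frequency"] = None
        table.to_csv(outdir / "targets.tsv", sep="\t", index=False)
        refinement.summary(prominent_only=True).to_csv(
            outdir / "targets_prominent.tsv", sep="\t", index=False
        )
        refinement.membership_matrix().to_csv(outdir / "membership.tsv", sep="\t")
        manifest["stages"]["refinement"] = {"status": "ok", "n_targets": len(table)}
    except Exception as err:  # noqa: BLE001
        fail("refinement", err)

    manifest["outputs"] = {
        p.name: _sha256(p) for p in sorted(outdir.glob("*")) if p.name != "manifest.json"
    }
    _dump_json(manifest, outdir / "manifest.json")
    return outdir


def run_simulation(
    model: MetabolicModel,
    exchange_map: dict[str, str],
    store_exchange: str,
    initial: CultureState,
    params: KineticParameters,
    duration: float,
    dt: float,
    constrained: bool,
    out_csv,
):
    """Convenience wrapper used by the CLI `simulate` subcommand."""
    problem = DfbaProblem(model=model, exchange_map=exchange_map, store_exchange=store_exchange)
    traj = simulate(problem, params, initial, duration, dt=dt, constrained=constrained)
    traj.to_csv(out_csv)
    return traj
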