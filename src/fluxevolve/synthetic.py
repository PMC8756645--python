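"""Synthetic toy fixtures with planted ground truth.

Builds a small, fully analysable fermentation network — glucose and xylose
feeding a triose pool that splits between biomass (phosphate-dependent),
respiration and a citrate branch — together with transcript expression and
differential-expression tables in which the regulatory events are planted.
The planted bottleneck is the citrate exporter: constraining it reproduces
the "suboptimal strain" scenario in which the maximal product flux sits well
below the stoichiometric optimum (unconstrained:constrained ratio ~2.6)
while carbon inputs and growth are unchanged.  Decoy events (a respiration
down-regulation and a futile-cycle up-regulation) are eligible for mutation
but cannot close the gap, so recovering the planted reaction is a genuine
inference task for the evolutionary algorithm.

Everything is regenerable from (spec, seed); there are no stored data files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .dfba import CultureState, DfbaProblem, KineticParameters
from .evolution import FitnessSpec
from .expression import (
    DifferentialExpression,
    ExpressionProfile,
    write_de_tsv,
    write_expression_tsv,
)
from .model import MetabolicModel, Reaction, Metabolite, parse_equation, solve_fba, write_model_tsv
from .gpr import parse_association

__all__ = [
    "ToyModelSpec",
    "GroundTruth",
    "make_toy_model",
    "make_dfba_problem",
    "make_initial_state",
    "make_expression_tables",
    "make_fitness_spec",
    "carbon_total",
    "write_fixture_directory",
]

# carbon atoms per molecule of each external pool (used by the closure check)
CARBON = {"GLC": 6, "XYL": 5, "CIT": 6, "CO2": 1}
#: mmol carbon fixed per gDW of biomass (5 triose x 3 C per unit growth)
BIOMASS_CARBON = 15.0


@dataclass
class ToyModelSpec:
    """Conditions of the synthetic study.

    Target exchange fluxes mirror the shape of the mid-fermentation state:
    glucose still consumed, external phosphate exhausted (growth fed from the
    internal store), slow growth, and a product flux constrained to ~1/2.6 of
    the stoichiometric optimum.
    """

    glucose_uptake: float = 1.0          # mmol gDW^-1 h^-1 (target flux -1.0)
    xylose_uptake: float = 0.1
    store_uptake: float = 0.01           # internal phosphate (target flux -0.01)
    growth_rate: float = 0.02            # h^-1
    constrained_citrate: float = 0.4     # the "in vivo" product flux
    n_bottlenecks: int = 1               # 1: exporter; 2: + citrate synthase
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bottlenecks not in (1, 2):
            raise ValueError("n_bottlenecks must be 1 or 2")


@dataclass
class GroundTruth:
    """What the generator planted, for oracle-style assertions."""

    planted_reactions: list[str]
    planted_bounds: dict[str, float]         # reaction -> upper bound reproducing the target
    eligible: dict[str, str]                 # reaction -> constrain/force
    unconstrained_citrate: float
    constrained_citrate: float
    targets: dict[str, float]                # fitness targets per exchange id
    tracked: dict[str, str]
    switched_off: list[str]                  # reactions silenced by the TPM cutoff

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


_REACTION_TABLE = [
    # id, name, equation, lb, ub, association
    ("EX_GLC", "Glucose exchange", "GLCe <==>", -1000, 0, ""),
    ("EX_XYL", "Xylose exchange", "XYLe <==>", -1000, 0, ""),
    ("EX_PI", "External phosphate exchange", "PIe <==>", -1000, 0, ""),
    ("EX_PIS", "Internal phosphate store exchange", "PIS <==>", -1000, 1000, ""),
    ("EX_CIT", "Citrate exchange", "CITe <==>", 0, 1000, ""),
    ("EX_CO2", "Carbon dioxide exchange", "CO2e <==>", 0, 1000, ""),
    ("EX_WST", "Overflow sink", "WSTe <==>", 0, 1000, ""),
    ("t_glc", "Glucose uptake", "GLCe -> GLC", 0, 1000, ""),
    ("t_xyl", "Xylose transporter", "XYLe -> XYL", 0, 1000, "tXYL"),
    ("glyc", "Glycolysis (lumped)", "GLC -> 2*TRI", 0, 1000, "tGLY1 OR tGLY2"),
    ("xyl_conv", "Pentose assimilation (lumped)", "3*XYL -> 5*TRI", 0, 1000, "tXCONV"),
    ("pyk", "Pyruvate kinase (lumped)", "TRI -> PYR", 0, 1000, "tPYK1 AND tPYK2"),
    ("cit_syn", "Citrate synthesis (lumped)", "2*PYR -> CIT", 0, 1000, "tCSY"),
    ("cit_exp", "Citrate exporter", "CIT -> CITe", 0, 1000, "tCEX"),
    ("resp", "Respiration (lumped)", "PYR -> 3*CO2e", 0, 1000, "tRSP"),
    ("t_pi", "Phosphate uptake", "PIe -> PI", 0, 1000, ""),
    ("t_pis", "Phosphate store shuttle", "PIS <==> PI", -1000, 1000, ""),
    ("biomass", "Biomass synthesis", "5*TRI + 0.5*PI ->", 0, 1000, ""),
    ("cycle_a", "Triose shunt A", "TRI -> DHA", 0, 1000, "tCYC"),
    ("cycle_b", "Triose shunt B", "DHA -> TRI", 0, 1000, ""),
    ("waste", "Overflow route", "TRI -> WSTe", 0, 1000, "tDEAD"),
]

#: baseline (T1) TPM per transcript
_T1_TPM = {
    "tXYL": 20.0, "tGLY1": 30.0, "tGLY2": 10.0, "tXCONV": 15.0,
    "tPYK1": 25.0, "tPYK2": 40.0, "tCSY": 50.0, "tCEX": 80.0,
    "tRSP": 60.0, "tCYC": 5.0, "tDEAD": 0.4, "tHK": 100.0,
}

# planted transcript-level DE events: comparison -> transcript -> (log2FC, q)
_DE_T1_T2 = {
    "tCEX": (-2.0, 1e-6),    # planted bottleneck: exporter down 4-fold
    "tRSP": (-2.0, 1e-4),    # decoy: respiration down (cannot lower product)
    "tXCONV": (-0.3, 0.5),   # sub-threshold
    "tGLY1": (0.5, 0.3),     # sub-threshold
}
_DE_T2_T3 = {
    "tCYC": (2.0, 1e-5),     # decoy: futile-cycle up (forcing it is neutral)
}
_BOTTLENECK2_EVENT = ("tCSY", (-2.0, 1e-6))  # second capable reaction


def make_toy_model(spec: ToyModelSpec | None = None) -> tuple[MetabolicModel, GroundTruth]:
    """Build the toy network and its ground-truth record.

    The record stores the unconstrained and planted-constrained product
    optima (both recomputed by LP, not hard-coded) and the planted eligible
    set the expression tables must reproduce.
    """
    spec = spec or ToyModelSpec()
    metabolites: dict[str, Metabolite] = {}
    reactions = []
    for rid, name, eq, lb, ub, assoc in _REACTION_TABLE:
        reactants, products, reversible = parse_equation(eq)
        for met in {*reactants, *products}:
            metabolites.setdefault(met, Metabolite(met))
        reactions.append(
            Reaction(
                id=rid, name=name, reactants=reactants, products=products,
                reversible=reversible, lower_bound=float(lb), upper_bound=float(ub),
                association=parse_association(assoc) if assoc else None,
            )
        )
    model = MetabolicModel(
        metabolites.values(), reactions, objective_id="EX_CIT", biomass_id="biomass"
    )

    tracked = {
        "internal_phosphate": "EX_PIS",
        "glucose": "EX_GLC",
        "xylose": "EX_XYL",
        "biomass": "biomass",
        "citrate": "EX_CIT",
    }
    targets = {
        "EX_GLC": -spec.glucose_uptake,
        "EX_XYL": -spec.xylose_uptake,
        "EX_PIS": -spec.store_uptake,
        "biomass": spec.growth_rate,
        "EX_CIT": spec.constrained_citrate,
    }
    fixed = {rid: (v, v) for rid, v in targets.items() if rid != "EX_CIT"}
    unconstrained = solve_fba(model, objective="EX_CIT", sense="max", extra_constraints=fixed)
    if not unconstrained.ok:
        raise RuntimeError(f"toy model reference LP {unconstrained.status}")

    planted = ["cit_exp"] if spec.n_bottlenecks == 1 else ["cit_exp", "cit_syn"]
    planted_bounds = {rid: spec.constrained_citrate for rid in planted}
    eligible = {"cit_exp": "constrain", "resp": "constrain", "cycle_a": "force"}
    if spec.n_bottlenecks == 2:
        eligible["cit_syn"] = "constrain"

    truth = GroundTruth(
        planted_reactions=planted,
        planted_bounds=planted_bounds,
        eligible=eligible,
        unconstrained_citrate=unconstrained.objective_value,
        constrained_citrate=spec.constrained_citrate,
        targets=targets,
        tracked=tracked,
        switched_off=["waste"],
    )
    return model, truth


def make_fitness_spec(truth: GroundTruth) -> FitnessSpec:
    return FitnessSpec(tracked=truth.tracked, targets=truth.targets, citrate_id="EX_CIT")


def make_expression_tables(
    spec: ToyModelSpec | None = None,
) -> tuple[dict[str, ExpressionProfile], dict[str, DifferentialExpression]]:
    """TPM profiles (T1/T2/T3) and DE tables consistent with the planted events.

    TPM trajectories follow the planted log2 fold changes exactly; the seed
    only jitters the unassociated housekeeping transcript, so the eligible
    set computed from these tables equals the planted set.
    """
    spec = spec or ToyModelSpec()
    rng = np.random.default_rng(spec.seed)
    de12 = dict(_DE_T1_T2)
    if spec.n_bottlenecks == 2:
        de12[_BOTTLENECK2_EVENT[0]] = _BOTTLENECK2_EVENT[1]
    de23 = dict(_DE_T2_T3)

    t1 = dict(_T1_TPM)
    t1["tHK"] = float(np.round(t1["tHK"] * rng.uniform(0.9, 1.1), 4))
    t2 = {t: v * 2.0 ** de12.get(t, (0.0,))[0] for t, v in t1.items()}
    t3 = {t: v * 2.0 ** de23.get(t, (0.0,))[0] for t, v in t2.items()}
    profiles = {
        "T1": ExpressionProfile("T1", t1),
        "T2": ExpressionProfile("T2", t2),
        "T3": ExpressionProfile("T3", t3),
    }
    neutral_q = 0.9
    de_tables = {
        "T1-T2": DifferentialExpression(
            ("T1", "T2"),
            {t: de12.get(t, (0.0, neutral_q)) for t in t1},
        ),
        "T2-T3": DifferentialExpression(
            ("T2", "T3"),
            {t: de23.get(t, (0.0, neutral_q)) for t in t1},
        ),
    }
    return profiles, de_tables


def make_dfba_problem(model: MetabolicModel) -> DfbaProblem:
    return DfbaProblem(
        model=model,
        exchange_map={"GLC": "EX_GLC", "XYL": "EX_XYL", "PIe": "EX_PI",
                      "CIT": "EX_CIT", "CO2": "EX_CO2"},
        store_exchange="EX_PIS",
    )


def make_initial_state(params: KineticParameters | None = None) -> CultureState:
    """Batch starting conditions for the toy fermentation (t = simulation start).

    40 mM glucose, 12 mM xylose and 4 mM phosphate at 0.5 g/L inoculum give
    the canonical phasing at desk scale: external phosphate depletes within
    ~25 h, glucose is exhausted around 110 h and bulk xylose consumption
    follows.
    """
    params = params or KineticParameters()
    return CultureState(
        t=params.start_time,
        biomass=0.5,
        concentrations={"GLC": 40.0, "XYL": 12.0, "PIe": 4.0, "CIT": 0.0, "CO2": 0.0},
        store=0.0,
    )


def carbon_total(state: CultureState) -> float:
    """Total carbon (mmol/L) across sugars, product, CO2 and biomass."""
    c = sum(CARBON[p] * state.concentrations[p] for p in CARBON)
    return c + BIOMASS_CARBON * state.biomass


def write_fixture_directory(outdir, spec: ToyModelSpec | None = None) -> None:
    """Emit model TSV, expression TSV, DE TSV and ground-truth JSON."""
    import pathlib

    spec = spec or ToyModelSpec()
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model, truth = make_toy_model(spec)
    profiles, de_tables = make_expression_tables(spec)
    write_model_tsv(model, outdir / "model.tsv")
    write_expression_tsv(profiles, outdir / "expression.tsv")
    write_de_tsv(de_tables, outdir / "differential_expression.tsv")
    truth.to_json(outdir / "ground_truth.json")
    with open(outdir / "fixture_spec.json", "w") as fh:
        json.dump(asdict(spec), fh, indent=2)
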