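"""Constraint-based metabolic model core: equation parsing, stoichiometry, FBA/FVA.

The model dialect is deliberately small: a tab-separated table with one row per
reaction (id, name, equation string, bounds, transcript association, subsystem).
Equations use the ``A + 2*B <==> C`` notation; several arrow spellings are
accepted and normalised on read.  Flux analysis is plain linear programming
(HiGHS via :func:`scipy.optimize.linprog`): maximise or minimise one reaction's
flux subject to steady state ``S v = 0`` and the bound box.

Units follow the fermentation-modelling convention: fluxes in mmol gDW^-1 h^-1,
except the biomass reaction whose flux is the specific growth rate in h^-1.
Exchange reactions (exactly one metabolite) use uptake-negative /
secretion-positive signs.
"""

from __future__ import annotations

import copy
import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .gpr import Association, parse_association

__all__ = [
    "EquationParseError",
    "ModelValidationError",
    "InfeasibleError",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "FluxState",
    "parse_equation",
    "format_equation",
    "build_stoichiometric_matrix",
    "solve_fba",
    "solve_lexicographic",
    "flux_variability",
    "apply_deletions",
    "read_model_tsv",
    "write_model_tsv",
]

#: default magnitude used for "unbounded" reaction bounds in the TSV dialect
DEFAULT_BOUND = 1000.0

FEASIBILITY_TOL = 1e-9
MASS_BALANCE_TOL = 1e-6


class EquationParseError(ValueError):
    """Raised when a reaction equation string cannot be parsed."""


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


class InfeasibleError(RuntimeError):
    """Raised when an LP required to be feasible is not."""


@dataclass
class Metabolite:
    """A chemical species.  Ids are opaque tokens; suffixes carry no semantics."""

    id: str
    name: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("metabolite id must be non-empty")


@dataclass
class Reaction:
    """A stoichiometric conversion with flux bounds and an optional transcript association."""

    id: str
    name: str = ""
    reactants: dict[str, float] = field(default_factory=dict)
    products: dict[str, float] = field(default_factory=dict)
    reversible: bool = False
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    association: Association | None = None
    subsystem: str = ""

    def validate(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id}: lower_bound {self.lower_bound} > upper_bound {self.upper_bound}"
            )
        if not self.reversible and self.lower_bound < 0:
            raise ModelValidationError(
                f"reaction {self.id}: irreversible reaction with negative lower bound"
            )
        for met, coeff in {**self.reactants, **self.products}.items():
            if coeff <= 0:
                raise ModelValidationError(
                    f"reaction {self.id}: non-positive coefficient {coeff} for {met}"
                )

    @property
    def metabolite_ids(self) -> set[str]:
        return set(self.reactants) | set(self.products)

    @property
    def is_exchange(self) -> bool:
        """Exchange = crosses the system boundary = touches exactly one metabolite."""
        return len(self.metabolite_ids) == 1

    def stoichiometry(self) -> dict[str, float]:
        """Net coefficients, products positive / reactants negative."""
        coeffs: dict[str, float] = {}
        for met, c in self.reactants.items():
            coeffs[met] = coeffs.get(met, 0.0) - c
        for met, c in self.products.items():
            coeffs[met] = coeffs.get(met, 0.0) + c
        return coeffs


class MetabolicModel:
    """An ordered collection of metabolites and reactions with named roles.

    Parameters
    ----------
    metabolites, reactions
        Model content; order is preserved and defines matrix row/column order.
    objective_id
        Reaction whose flux is maximised by default (typically the product
        exchange or the biomass reaction).
    biomass_id
        The biomass reaction; its flux is the specific growth rate (h^-1).
    """

    def __init__(
        self,
        metabolites: Iterable[Metabolite],
        reactions: Iterable[Reaction],
        objective_id: str | None = None,
        biomass_id: str | None = None,
    ) -> None:
        self.metabolites: dict[str, Metabolite] = {}
        for met in metabolites:
            if met.id in self.metabolites:
                raise ModelValidationError(f"duplicate metabolite id {met.id}")
            self.metabolites[met.id] = met
        self.reactions: dict[str, Reaction] = {}
        for rxn in reactions:
            if rxn.id in self.reactions:
                raise ModelValidationError(f"duplicate reaction id {rxn.id}")
            rxn.validate()
            for met in rxn.metabolite_ids:
                if met not in self.metabolites:
                    raise ModelValidationError(
                        f"reaction {rxn.id} references unknown metabolite {met}"
                    )
            self.reactions[rxn.id] = rxn
        self.objective_id = objective_id
        self.biomass_id = biomass_id
        for rid in (objective_id, biomass_id):
            if rid is not None and rid not in self.reactions:
                raise ModelValidationError(f"unknown reaction id {rid}")
        self._lp_cache: _LPCache | None = None

    # -- structure -------------------------------------------------------

    @property
    def reaction_ids(self) -> list[str]:
        return list(self.reactions)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.metabolites)

    @property
    def exchange_ids(self) -> list[str]:
        return [r.id for r in self.reactions.values() if r.is_exchange]

    def copy(self) -> "MetabolicModel":
        new = MetabolicModel.__new__(MetabolicModel)
        new.metabolites = {k: copy.copy(v) for k, v in self.metabolites.items()}
        new.reactions = {k: copy.deepcopy(v) for k, v in self.reactions.items()}
        new.objective_id = self.objective_id
        new.biomass_id = self.biomass_id
        new._lp_cache = None
        return new

    def bounds(self) -> dict[str, tuple[float, float]]:
        return {r.id: (r.lower_bound, r.upper_bound) for r in self.reactions.values()}

    # -- LP plumbing -----------------------------------------------------

    def _cache(self) -> "_LPCache":
        if self._lp_cache is None:
            self._lp_cache = _LPCache(self)
        return self._lp_cache

    def invalidate_cache(self) -> None:
        self._lp_cache = None


@dataclass
class FluxState:
    """The result of one FBA solve."""

    fluxes: dict[str, float]
    objective_value: float
    status: str  # "optimal" | "infeasible" | "unbounded"

    @property
    def ok(self) -> bool:
        return self.status == "optimal"

    def to_tsv(self, path, objective_id: str | None = None) -> None:
        """Write fluxes as TSV plus a JSON sidecar with objective and status."""
        df = pd.DataFrame(
            {"reaction_id": list(self.fluxes), "flux": list(self.fluxes.values())}
        )
        df.to_csv(path, sep="\t", index=False)
        sidecar = {
            "objective_id": objective_id,
            "objective_value": self.objective_value,
            "status": self.status,
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2)


# ---------------------------------------------------------------------------
# Equation parsing

_REVERSIBLE_ARROWS = ("<==>", "<->", "↔")
_IRREVERSIBLE_ARROWS = ("-->", "->", "→")
# longest-first so "<->" is not split as "<" + "->"
_ARROW_RE = re.compile("|".join(re.escape(a) for a in ("<==>", "<->", "↔", "-->", "->", "→")))


def parse_equation(text: str) -> tuple[dict[str, float], dict[str, float], bool]:
    """Parse ``A + 2*B <==> C`` into (reactants, products, reversible).

    Coefficients default to 1; ``k*MET`` sets coefficient ``k`` (> 0).  Either
    side may be empty (exchange reactions are written ``GLCe <==>``).  A
    metabolite repeated on one side has its coefficients summed.
    """
    arrows = _ARROW_RE.findall(text)
    if len(arrows) != 1:
        raise EquationParseError(
            f"equation must contain exactly one arrow token, found {len(arrows)}: {text!r}"
        )
    arrow = arrows[0]
    reversible = arrow in _REVERSIBLE_ARROWS
    left, right = _ARROW_RE.split(text)
    return _parse_side(left, text), _parse_side(right, text), reversible


def _parse_side(side: str, context: str) -> dict[str, float]:
    coeffs: dict[str, float] = {}
    side = side.strip()
    if not side:
        return coeffs
    for term in side.split("+"):
        term = term.strip()
        if not term:
            raise EquationParseError(f"empty term in equation {context!r}")
        if "*" in term:
            coeff_text, _, met = term.partition("*")
            try:
                coeff = float(coeff_text.strip())
            except ValueError:
                raise EquationParseError(
                    f"malformed coefficient {coeff_text.strip()!r} in {context!r}"
                ) from None
            met = met.strip()
        else:
            coeff, met = 1.0, term
        if coeff <= 0:
            raise EquationParseError(f"coefficient {coeff} <= 0 for {met!r} in {context!r}")
        if not met or " " in met:
            raise EquationParseError(f"malformed metabolite token {met!r} in {context!r}")
        coeffs[met] = coeffs.get(met, 0.0) + coeff
    return coeffs


def _format_coeff(c: float) -> str:
    return str(int(c)) if float(c).is_integer() else repr(c)


def format_equation(reaction: Reaction) -> str:
    """Inverse of :func:`parse_equation` (normalised arrows ``<==>`` / ``->``)."""

    def side(coeffs: Mapping[str, float]) -> str:
        return " + ".join(
            met if c == 1 else f"{_format_coeff(c)}*{met}" for met, c in coeffs.items()
        )

    arrow = "<==>" if reaction.reversible else "->"
    return f"{side(reaction.reactants)} {arrow} {side(reaction.products)}".strip()


# ---------------------------------------------------------------------------
# Stoichiometry and LP

def build_stoichiometric_matrix(model: MetabolicModel) -> np.ndarray:
    """S[i, j] = net coefficient of metabolite i in reaction j."""
    met_index = {m: i for i, m in enumerate(model.metabolite_ids)}
    S = np.zeros((len(met_index), len(model.reactions)))
    for j, rxn in enumerate(model.reactions.values()):
        for met, coeff in rxn.stoichiometry().items():
            S[met_index[met], j] += coeff
    return S


class _LPCache:
    """Prebuilt S matrix and bound arrays, reused across many solves."""

    def __init__(self, model: MetabolicModel) -> None:
        self.model = model
        self.S = build_stoichiometric_matrix(model)
        self.index = {rid: j for j, rid in enumerate(model.reaction_ids)}
        self.base_lb = np.array([r.lower_bound for r in model.reactions.values()])
        self.base_ub = np.array([r.upper_bound for r in model.reactions.values()])

    def solve(
        self,
        objective_id: str,
        sense: str = "max",
        extra_bounds: Mapping[str, tuple[float, float]] | None = None,
    ) -> FluxState:
        if objective_id not in self.index:
            raise ModelValidationError(f"unknown objective reaction {objective_id}")
        if sense not in ("max", "min"):
            raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")
        lb = self.base_lb.copy()
        ub = self.base_ub.copy()
        if extra_bounds:
            for rid, (lo, hi) in extra_bounds.items():
                j = self.index[rid]
                lb[j], ub[j] = lo, hi
        n = len(self.index)
        c = np.zeros(n)
        c[self.index[objective_id]] = -1.0 if sense == "max" else 1.0
        res = linprog(
            c,
            A_eq=self.S,
            b_eq=np.zeros(self.S.shape[0]),
            bounds=np.column_stack([lb, ub]),
            method="highs",
        )
        if res.status == 0:
            fluxes = {rid: float(res.x[j]) for rid, j in self.index.items()}
            obj = fluxes[objective_id]
            return FluxState(fluxes=fluxes, objective_value=obj, status="optimal")
        status = "infeasible" if res.status == 2 else "unbounded" if res.status == 3 else "infeasible"
        return FluxState(fluxes={}, objective_value=float("nan"), status=status)


def solve_fba(
    model: MetabolicModel,
    objective: str | None = None,
    sense: str = "max",
    extra_constraints: Mapping[str, tuple[float, float]] | None = None,
) -> FluxState:
    """Flux balance analysis: optimise one reaction's flux at steady state.

    ``extra_constraints`` override the stored bounds for this solve only.
    Infeasible or unbounded problems are reported through ``FluxState.status``,
    never as silent zeros.
    """
    objective = objective or model.objective_id
    if objective is None:
        raise ModelValidationError("no objective reaction given and model has none")
    return model._cache().solve(objective, sense=sense, extra_bounds=extra_constraints)


def solve_lexicographic(
    model: MetabolicModel,
    objectives: Sequence[tuple[str, str]],
    extra_constraints: Mapping[str, tuple[float, float]] | None = None,
    tol: float = 1e-9,
) -> FluxState:
    """Solve a sequence of objectives, fixing each optimum before the next.

    ``objectives`` is a list of (reaction_id, sense).  Used by the dynamic
    simulator for growth-then-product phasing.
    """
    bounds = dict(extra_constraints or {})
    state = FluxState(fluxes={}, objective_value=float("nan"), status="infeasible")
    for rid, sense in objectives:
        state = solve_fba(model, objective=rid, sense=sense, extra_constraints=bounds)
        if not state.ok:
            return state
        opt = state.objective_value
        # fix this objective (with a small relaxation for LP tolerance)
        if sense == "max":
            bounds[rid] = (opt - tol, opt + tol)
        else:
            bounds[rid] = (opt - tol, opt + tol)
    return state


def flux_variability(
    model: MetabolicModel,
    reaction_id: str,
    fixed: Mapping[str, tuple[float, float]] | None = None,
) -> tuple[float, float]:
    """Minimum and maximum flux of one reaction over the feasible region."""
    lo = solve_fba(model, objective=reaction_id, sense="min", extra_constraints=fixed)
    hi = solve_fba(model, objective=reaction_id, sense="max", extra_constraints=fixed)
    if not (lo.ok and hi.ok):
        raise InfeasibleError(
            f"flux variability of {reaction_id} infeasible under fixed constraints "
            f"{sorted(fixed) if fixed else []}"
        )
    return lo.objective_value, hi.objective_value


def apply_deletions(model: MetabolicModel, reaction_ids: Iterable[str]) -> MetabolicModel:
    """Return a copy with both bounds of the listed reactions set to zero."""
    new = model.copy()
    for rid in reaction_ids:
        if rid not in new.reactions:
            raise ModelValidationError(f"cannot delete unknown reaction {rid}")
        new.reactions[rid].lower_bound = 0.0
        new.reactions[rid].upper_bound = 0.0
    return new


# ---------------------------------------------------------------------------
# Tabular I/O

_TSV_COLUMNS = [
    "reaction_id",
    "name",
    "equation",
    "lower_bound",
    "upper_bound",
    "association",
    "subsystem",
]


def read_model_tsv(
    path,
    objective_id: str | None = None,
    biomass_id: str | None = None,
) -> MetabolicModel:
    """Read a model from the tab-separated dialect.

    Columns: ``reaction_id  name  equation  lower_bound  upper_bound
    association  subsystem``.  Metabolites are collected from the equations.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ModelValidationError(f"model TSV missing columns: {missing}")
    metabolites: dict[str, Metabolite] = {}
    reactions: list[Reaction] = []
    for row in df.itertuples(index=False):
        reactants, products, reversible = parse_equation(row.equation)
        for met in {*reactants, *products}:
            metabolites.setdefault(met, Metabolite(met))
        assoc = parse_association(row.association) if row.association.strip() else None
        reactions.append(
            Reaction(
                id=row.reaction_id,
                name=row.name,
                reactants=reactants,
                products=products,
                reversible=reversible,
                lower_bound=float(row.lower_bound),
                upper_bound=float(row.upper_bound),
                association=assoc,
                subsystem=row.subsystem,
            )
        )
    return MetabolicModel(
        metabolites.values(), reactions, objective_id=objective_id, biomass_id=biomass_id
    )


def write_model_tsv(model: MetabolicModel, path) -> None:
    rows = []
    for rxn in model.reactions.values():
        rows.append(
            {
                "reaction_id": rxn.id,
                "name": rxn.name,
                "equation": format_equation(rxn),
                "lower_bound": rxn.lower_bound,
                "upper_bound": rxn.upper_bound,
                "association": str(rxn.association) if rxn.association else "",
                "subsystem": rxn.subsystem,
            }
        )
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)
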