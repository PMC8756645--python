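"""Dynamic FBA for batch fermentation with sequential glucose/xylose uptake.

The simulator couples repeated FBA solves to Euler updates of the external
pools.  Substrate uptake capacities follow saturable (Michaelis–Menten style)
carriers plus passive terms; xylose transport is gated off while external
glucose is above a threshold, reproducing sequential sugar consumption.
Phosphate is handled as two pools: an external pool taken up through a
saturable carrier, and an internal store that fills while external phosphate
is available and is consumed (again saturably) once it is depleted — growth
after external-phosphate depletion is store-limited and coincides with the
onset of product formation.  Product (citrate) output can be capped at a
fixed rate from a scheduled time onward to emulate a suboptimal strain.

State variables: biomass X (g/L), external concentrations (mM), and the
internal phosphate store (mmol/gDW).  With fluxes v in mmol gDW^-1 h^-1 the
Euler update is C <- C + v*X*dt (mM) and X <- X*(1 + mu*dt).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import pandas as pd

from .model import FluxState, MetabolicModel, solve_lexicographic

__all__ = [
    "KineticParameters",
    "CultureState",
    "Trajectory",
    "uptake_bounds",
    "citrate_cap_schedule",
    "euler_step",
    "simulate",
]

PHOSPHATE_DEPLETED = 1e-6  # mM below which the external pool counts as exhausted


@dataclass
class KineticParameters:
    """Kinetic parameters of the batch fermentation model.

    Rates in mmol gDW^-1 h^-1, Michaelis constants in mM (the internal-store
    constant ``K_P`` is applied on the store scale, mmol/gDW).  Passive uptake
    terms are linear in concentration: v_G1 = g_passive_coeff * [GLC].
    """

    v_Pe_max: float = 0.15
    K_Pe: float = 0.0333
    v_P_max: float = 0.06
    K_P: float = 20.0
    g_passive_coeff: float = 0.0027
    v_G2_max: float = 0.08
    K_G2: float = 0.26
    K_i2: float = 933.0
    x_passive_coeff: float = 0.00027
    v_X2_max: float = 0.18
    K_X2: float = 3.33
    v_CIT_cap: float = 0.12
    glucose_gate: float = 5.0   # mM external glucose above which the xylose carrier is off
    cap_delay: float = 32.0     # h after start_time before the citrate cap applies
    start_time: float = 10.0    # h post-inoculation at which the simulation clock starts

    def __post_init__(self) -> None:
        for name in ("v_Pe_max", "v_P_max", "v_G2_max", "v_X2_max", "v_CIT_cap",
                     "g_passive_coeff", "x_passive_coeff"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("K_Pe", "K_P", "K_G2", "K_i2", "K_X2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CultureState:
    """Snapshot of the batch culture at time ``t`` (hours)."""

    t: float
    biomass: float                      # g/L
    concentrations: dict[str, float]    # pool label -> mM
    store: float = 0.0                  # internal phosphate, mmol/gDW

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.concentrations.items() if v < -1e-12}
        if bad:
            raise ValueError(f"negative concentrations: {bad}")

    def copy(self) -> "CultureState":
        return CultureState(self.t, self.biomass, dict(self.concentrations), self.store)


@dataclass
class Trajectory:
    """Time-ordered culture states with optional per-step flux snapshots."""

    states: list[CultureState] = field(default_factory=list)
    fluxes: list[FluxState] = field(default_factory=list)

    @property
    def final(self) -> CultureState:
        return self.states[-1]

    def to_dataframe(self) -> pd.DataFrame:
        pools = list(self.states[0].concentrations)
        rows = []
        for s in self.states:
            row = {"t_h": s.t, "biomass_gL": s.biomass}
            row.update({f"{p}_mM": s.concentrations[p] for p in pools})
            row["PI_store"] = s.store
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class DfbaProblem:
    """Binds a metabolic model to the fermentation pools it exchanges with.

    ``exchange_map`` maps pool labels {GLC, XYL, PIe, CIT, CO2, ...} to the
    model's exchange-reaction ids; ``store_exchange`` is the internal-phosphate
    exchange.  ``objectives`` is the per-step lexicographic FBA objective list;
    the default maximises growth, then product, then store deposition.
    """

    model: MetabolicModel
    exchange_map: dict[str, str]
    store_exchange: str
    objectives: Sequence[tuple[str, str]] | None = None

    def default_objectives(self) -> list[tuple[str, str]]:
        if self.objectives is not None:
            return list(self.objectives)
        objs = [(self.model.biomass_id, "max"), (self.exchange_map["CIT"], "max")]
        objs.append((self.store_exchange, "max"))
        return objs


def citrate_cap_schedule(t: float, params: KineticParameters, constrained: bool) -> float:
    """Upper bound for the citrate exchange at simulation time ``t`` (h).

    When ``constrained``, the cap ``v_CIT_cap`` applies from
    ``start_time + cap_delay`` onward; before that (and always when
    unconstrained) only model-internal limits apply.
    """
    if constrained and t >= params.start_time + params.cap_delay:
        return params.v_CIT_cap
    return math.inf


def uptake_bounds(
    state: CultureState,
    params: KineticParameters,
    problem: DfbaProblem,
    constrained: bool = False,
) -> dict[str, tuple[float, float]]:
    """Per-step exchange bounds from the culture state.

    Glucose capacity is passive + carrier (the carrier inhibited by citrate,
    1/(1+[CIT]/K_i2)); the xylose carrier is gated off above the glucose gate;
    external phosphate follows a saturable carrier; the internal store accepts
    deposits while external phosphate remains and only then becomes a
    saturable source.  Uptake bounds are negative (uptake) by convention.
    """
    conc = state.concentrations
    for label, value in conc.items():
        if value < 0:
            raise ValueError(f"negative concentration for {label}: {value}")
    glc = conc.get("GLC", 0.0)
    xyl = conc.get("XYL", 0.0)
    pie = conc.get("PIe", 0.0)
    cit = conc.get("CIT", 0.0)

    v_g1 = params.g_passive_coeff * glc
    v_g2 = params.v_G2_max * glc / (params.K_G2 + glc) / (1.0 + cit / params.K_i2)
    v_x1 = params.x_passive_coeff * xyl
    v_x2 = 0.0 if glc > params.glucose_gate else params.v_X2_max * xyl / (params.K_X2 + xyl)
    v_pe = params.v_Pe_max * pie / (params.K_Pe + pie)

    bounds: dict[str, tuple[float, float]] = {
        problem.exchange_map["GLC"]: (-(v_g1 + v_g2), 0.0),
        problem.exchange_map["XYL"]: (-(v_x1 + v_x2), 0.0),
        problem.exchange_map["PIe"]: (-v_pe, 0.0),
        problem.exchange_map["CIT"]: (0.0, citrate_cap_schedule(state.t, params, constrained)),
    }
    if pie > PHOSPHATE_DEPLETED:
        # external phosphate available: store may only fill (secretion-positive)
        bounds[problem.store_exchange] = (0.0, math.inf)
    else:
        v_p = params.v_P_max * state.store / (params.K_P + state.store)
        bounds[problem.store_exchange] = (-v_p, 0.0)
    return bounds


def _clip_to_pools(
    bounds: dict[str, tuple[float, float]],
    state: CultureState,
    problem: DfbaProblem,
    dt: float,
) -> dict[str, tuple[float, float]]:
    """Tighten uptake bounds so one Euler step cannot drive any pool negative."""
    clipped = dict(bounds)
    X = state.biomass
    if X <= 0 or dt <= 0:
        return clipped
    for label, rid in problem.exchange_map.items():
        if rid not in clipped:
            continue
        lo, hi = clipped[rid]
        pool = state.concentrations.get(label, 0.0)
        max_uptake = pool / (X * dt)  # mM / (g/L * h) = mmol gDW^-1 h^-1
        clipped[rid] = (max(lo, -max_uptake), hi)
    lo, hi = clipped[problem.store_exchange]
    clipped[problem.store_exchange] = (max(lo, -state.store / dt), hi)
    return clipped


def euler_step(
    state: CultureState,
    params: KineticParameters,
    problem: DfbaProblem,
    dt: float,
    constrained: bool = False,
) -> tuple[CultureState, FluxState]:
    """One Euler step: solve FBA under the current uptake bounds, update pools."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    bounds = _clip_to_pools(uptake_bounds(state, params, problem, constrained), state, problem, dt)
    # replace inf with the model's own stored bound for the LP
    for rid, (lo, hi) in bounds.items():
        rxn = problem.model.reactions[rid]
        bounds[rid] = (
            lo if math.isfinite(lo) else rxn.lower_bound,
            min(hi, rxn.upper_bound) if math.isfinite(hi) else rxn.upper_bound,
        )
    flux_state = solve_lexicographic(problem.model, problem.default_objectives(), bounds)
    if not flux_state.ok:
        raise RuntimeError(
            f"dFBA step infeasible at t={state.t:.3f} h (status {flux_state.status}); "
            f"state: X={state.biomass:.4f}, conc={state.concentrations}"
        )
    mu = flux_state.fluxes[problem.model.biomass_id]
    new = state.copy()
    new.t = state.t + dt
    new.biomass = state.biomass * (1.0 + mu * dt)
    for label, rid in problem.exchange_map.items():
        v = flux_state.fluxes[rid]
        c = state.concentrations[label] + v * state.biomass * dt
        new.concentrations[label] = max(c, 0.0)  # floor guards LP-tolerance dust
    new.store = max(state.store + flux_state.fluxes[problem.store_exchange] * dt, 0.0)
    return new, flux_state


def simulate(
    problem: DfbaProblem,
    params: KineticParameters,
    initial: CultureState,
    duration: float,
    dt: float = 0.01,
    constrained: bool = False,
    record_fluxes: bool = False,
) -> Trajectory:
    """Integrate the batch culture for ``duration`` hours with step ``dt``."""
    n_steps = int(round(duration / dt))
    traj = Trajectory(states=[initial.copy()])
    state = initial.copy()
    for _ in range(n_steps):
        state, flux_state = euler_step(state, params, problem, dt, constrained)
        traj.states.append(state)
        if record_fluxes:
            traj.fluxes.append(flux_state)
    return traj
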