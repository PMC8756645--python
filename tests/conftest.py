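import pytest

from fluxevolve.dfba import KineticParameters, simulate
from fluxevolve.evolution import (
    FluxBoundEvolution,
    MutationParams,
    SolutionEvaluator,
    reference_fluxes_from_targets,
)
from fluxevolve.expression import apply_expression_switch
from fluxevolve.model import (
    MetabolicModel,
    Metabolite,
    Reaction,
    parse_equation,
)
from fluxevolve.pipeline import reaction_fold_changes
from fluxevolve.synthetic import (
    ToyModelSpec,
    make_dfba_problem,
    make_expression_tables,
    make_fitness_spec,
    make_initial_state,
    make_toy_model,
)


def build_model(rows, objective_id=None, biomass_id=None):
    """Assemble a model from (id, equation, lb, ub) rows."""
    metabolites, reactions = {}, []
    for rid, eq, lb, ub in rows:
        reactants, products, reversible = parse_equation(eq)
        for met in {*reactants, *products}:
            metabolites.setdefault(met, Metabolite(met))
        reactions.append(
            Reaction(id=rid, reactants=reactants, products=products,
                     reversible=reversible, lower_bound=lb, upper_bound=ub)
        )
    return MetabolicModel(metabolites.values(), reactions,
                          objective_id=objective_id, biomass_id=biomass_id)


@pytest.fixture(scope="session")
def chain_model():
    """EX_A -> A -> B -> C -> EX_C, input capped at 10."""
    return build_model(
        [
            ("EX_A", "A <==>", -10, 0),
            ("r1", "A -> B", 0, 1000),
            ("r2", "B -> C", 0, 1000),
            ("EX_C", "C <==>", 0, 1000),
        ],
        objective_id="EX_C",
    )


@pytest.fixture(scope="session")
def branch_model():
    """Two routes A->P: yield 1.0 (r_hi) and yield 0.5 (r_lo)."""
    return build_model(
        [
            ("EX_A", "A <==>", -10, 0),
            ("r_hi", "A -> P", 0, 1000),
            ("r_lo", "2*A -> P", 0, 1000),
            ("EX_P", "P <==>", 0, 1000),
        ],
        objective_id="EX_P",
    )


@pytest.fixture(scope="session")
def toy():
    return make_toy_model(ToyModelSpec())


@pytest.fixture(scope="session")
def toy_model(toy):
    return toy[0]


@pytest.fixture(scope="session")
def truth(toy):
    return toy[1]


@pytest.fixture(scope="session")
def tables():
    return make_expression_tables(ToyModelSpec())


@pytest.fixture(scope="session")
def profiles(tables):
    return tables[0]


@pytest.fixture(scope="session")
def de_tables(tables):
    return tables[1]


@pytest.fixture(scope="session")
def switched_model(toy_model, profiles):
    return apply_expression_switch(toy_model, profiles["T2"])


@pytest.fixture(scope="session")
def fitness_spec(truth):
    return make_fitness_spec(truth)


@pytest.fixture(scope="session")
def evaluator(switched_model, fitness_spec):
    return SolutionEvaluator(switched_model, fitness_spec)


@pytest.fixture(scope="session")
def reference_fluxes(switched_model, fitness_spec):
    return reference_fluxes_from_targets(switched_model, fitness_spec)


@pytest.fixture(scope="session")
def fold_changes(switched_model, de_tables, profiles):
    return reaction_fold_changes(switched_model, de_tables, profiles, ("T1-T2", "T2-T3"))


def make_evolution(switched_model, fitness_spec, truth, fold_changes, reference_fluxes,
                   population_size=16, **kwargs):
    params = MutationParams(population_size=population_size, **kwargs)
    return FluxBoundEvolution(
        switched_model, fitness_spec, truth.eligible, fold_changes, reference_fluxes, params
    )


@pytest.fixture()
def evolution(switched_model, fitness_spec, truth, fold_changes, reference_fluxes):
    return make_evolution(switched_model, fitness_spec, truth, fold_changes, reference_fluxes)


@pytest.fixture(scope="session")
def fitted_results(toy_model, profiles, de_tables, truth):
    """One shared small fit (3 runs, 1 solution each) reused across tests."""
    switched = apply_expression_switch(toy_model, profiles["T2"])
    spec = make_fitness_spec(truth)
    refs = reference_fluxes_from_targets(switched, spec)
    folds = reaction_fold_changes(switched, de_tables, profiles, ("T1-T2", "T2-T3"))
    evo = FluxBoundEvolution(
        switched, spec, truth.eligible, folds, refs, MutationParams(population_size=16)
    )
    return evo.fit(seed=11, generations=4000, n_runs=3, max_solutions=1)


@pytest.fixture(scope="session")
def kinetics():
    return KineticParameters()


@pytest.fixture(scope="session")
def dfba_problem(toy_model):
    return make_dfba_problem(toy_model)


@pytest.fixture(scope="session")
def trajectory(dfba_problem, kinetics):
    """Unconstrained batch trajectory reused by several invariant checks."""
    initial = make_initial_state(kinetics)
    return simulate(dfba_problem, kinetics, initial, duration=60.0, dt=0.1,
                    constrained=False, record_fluxes=True)


@pytest.fixture(scope="session")
def trajectory_constrained(dfba_problem, kinetics):
    initial = make_initial_state(kinetics)
    return simulate(dfba_problem, kinetics, initial, duration=60.0, dt=0.1,
                    constrained=True, record_fluxes=True)
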