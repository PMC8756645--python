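# Methods

This note documents the models and procedures implemented in `fluxevolve`,
their assumptions, the parameters that matter, and the choices made where the
design was genuinely open.

## Constraint-based core

A model is a list of reactions with equation strings, flux bounds
(mmol gDW⁻¹ h⁻¹; the biomass reaction in h⁻¹) and optional transcript
associations. Equations accept `<==>`, `<->` and `↔` as reversible arrows and
`->`, `-->`, `→` as irreversible; coefficients are written `k*MET`; either
side may be empty, which is how single-metabolite exchange reactions
(`GLCe <==>`) are written. A reaction touching exactly one metabolite is an
exchange; uptake is negative, secretion positive.

FBA solves `max/min v_obj` subject to `S v = 0` and the bound box with
scipy's HiGHS backend. The stoichiometric matrix and bound arrays are built
once per model and reused across solves, which matters because the
evolutionary driver performs thousands of LPs. Degenerate optima are real:
alternate optimal vertices exist in any non-trivial network, and the solver's
vertex choice is backend-specific. All quantitative claims in the package
therefore rest on objective values or flux-variability envelopes, never on
individual interior fluxes. Tolerances: feasibility 1e-9, mass-balance check
1e-6 (both configurable at call sites).

Flux variability is the paired min/max LP per reaction. Deletions zero both
bounds on a copy; the input model is never modified in place.

## Expression integration

Reaction-level expression evaluates the association tree with OR → sum
(isoenzymes add capacity) and AND → min (a complex is limited by its scarcest
subunit). A transcript missing from a profile counts as 0 TPM with a logged
warning — the conservative reading, consistent with switching off unobserved
reactions. Reactions whose reaction-level TPM falls below 1 (strict `<`) have
both bounds zeroed; reactions with no association are untouched. The switch
is idempotent.

Reaction-level differential expression is the log2 ratio of reaction-level
TPM (later/earlier) with a 0.5-TPM pseudocount on both sides to avoid
division by zero; the pseudocount is configurable. Significance combines the
associated transcripts' q-values by minimum — the least surprising lift from
transcript-level calls to a reaction-level call — and requires the
reaction-level |log2FC| to clear the threshold (0.7 for reporting; fold ≥ 2,
i.e. |log2FC| ≥ 1, for mutation eligibility).

Eligibility uses the *union* of events across the two timepoint comparisons
by default (an event in either suffices); an intersection mode is available
(`mode="intersection"`). When the two comparisons disagree in direction, the
larger |log2FC| wins and an exact tie makes the reaction ineligible — a
deterministic rule for a case the data rarely produce.

## Dynamic FBA

The batch simulator advances `(X, C, store)` by explicit Euler steps: solve
an FBA under state-dependent exchange bounds, then
`C ← C + v·X·dt` (mM), `X ← X·(1 + μ·dt)`, `store ← store + v_store·dt`.

Uptake capacities per gDW:

| term | form | default |
|---|---|---|
| glucose passive | `0.0027·[GLC]` | coeff 0.0027 |
| glucose carrier | `0.08·[GLC]/(0.26+[GLC]) · 1/(1+[CIT]/933)` | v_max 0.08, K 0.26 mM, K_i 933 mM |
| xylose passive | `0.00027·[XYL]` | coeff 0.00027 |
| xylose carrier | `0.18·[XYL]/(3.33+[XYL])`, **0 while [GLC] > 5 mM** | v_max 0.18, K 3.33 mM |
| external phosphate | `0.15·[PIe]/(0.0333+[PIe])` | v_max 0.15, K 0.0333 mM |
| internal store | `0.06·s/(20+s)`, only once [PIe] < 1e-6 mM | v_max 0.06, K 20 |
| product cap | 0.12, applied from start+32 h in constrained runs | start 10 h |

The citrate-inhibition factor `1/(1+[CIT]/K_i)` is the simplest
single-constant form; it is a hook, not a claim about mechanism. The internal
phosphate store may only fill while external phosphate remains (its exchange
bound is deposition-only) and becomes a saturable source after depletion;
this reproduces the two-phase behaviour in which growth continues slowly
after external phosphate is gone and product formation begins. The store is
carried per gDW and is not diluted by growth — a deliberate simplification;
at the growth rates reached after phosphate depletion the dilution term is
second-order.

The per-step FBA objective is lexicographic: maximise growth, then product,
then store deposition. This is a modelling choice (any single objective
either starves growth or never secretes product); it is exposed as the
`objectives` list on `DfbaProblem`. Uptake bounds are additionally clipped to
`C/(X·dt)` so a step can never drive a pool negative; a floor at 0 catches
LP-tolerance dust. Default `dt` is 0.01 h; the bundled analyses use 0.05–0.1 h
with a halving check showing endpoint changes below 1%, and carbon closure on
the toy network is exact to machine precision because every carbon pool is
tracked.

Biomass death and maintenance ATP are not modelled. Concentrations are kept
in mM throughout; conversion to g/L is left to the caller with their own
molar masses.

## Evolutionary algorithm

Fitness: `F = −log10 Σ (f_t − f_a)²` over five tracked exchanges (internal
phosphate, glucose, xylose, biomass, product). The product target is the
observed constrained flux; the other targets are the reference solution's
values. `F` diverges at a perfect fit, so it is capped at 12 (any finite cap
above the capture threshold works; 12 keeps double precision meaningful).
Actual fluxes come from an LP maximising the product exchange with the other
four tracked exchanges fixed at their targets and the individual's mutated
bounds applied; an infeasible LP scores −∞. The achieved-flux vector is
stored on the individual, so the score can always be recomputed independently
from Σ(f_t−f_a)².

Mutation limits: for a reaction down-regulated by fold change `c` with
reference flux `f`, the flux may be constrained no tighter than `|f|/c`; for
an up-regulated reaction the forced minimum is `|f|·c`, clipped at the
flux-variability maximum under the base exchange constraints. Forcing is
disallowed when the variability interval straddles zero (no clear flux
direction). Where two timepoint reference fluxes are available the
larger-magnitude one feeds the constraint limit and the smaller the forcing
minimum (`assignment="larger_constrain"`); the alternative pairing
(`"t1_constrain"`) is behind the same switch. Constraining a reversible
reaction moves both bounds symmetrically toward zero.

Mutation steps: first mutation uniform over the allowed interval; subsequent
mutations add a Laplace(0, b) draw with `b = 0.01·|B|` (`0.001` at `B = 0`)
and clip to the interval. The Laplace distribution concentrates small steps
while keeping heavy tails, which is what lets bounds settle to within the
1e-3 precision the capture threshold implies.

Driver: a generational GA with population 50, tournament selection (size 2),
elitism 1, and per-individual mutation probability 0.3 per generation — all
configurable, and any reasonable scheme satisfies the procedure's
description. On capture (`F ≥ 6`), the key reaction is identified by
complementation (restore each mutated bound, largest fitness drop wins, ties
broken lexicographically), reset across the population, and blocked from
further mutation; captures therefore accumulate distinct solutions within a
run. The default budget is 150,000 generations; the bundled analyses run the
toy fixture at ≤ 5,000 generations with population 16, where captures occur
within a few hundred generations. Per-run seeds derive from the master seed
as `SeedSequence((seed, run_index))`, so an n-run experiment is reproducible
and each run is independent.

## Refinement

Pruning reverts mutations in ascending order of contribution (ties by id) and
keeps a reversion iff fitness stays ≥ 6, looping to a fixed point; removing
low-contribution mutations first maximises removals. The pruned set is not
unique under permuted order — only the threshold is guaranteed — which is
documented behaviour, not a defect. Micro-optimisation is a coordinate hill
climb (steps of 1% of |B|, at most 20 sweeps, improving moves only), so
fitness is non-decreasing by construction.

The key set walks the contribution ranking, cumulatively restoring original
bounds and recomputing a revised fitness in which the product target is the
unconstrained optimum; the walk stops at revised fitness ≥ 3.5. The percent
increase for a reaction is `100·(citrate_restored − citrate_mutated)/
citrate_mutated`, both from product-maximising LPs — the denominator is the
constrained (mutated) flux, the reading consistent with restoring *one*
reaction while retaining the rest. Aggregation counts, per reaction, the
number of runs whose key sets contain it, takes the highest percent increase
across solutions, flips the direction (constrain → up-regulate, force →
down-regulate), sorts by (frequency, percent increase) descending and applies
a 50% prominence cutoff on request. An `exclude-previous-targets` mode
reports frequencies as missing, for follow-up runs with earlier targets
blocked.

## Synthetic fixture

The toy network (21 reactions, 14 metabolites) converts glucose (→ 2 triose)
and xylose (3 → 5 triose) into biomass (5 triose + 0.5 phosphate per unit
growth), respiration (CO₂) or citrate (2 pyruvate → citrate → export). With
the study-shaped targets (glucose −1.0, xylose −0.1, store −0.01, growth
0.02) the unconstrained product optimum is 31/30 by hand computation, and the
planted exporter bound of 0.4 reproduces a 2.58× suboptimality gap —
mirroring the ~2.6× mid-fermentation scenario the method is designed for.
Expression tables plant a 4-fold exporter down-regulation (q = 1e-6) plus two
eligible decoys — a respiration down-regulation (its reference flux is zero,
so constraining it is vacuous) and a futile-cycle up-regulation (forcing it
is neutral) — and sub-threshold events that must stay ineligible. A
two-bottleneck variant adds a citrate-synthase event so multi-solution
capture can be exercised. The batch starting state (40 mM glucose, 12 mM
xylose, 4 mM phosphate, 0.5 g/L inoculum) was chosen once to give the
canonical phasing at desk scale: phosphate depletes by ~25 h, the product cap
binds from 42 h, glucose is exhausted near 110 h and bulk xylose consumption
follows.

What the fixture does *not* emulate: genome-scale redundancy (thousands of
reactions, many alternate optima), noisy expression estimates, partial
transcript–reaction annotation, and compartmentalisation. Passing tests
therefore demonstrate correctness of the machinery and recoverability of
planted signals, not performance on a genome-scale model.

## Known limitations

- The LP-backed fitness makes the EA's cost one LP per mutated individual per
  generation; genome-scale models would need warm-started solves.
- Kinetic parameters are taken as given; no fitting to time-series data is
  shipped.
- The eligible-direction conflict rule and the q-value min-combination are
  pragmatic defaults, exposed as configuration, not statistical claims.
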