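# Methods

## Scope and model classes

The package simulates growth of a microorganism described by a
constraint-based metabolic model in three reactor settings (chemostat,
batch, fed-batch), computes a protein-cost statistic for substrate
preference, and characterises flux uncertainty by sampling.  Two model
classes are handled:

* plain genome-scale models (GEMs): signed fluxes, uptake = negative
  exchange flux;
* enzyme-constrained models (ecGEMs, GECKO convention): fully irreversible
  networks in which reversible reactions are split into a forward copy and
  a `_REV` twin, and each catalysed reaction draws protein mass from a
  bounded pool pseudo-exchange.

A single accessor maps `(model, exchange id)` to `(reaction, sign)` so all
simulation code is convention-blind.  Enzyme-constraint detection handles
both encodings found in published ecGEM releases: reactions consuming the
pool metabolite directly, and draw chains in which the pool produces
per-enzyme pseudo-metabolites (coefficient = molecular weight) consumed by
catalysed reactions (coefficient = 1/k_cat); in the latter case the net
pool coefficient of a reaction is the aggregated MW/k_cat over its
enzymes.  Which encoding was found is recorded on the result.

## LP layer

FBA problems are solved with scipy's HiGHS simplex/IPM backend
(feasibility and optimality tolerances 1e-9, recorded in every solution).
HiGHS is deterministic for a fixed model, which the sampling and scenario
layers rely on.  Lexicographic (staged) optimisation fixes each stage's
objective within a relative tolerance of 1e-6 (absolute floor 1e-9)
before solving the next stage; exact re-fixing causes spurious
infeasibility from round-off.

FBA optima are generically degenerate.  As an API contract, downstream
code consumes only (a) objective values, (b) fluxes pinned by
lexicographic stages, or (c) sampling distributions — never a single
solver-arbitrary flux.

## Chemostat

At steady state the specific growth rate equals the dilution rate D, so
the biomass reaction is bounded to [D, D] and the substrate uptake is
minimised.  Reactor quantities follow from the substrate-limited balances
with negligible residual substrate:

    c_x = D · c_feed / q_s,      c_p = q_p · c_x / D.

The biomass yield in g·g⁻¹ is 1000·D/(q_s·MW) via a molar-mass registry
(glucose 180.156, ethanol 46.069, O2 31.998, CO2 44.009 g·mol⁻¹,
extensible).  The medium supplies only the feed substrate plus a minimal
inorganic keep-list (o2, h2o, h, nh4, pi, so4 by default); uptake of every
other exchanged species is closed before solving, since otherwise the LP
can import carbon that is not fed (e.g. ethanol through an assimilation
route) and reports an artificially low substrate demand.

The critical dilution rate is reported with a grid convention: the first
grid point at which ethanol secretion exceeds 1e-4 mmol·gDW⁻¹·h⁻¹ (far
above solver noise, far below physiological rates).  On a 0.02-step grid
this lands within one step above the analytic onset.  Byproducts below
1e-6 mmol·gDW⁻¹·h⁻¹ are suppressed as solver noise.  Dilution rates above
the maximum growth rate are recorded as washout entries, never silently
dropped.

## Dynamic FBA

The static-optimisation loop per step: fire due events → translate the
reactor state into bounds → maximise growth → integrate the extracellular
balances.  Bound construction:

* Michaelis-Menten: uptake ≤ q_max·c/(k_m + c).  Defaults for glucose
  q_max = 10 mmol·gDW⁻¹·h⁻¹, k_m = 0.28 mmol·l⁻¹.
* Presence-gated: uptake allowed at its cap only while the species exceeds
  1e-6 mmol·l⁻¹ (used for substrates that are "unconstrained" in ecGEMs).
* Feed phase (fed-batch): uptake ≤ F(t)·c_feed/(X·V), the quasi-steady
  balance of a limiting substrate with negligible reactor concentration.
* Regulation rules: a rule (inhibitor species, inhibited exchange,
  threshold 0.1 mmol·l⁻¹ by default) closes the inhibited uptake while the
  inhibitor is above threshold — a declarative stand-in for carbon
  catabolite repression.
* Any tracked species absent from the reactor has its uptake closed
  (gases exempt), so the LP cannot consume mass that is not there.

Integration is exact for constant specific rates: B → B·e^{μdt},
n_i → n_i + q_i·B·(e^{μdt}−1)/μ (limit q_i·B·dt as μ → 0) plus feed
additions from the closed-form volume integral of constant or exponential
feeds.  Gas species (o2, co2 by default) exchange with the headspace and
are not accumulated in the liquid.  Default dt = 0.01 h; the worked
examples and tests use 0.02–0.1 h, which changes final biomass of the toy
batch by well under 0.5% on halving.

Depletion handling: a step that would drive a species negative beyond
1e-9 is rejected; the loop first computes the exact within-step depletion
time (the balance has a closed form in dt) and lands on it, so no mass is
clamped away at phase boundaries; dt-halving remains as a fallback when a
feed supplies the crossing species.  Depletion times are recorded as phase
boundaries, and clamp events are logged.

Infeasible LPs are retried with growth forced to zero ("maintenance
mode", flagged); if still infeasible the state is frozen and flagged.
This mirrors stationary phase without inventing maintenance kinetics.

Carbon recovery is a QC statistic, not a result: per step,
(C produced − C consumed)/C consumed over biomass, tracked species (net of
feed additions) and gas flows.  Steps with negligible turnover — solver
noise of order 1e-11 after total depletion — are normalised by 1e-6 of
the system carbon inventory instead of their own near-zero consumption,
which would otherwise amplify float dust into large relative residuals.

## Protein cost

The protein cost of a substrate is the pool exchange flux required to
consume 1 mmol·gDW⁻¹·h⁻¹ of it as sole carbon source, and the relative
cost divides by the reference substrate (glucose).  "Required" is
implemented as lexicographic max-growth-then-min-pool at the fixed unit
uptake: this is the main interpretive choice of the module; it pins a
unique, reproducible value where plain FBA would be degenerate, and reads
"required" as the minimal pool consistent with optimal growth.  During the
evaluation the uptake of every other carbon exchange is closed; by
default their secretion is closed too, so an oligosaccharide's hydrolysis
products must be metabolised (an `allow_product_accumulation` flag
switches to the permissive reading where they may escape to the medium).
The biomass yield per C-mol is μ/(uptake·n_C/1000) at the same optimum.

## Flux sampling

The sampled polytope is prepared the way chemostat states are simulated:
growth fixed, substrate uptake minimised and then confined to
[v*, (1+slack)·v*] with slack 0.10.  The stated "minimal flux ± 10%" is
implemented one-sided because fluxes below the minimum are infeasible by
definition; the lower arm is vacuous.  Numerically troublesome reactions
(e.g. a reversible transaldolase, cytosolic reductions of TCA
intermediates) are blocked via configuration lists — their identities are
model-release specific and are deliberately not hardcoded.  A rescaling
pass can lift stoichiometric coefficients above solver tolerance by
changing enzyme/pool mass units; the transformation preserves the
solution set up to recorded flux scale factors on the affected exchanges.

Warmup points come from ± coordinate objectives (exchanges and pool
first, capped at 200 coordinates) plus seeded random dense objectives.
The ACHR chain moves along directions from the running centre to a
randomly chosen warmup point; directions are differences of feasible
points, so S·d = 0 holds exactly and only the bound interval along the
direction must be computed.  The centre is updated as the running mean of
all chain states; every `thinning`-th state is emitted (default 100 for
study-style runs; tests use 3–10).  All randomness flows from a single
integer seed, and reruns are byte-identical.

Validation discards samples violating bounds or |S·v| beyond 1e-6 and
reports the retention fraction.  Summaries are per-reaction median ± MAD;
when a substrate exchange is named, relative fluxes v_i/v_substrate are
summarised as well (samples with zero substrate flux are excluded and
counted).  Flux variability contracts with growth rate in the relative
(v/v_substrate) metric — the absolute widths grow because the ±10% slack
scales with v*, so the contraction statement is made, and tested, on
relative fluxes.

## Synthetic toy models

The overflow toy has one substrate (6 carbons, glucose-like), a
respiratory route (yield y_r = 0.10 gDW·mmol⁻¹, pool cost
c_r = 0.010 g·h·mmol⁻¹) and a fermentative route (y_f = 0.05,
c_f = 0.002) producing 1 ethanol (2 C) per substrate, a biomass sink, and
a pool exchange bounded at 0.02 g·gDW⁻¹·h⁻¹ with substrate uptake capped
at 10 mmol·gDW⁻¹·h⁻¹.  Defaults give the landmarks μ_crit = 0.2 h⁻¹ and
μ_max = 0.5 h⁻¹.  Validity requires y_r > y_f, c_r > c_f and
c_f/y_f < c_r/y_r (fermentation cheaper per unit growth) — without the
last condition no overflow regime exists.  Carbon closure is exact by
construction: biomass carries 40 C-mmol·gDW⁻¹ and CO2 closes every
balance (respiration is run at respiratory quotient 1), so conservation
tests must return zero residuals.  Uptake reactions carry no pool cost,
matching the convention that transporters are outside the protein pool.
An optional ethanol assimilation route (y_a = 0.025, c_a = 0.012) enables
diauxic re-consumption after substrate depletion.

The dual-substrate toy shares one biomass yield between two routes with
costs c_A < c_B; when the pool binds
(P < c_A·q_max,A + c_B·q_max,B) the growth-maximising LP fills the cheap
substrate to its cap first, so the consumption order emerges from the
protein costs alone.  Closed forms for both toys (vertex enumeration of
the 2-constraint LP, piecewise q_s(μ), chemostat balances) serve as
independent oracles; the acceptance checks compare the simulation modules
against them across random parameterisations drawn inside the validity
region.

What the toys do not emulate: genome-scale redundancy (isozymes,
compartments, transport costs), realistic yeast stoichiometry or ATP
maintenance, proton/charge balancing, and measurement noise.  Passing
tests therefore demonstrate correctness of the simulation machinery and
of the overflow/ordering mechanisms, not quantitative yeast physiology;
quantitative reproduction requires the published genome-scale model files
as inputs.

## Numerical choices

* Unbounded flux directions are capped at ±1000 mmol·gDW⁻¹·h⁻¹ (COBRA
  community convention) at load time.
* Solver tolerances 1e-9; sample validation 1e-6; ethanol onset 1e-4;
  presence threshold 1e-6 mmol·l⁻¹; depletion tolerance 1e-9 mmol.
* Knockouts match GECKO id families: a target id also zeroes its `_REV`
  twin and `No<k>` isozyme copies.
* Secretion restriction closes only secretion directions and keeps a
  configurable gas/water/proton list open; the biomass sink and pool
  exchange are never touched.
* Problem sizes in tests and the acceptance script (500–2000 samples,
  ≤ 24 chemostat grid points, 20 random draws, dt 0.02–0.1 h) were chosen
  as the smallest sizes at which the checked invariants are sharp.

## Known limitations

* The kcat-recalibration hook multiplies selected pool coefficients by
  user-supplied factors only; no recalibration recipe is bundled.
* Chemostats are single-substrate and glucose-limited (residual substrate
  assumed zero); non-substrate-limited steady states are out of scope.
* No product-toxicity growth inhibition, pH or temperature effects; gas
  transfer is represented only through event-driven uptake bounds, not a
  kLa model.
* Sampling convergence diagnostics are limited to retention and seed
  determinism by design.
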