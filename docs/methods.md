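# Methods

## The modeling formalism

`stomasim` implements multi-level logical modeling: each network
component *v* carries a discrete state variable ("level") confined to a
declared range `[min_v, max_v]` and one update rule giving its next
level as a function of its regulators' current levels. Binary nodes
(0/1) read as inactive/active; multi-level nodes express graded
activity (e.g. the membrane potential PMV spans −2…2, with 0 the
resting potential, negative values hyperpolarized, positive
depolarized). Rules combine Boolean clauses with arithmetic:

- in a *logical* context a level is true iff strictly positive, and
  threshold clauses (`node ≥ k`, `node = k`, …) make multi-level
  decisions explicit; logical results are 0/1;
- in an *arithmetic* context raw levels are used, with logical
  sub-results coerced to 0/1;
- the completed rule value is clamped **once** to the target's range;
  intermediate sub-expressions are unrestricted. This makes bounded
  accumulator rules (`PMV* = PMV − pump + …`) saturate at their floors
  and ceilings without auxiliary bookkeeping.

Operator precedence, loosest to tightest: `Or < And < + − < × < Not <
comparisons`. The parser is a hand-written recursive-descent
implementation (the grammar is ~10 productions; a parser-generator
dependency would be heavier than the parser). Rules compile to Python
closures over a positional state vector for the simulation inner loop;
an independent AST-walking evaluator defines the reference semantics
and the two are property-tested against each other.

## Time and update order

Time is discretized. One step updates every internal node exactly once,
in a freshly drawn uniform random permutation, each node seeing the
partially updated state of its predecessors in the sequence (random
order asynchronous update). This samples unknown relative reaction
speeds; ensemble averages over replicates are the model's observable
predictions, and each replicate draws its random stream from a spawned
child of the master seed, making ensembles reproducible and independent
of evaluation order. The output node (stomatal opening) is a readout,
not a participant: it always updates last. Signal nodes are prescribed
per step from the experiment configuration and never updated by rules;
schedule change points persist until the next change point. Clamped
nodes are removed from the permutation entirely rather than updated and
reset, so a clamp can never flicker within a step.

A node with `delay_steps = d` evaluates its rule against the recorded
system state `d` steps earlier; states before step 0 equal the initial
state. Sucrose carries `d = 10`, modeling the slow build-up of
photosynthetic sugar relative to ion transport. A consequence of the
lagged-lookup semantics is that sucrose-driven responses switch on
about 11–12 steps after their photosynthetic precondition, so purely
sucrose-carried conditions (red light in ambient air) have t₅₀ ≈ 12.
A synchronous (parallel) update step is provided only as a test oracle.

Defaults: 18 steps, 2000 replicates — enough for every component of the
shipped model to reach a time-invariant state (a fixed plateau, or a
sustained oscillation for the calcium module) and for ensemble means to
be reproducible across seeds to better than 0.02 opening levels
(measured over ≥5 seeds; the plateau itself is deterministic, so
residual seed-to-seed disagreement reflects only replicates still
rising at the peak step). Summary statistics of a trajectory: the
maximum over steps of the ensemble mean ("maximum steady-state level" —
the max, not the final value, so pulse protocols are covered), and
t₅₀/t₉₅, the first step at which ≥50%/≥95% of replicates attain
≥50%/≥95% of that maximum (attain-or-exceed, ties to the earliest
step). A node that never rises reports (0, 0, 0).

## The synthetic guard-cell model

The shipped fixture (44 nodes, 74 edges) is a **synthetic** network:
node identities and pathway logic follow guard-cell biology, but the
wiring and rules are this package's own compact design, sized so that
every framework feature is exercised and the established qualitative
phenomenology emerges from local rules. It is not a transcription of
any published model file, and its quantitative outputs (opening level
13.49 under dual beam, etc.) are properties of this fixture only.

Architecture:

- **Signals** (in-degree 0): blue light (0/1), red light (0/1), CO₂
  (0 free / 1 ambient / 2 elevated), ABA (0/1).
- **Photosynthetic branch**: photophosphorylation = blue + red; the
  intercellular CO₂ pool (Ci) is fed by atmospheric CO₂ and drawn down
  by mesophyll fixation (a 2-node feedback, the model's second SCC);
  guard-cell carbon fixation requires light reactions plus CO₂; sucrose
  is its 10-step-delayed readout.
- **Blue branch**: phototropins (phot1 via a 14-3-3 complex, phot2)
  activate the pump-phosphorylating kinase, boosted by
  photophosphorylation-derived ATP and requiring PP1.
- **Pump and ions**: the 14-3-3-bound H⁺-ATPase integrates
  phosphorylation, ATP and a CO₂ brake (activity `ATP × (4 − 2·CO₂)`,
  range 0–9); it acidifies the apoplast (a 0–5 proton-motive index),
  hyperpolarizes PMV, and powers K⁺ uptake through inward channels. K⁺
  content ratchets toward the acidification ceiling at up to 2
  levels/step while channels are open and decays when the ceiling
  falls; counterions (malate, Cl⁻, NO₃⁻) track K⁺, malate doubling
  under dual beam. A red-light pathway activates the pump only in
  CO₂-free air, reproducing the low-CO₂ ion uptake phenotype.
- **ABA branch** (condensed): ABA → PLD → PA inhibits PP1; ABA
  inactivates ABI1, releasing OST1 → ROS → NO → Ca²⁺ release; ABA also
  inhibits pump phosphorylation directly. Sustained high Ca²⁺ closes
  the inward K⁺ channels. Under light without ABA, cytosolic Ca²⁺
  oscillates (hyperpolarization-activated influx vs constitutive
  efflux), stochastically gating the *rate* — not the ceiling — of K⁺
  uptake, the model's sustained-oscillation component.
- **Output**: `opening = 2.5·K_c + malate_c + Cl_c + NO₃_c +
  sucrose × carbon_fixation`, a numeric readout (range 0–18.5). The
  osmotica split reported by `osmotica_composition` evaluates exactly
  these rule terms (declared in the model metadata, re-partitionable)
  at the step of peak mean opening, normalized to 100%.

Initial condition: all signals and responsive nodes off except seven
constitutively present components (the two 14-3-3 proteins, PP1, ABI1,
the Ca²⁺ efflux pumps, basal ATP, ambient Ci).

Because the ionic plateau is pump-determined and deterministic, steady
opening levels are exact rational numbers (13.5, 9, 16.5, …) and
ensemble means converge tightly; stochasticity shows up in rise timing
and in the oscillating calcium module. One edge-on-edge regulation is
included (anion channels gating the malate export edge) to exercise
that pathway of the format: it is stored faithfully and projected, for
all graph work, as an edge from the modulator to the modulated edge's
target, carrying a `modulates_edge` flag.

## What the fixture does and does not show

Passing tests demonstrate that the framework's semantics (update order,
delays, clamps, seeding), analyses and screens behave correctly on a
realistic, fully featured model, and that the qualitative biology wired
into the fixture (synergy, CO₂ monotonicity, ABA/blue crosstalk and
ABA/red independence, perturbation phenotypes) emerges from local rules
under ensemble simulation. They do not validate the fixture against
wet-bench data — quantitative levels are design artifacts of this
network — and a transcription of a literature-curated network would be
loaded through exactly the same `ModelSpec` format.

## Screens and binning

The knockout screen clamps each internal node at 0 (one at a time)
across a light × CO₂ grid, ABA absent, and reports each mutant's
maximal opening as a percentage of the same condition's wild type.
Percentages are undefined (flagged, not zeroed) where the wild type
does not open. Histogram bins follow the conventional percent-of-WT
ranges `[0,5), [5,15), …, [85,95), [95,100], (100,105]`: a knockout at
exactly 100% of wild type counts as wild-type-like (95–100% bin), and
the 100–105% bin holds strictly-supra-wild-type mutants; an explicit
overflow bin above 105% keeps the counts summing to the number of
screened nodes in all cases. Screens default to 500 replicates per
ensemble in the acceptance script: the screened quantity is a
deterministic plateau, so the knockout-vs-wild-type comparison is
insensitive to ensemble size beyond a few hundred replicates.

## Structural analysis choices

Graph metrics run on the projected directed graph (edge-on-edge
regulations as modulator→target edges); degrees use the multigraph so
parallel edges count separately; singleton SCCs are excluded from
reports. Edge-removal impact for an SCC is the number of nodes expelled
from it: SCC size minus the largest strongly connected component its
nodes form after deleting one internal edge. Simple-path counting is an
exhaustive depth-first backtracking count (no path storage), with a
configurable cap raising an explicit overflow error on pathological
inputs; it is cross-checked in tests against brute-force enumeration of
injective node sequences and against `networkx.all_simple_paths`.

## Numerical and testing choices

- Replicate streams: `SeedSequence(seed).spawn(k)`; derived scenario
  seeds are reduced below 2³¹.
- Integer-kind nodes hold exact small integers in float storage; the
  compiled and interpreted rule paths agree exactly (property-tested),
  so ensembles are bit-reproducible for a given seed.
- The permutation oracle test compares engine step-1 outcome frequencies
  with exhaustive enumeration over all update orders (chi-square,
  p > 10⁻³ at n = 6000).
- The SEM-vs-replicates check runs at a mid-rise step: at the plateau
  the across-replicate variance of this model vanishes by design, so
  the final step carries no dispersion signal.
- Test ensembles use 100–500 replicates; asserted orderings have
  margins of whole opening levels, orders of magnitude above the
  sampling noise at those sizes. Exact equality asserts are reserved
  for deterministic plateau values.

## Known limitations

- No continuous-time or ODE semantics; no attractor enumeration beyond
  fixed-point persistence; the synchronous mode exists only as a test
  oracle.
- Single-node knockouts only; no combinatorial perturbations or
  dose–response modeling.
- The delay mechanism is a lagged regulator lookup; if a counter-based
  ("cannot fire before step d") semantics is ever needed it would slot
  into the same per-node `delay_steps` field.
- The rule grammar compares nodes against constants only; comparisons
  between two nodes are expressed arithmetically (`(a − b)` in a
  logical context means a > b), which the K⁺ ratchet rule uses.
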