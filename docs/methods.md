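# Methods

## Model semantics

A logical model assigns each species `i` a level `x_i ∈ {0..max_i}` and, if
regulated, an update function given by ordered function terms over regulator
levels with a default fallback. Function terms are evaluated in document
order and the **first** true term wins. Overlapping terms (two terms true in
the same regulator context) are legal in the format but ambiguous; the
validator searches regulator contexts for overlaps (up to 4096 contexts per
transition) and emits a warning diagnostic rather than an error. Species
without a transition, and species flagged constant, keep their level — they
are the model's external inputs.

Multivalued updates default to *direct assignment*: at the next step the
species takes the term's result level outright. An optional `stepwise` mode
instead moves the level by ±1 toward the target each step, the usual
multilevel convention when a species should not jump across intermediate
thresholds. Boolean models are unaffected by the choice, and all
cross-scheme invariants asserted in the tests hold in either mode.

A species' `initialLevel` is a single integer; sets of initial values are
not supported. Simulations that need a start state use the declared levels
when complete, otherwise they require an explicit state and fail with a
clear message. The "null state" convention used for reproducing published
runs is all species at 0 with inputs clamped to the condition's values.

## SBML qual I/O

The reader and writer implement the logical-model profile of the SBML Level
3 qual package (namespace `…/level3/version1/qual/version1`) directly on
lxml: qualitative species (`maxLevel`, `initialLevel`, `constant`,
compartment), transitions with inputs (`transitionEffect="none"`), outputs
(`assignmentLevel`), ordered function terms with MathML conditions, and a
mandatory default term. Petri-net transition effects
(consumption/production) are rejected with an `unsupported-profile` error
instead of being silently misread. The MathML subset is `apply` with
and/or/xor/not and the six relational operators comparing one species
symbol with one integer constant; `xor` is normalised into and/or/not form
on input, and species-vs-species comparisons are rejected. Core SBML
reaction lists are ignored with a warning; unknown qual attributes warn by
default and are errors under `strict`. Annotation and notes elements are
carried through opaquely, so they survive a round-trip.

Output is canonical — species, transitions and attributes in fixed
(lexicographic) order, UTF-8 — so equal models serialise to byte-identical
documents, and `read(write(m)) == m` for every supported model.

BoolNet export synthesises a minterm disjunction from each species' update
table over its declared regulators; the round-trip therefore preserves
update *tables* (the semantics), not the syntactic shape of conditions.
Constant-0/1 rules export as `0`/`1`; external inputs as self-lines
(`A, A`), which the importer maps back to transition-less species.

## Dynamics

State transition graphs are built by breadth-first closure with nodes
encoded as level tuples in canonical species order; node and edge insertion
order is deterministic, so equal inputs give identical graphs and exports.
Synchronous fixed points are represented with a self-loop, asynchronous and
priority stable states with no outgoing edge; attractor detection treats
both as terminal. Full-space enumeration is capped at 2^22 states by
default (override via `max_states`) so runaway multivalued products fail
fast with the state count reached.

Within a priority scheme, classes are re-evaluated at every step: the
highest-ranked class with an unstable member fires, even if a higher class
stabilised only transiently earlier in the trajectory. Clamping replaces a
species' transition with a constant rule at the clamped level (knock-out 0,
ectopic expression `max_i`), so the species converges to and holds that
level under every scheme; a transition whose outputs are only partially
clamped is not supported (the package's transitions carry one output each).

## Analysis

`stable_states` avoids building any dynamics: species are assigned
backtracking in ascending-regulator-count order, and a partial assignment is
pruned as soon as a fully-decided species' target differs from its assigned
level. Correctness, not speed, is the contract; the suite checks equality
with brute-force enumeration up to 12 Boolean species.

Attractors are the terminal SCCs of the STG (via networkx SCC
decomposition; an independent reachability-closure oracle re-derives them in
the tests). A cyclic attractor is flagged *elementary* when every internal
edge changes exactly one species — such cycles are exactly the ones shared
between synchronous and asynchronous schemes.

The HTG groups trivial-SCC states by the set of non-trivial (or terminal)
components they can reach, then splits each group into maximal weakly
connected sets; non-trivial SCCs become transient-cycle or attractor nodes.
The grouping predicate is isolated in one function
(`_reachable_key_grouping`) so a refined irreversible-component equivalence
can be swapped in without touching the construction. Node state sets always
partition the STG's states, and terminal HTG nodes coincide with the
attractors (asserted as invariants).

Pseudo-output reduction iteratively deletes regulated species that no
transition references as a regulator. Because a removed species cannot
influence any remaining update function, attractor count and the projection
of attractor states are preserved; the suite verifies this exhaustively on
100 random models of up to 10 species.

Circuits are elementary cycles of the *functional* signed regulatory graph,
inferred by brute force over regulator contexts (positive if raising the
regulator never decreases and somewhere increases the target, negative
dually, dual if both). Dual edges expand into both signed variants for
enumeration, each tested separately. Functionality contexts are computed for
Boolean models edge by edge: the assignments of the target's other
regulators in which flipping the source changes the target with the edge's
sign. The reported context is the conjunction of per-species level
constraints on non-circuit species. When an edge's assignment set is not a
product of per-species constraints the context keeps its rectangular hull
and is flagged `exact=False`; multivalued (threshold-dependent) contexts are
out of scope.

## Stochastic semi-quantitative simulation

Each external input is sampled active with probability `p/100`
independently at every step (memoryless, no autocorrelation parameter);
regulated species follow the synchronous update of the previous state, a
choice isolated in the updater so a random-order asynchronous variant can be
slotted in. Clamps override everything; events (percentage changes, clamp,
unclamp) take effect from their step onward and never alter the trace
before it. The activity level of a species at step `t` is 100 × the mean of
its binary states over the last `n` steps (shorter prefix windows at the
start); with `n = 1` it equals 100 × the state, and with all input
percentages in {0, 100} the run reproduces the deterministic synchronous
trajectory exactly.

Defaults follow the published protocol scale: 800 steps, window 200,
dose–response sweeps of 100 simulations with the varied input's percentage
drawn uniformly on [0, 100] (percentages are real-valued). Randomness comes
from a named generator (NumPy PCG64) whose seed is recorded in the trace
metadata; identical seeds give bit-identical traces.

## Synthetic fixtures

The random-model generator draws, per regulated species, 1–k regulators
(default k = 3) and an update table, either uniform over levels or monotone
("sign-consistent": each regulator gets a sign and the table is monotone in
the signed inputs, so the inferred influence graph has no dual edges). Terms
are synthesised one-per-active-table-row with default 0 — no logic
minimisation, correctness over elegance. A fifth of the species are
transition-less inputs by default. These fixtures emulate the combinatorial
structure of curated signalling models (sparse regulation, mixed signs,
free inputs) but not their biological organisation — no pathway hierarchy,
no hub structure, no realistic input/output stratification — so passing
tests demonstrate correctness of the algorithms on the model class, not
biological validity of any particular network. Test and acceptance problem
sizes (≤ 12 Boolean species for exhaustive cross-checks, 100-model
reduction sweeps at ≤ 10 species, 100 × 800-step simulations) were chosen
so every exhaustive oracle comparison stays exact while the whole suite
runs in seconds on one CPU.

## Known limitations

- Single integer `initialLevel` only; no sets of initial values.
- Petri-net semantics, rate/timing annotations, model-checking exports and
  general variable-elimination reduction (beyond pseudo-output removal) are
  out of scope.
- Functionality contexts are Boolean-only and reported as per-species
  constraints (rectangular hull when the exact region is not a product).
- The published state counts for the EGF/TNFα signalling model require the
  externally distributed model file; the analysis pipeline for them is in
  place and runs when a copy is provided.
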