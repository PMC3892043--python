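# qualm — qualitative logical models of regulatory and signalling networks

`qualm` is a Python toolkit for Boolean and multivalued logical models of
molecular networks. It reads and writes the SBML Level 3 *qual* exchange
format (logical-model profile) and the BoolNet `targets, factors` text
format, generates the discrete dynamics of a model under synchronous,
asynchronous and priority-class updating, analyses the resulting state
transition graphs (attractors, hierarchical transition graphs, pseudo-output
reduction, regulatory circuits and their functionality contexts), and runs
semi-quantitative stochastic simulations with probabilistic inputs and
sliding-window activity levels.

## The model class

A model is a set of *qualitative species*, each holding a discrete activity
level `x_i ∈ {0, …, max_i}` (`max_i = 1` in the Boolean case), plus one
*transition* per regulated species: an ordered list of function terms —
boolean conditions over regulator levels, each carrying a result level — and
a default term used when no condition holds. The update function is

    f_i(x) = resultLevel of the first true function term, else the default,

and species without a transition are external inputs that keep their level.
Dynamics are generated by an updating scheme: synchronous (all unstable
species move together, one successor per state), asynchronous (one successor
per unstable species), or ranked priority classes (only the highest-ranked
class with an unstable member fires). Attractors are the terminal strongly
connected components of the state transition graph: stable states
(`f(x) = x`) and terminal cycles. Signed regulatory circuits govern the
long-run repertoire — positive circuits (an even number of inhibitions)
enable multi-stability, negative circuits sustained oscillations — and each
circuit is only *functional* in the state-space region where every one of
its edges actually affects its target's update function.

The stochastic simulator treats each external input as active at step *t*
with probability `p/100` and reports, per species, the *activity level*:
100 × the fraction of active steps within a sliding window of the last *n*
steps — a continuous 0–100 readout from a binary trajectory.

## Worked example

```python
from qualm import (
    toy_network, target_level, stable_states, build_stg, attractors,
    UpdateScheme, ALL, infer_regulatory_graph,
)

model = toy_network()          # Boolean A, B -> C with C = A AND NOT B
print(infer_regulatory_graph(model).edges)
print(target_level(model, "C", {"A": 1, "B": 0, "C": 0}))
print([model.state_tuple(s) for s in stable_states(model)])
stg = build_stg(model, ALL, UpdateScheme.synchronous())
print(len(stg), [a.kind for a in attractors(stg)])
```

prints

```
(('A', 'C', '+'), ('B', 'C', '-'))
1
[(0, 0, 0), (0, 1, 0), (1, 0, 1), (1, 1, 0)]
8 ['stable-state', 'stable-state', 'stable-state', 'stable-state']
```

that is: A activates and B inhibits C; with A on and B off the target level
of C is 1; the model has four stable states (one per input combination, C
following A AND NOT B); and the full synchronous state transition graph has
8 states whose attractors are exactly those four stable states.

The same surface is available from the shell:

```sh
qualm convert model.sbml --to boolnet
qualm attractors model.sbml --scheme async
qualm simulate model.sbml --input EGF=50 --steps 800 --window 200 --track Akt
```

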