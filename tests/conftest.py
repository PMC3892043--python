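"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the code paths they check: stable states
by full enumeration of the state space, attractors by a reachability-closure
definition of terminal SCCs (no networkx), and regulator signs read off the
full truth table.
"""

from __future__ import annotations

import itertools

import pytest

from qualm import (
    GeneratorParams,
    LogicalModel,
    motif_library,
    random_model,
    target_level,
    toy_network,
)


@pytest.fixture
def toy() -> LogicalModel:
    return toy_network()


@pytest.fixture
def motifs() -> dict[str, LogicalModel]:
    return motif_library()


@pytest.fixture
def random_models():
    """Factory for seeded random Boolean models."""

    def make(n: int, **kwargs) -> list[LogicalModel]:
        return [
            random_model(GeneratorParams(seed=s, **kwargs)) for s in range(n)
        ]

    return make


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def brute_force_stable_states(model: LogicalModel) -> list[dict[str, int]]:
    """Fixed points by exhaustive enumeration of the state space."""
    out = []
    for state in model.iter_states():
        if all(
            target_level(model, sid, state) == state[sid]
            for sid in model.species_by_id
        ):
            out.append(state)
    out.sort(key=model.state_tuple)
    return out


def reachability_attractors(graph) -> list[frozenset]:
    """Terminal SCCs of a digraph by transitive-closure, no SCC library.

    A node's SCC is {m : n reaches m and m reaches n}; it is terminal when
    the SCC equals the full reachable set of each member.
    """
    nodes = sorted(graph.nodes)
    succ = {n: sorted(graph.successors(n)) for n in nodes}
    reach = {}
    for n in nodes:
        seen = {n}
        stack = [n]
        while stack:
            cur = stack.pop()
            for m in succ[cur]:
                if m not in seen:
                    seen.add(m)
                    stack.append(m)
        reach[n] = seen
    out = set()
    for n in nodes:
        scc = frozenset(m for m in reach[n] if n in reach[m])
        # terminal iff nothing outside the SCC is reachable from n
        if reach[n] == set(scc):
            out.add(scc)
    return sorted(out, key=min)


def same_update_semantics(a: LogicalModel, b: LogicalModel) -> bool:
    """Equal species sets and identical target levels in every state."""
    if sorted(a.species_by_id) != sorted(b.species_by_id):
        return False
    for state in a.iter_states():
        for sid in a.species_by_id:
            if target_level(a, sid, state) != target_level(b, sid, state):
                return False
    return True


def truth_table_sign(model: LogicalModel, u: str, v: str):
    """Sign of u on v straight from the full truth table over v's regulators."""
    regs = model.regulators(v)
    if u not in regs:
        return None
    others = [r for r in regs if r != u]
    increases = decreases = False
    base = {sid: 0 for sid in model.species_by_id}
    ranges = [range(model.species_by_id[r].max_level + 1) for r in others]
    for combo in itertools.product(*ranges):
        state = dict(base)
        state.update(dict(zip(others, combo)))
        levels = []
        for lvl in range(model.species_by_id[u].max_level + 1):
            state[u] = lvl
            levels.append(target_level(model, v, state))
        for a, b in zip(levels, levels[1:]):
            if b > a:
                increases = True
            if b < a:
                decreases = True
    if increases and decreases:
        return "dual"
    if increases:
        return "+"
    if decreases:
        return "-"
    return None
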