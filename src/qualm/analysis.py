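"""Asymptotic and structural analysis of logical models.

Attractors are the terminal strongly connected components of the state
transition graph: single stable states or terminal cycles. The hierarchical
transition graph (HTG) condenses an STG into attractor components, transient
cycles (non-trivial SCCs with an exit), and irreversible components — maximal
weakly connected sets of trivial-SCC states sharing the same set of reachable
non-trivial components. Stable states can also be found directly from the
logical rules by backtracking search, without building any dynamics.

On the structural side, the signed regulatory graph supports enumeration of
elementary circuits with their signs (positive circuits enable
multi-stability, negative circuits sustained oscillations) and brute-force
computation of the state-space region — the functionality context — in which
every edge of a circuit actually affects its target's update function.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional

import networkx as nx

from .errors import QualmError, StateSpaceCapError
from .dynamics import STG, UpdateScheme, build_stg
from .model import (
    LogicalModel,
    RegulatoryGraph,
    infer_regulatory_graph,
    target_level,
)

__all__ = [
    "Attractor",
    "HTGNode",
    "HTG",
    "Circuit",
    "Context",
    "stable_states",
    "attractors",
    "build_htg",
    "reduce_outputs",
    "enumerate_circuits",
    "functionality_context",
]


# ---------------------------------------------------------------------------
# Stable states by constraint search
# ---------------------------------------------------------------------------


def stable_states(model: LogicalModel) -> list[dict[str, int]]:
    """All fixed points of the update rules, without enumerating the dynamics.

    Backtracking over species assignments: species are decided in order of
    ascending regulator count and a partial assignment is pruned as soon as
    some decided species whose regulators are all decided has target level
    different from its assigned level. Species without a transition are free
    (always stable at any level). Equals brute-force enumeration.
    """
    order = sorted(
        model.species_order, key=lambda s: (len(model.regulators(s)), s)
    )
    pos = {s: i for i, s in enumerate(order)}
    # species fully checkable once index i is assigned
    checkable_at: list[list[str]] = [[] for _ in order]
    for s in order:
        if s not in model.transition_of or model.species_by_id[s].constant:
            continue
        deps = set(model.regulators(s)) | {s}
        last = max(pos[d] for d in deps)
        checkable_at[last].append(s)

    results: list[dict[str, int]] = []
    partial: dict[str, int] = {}

    def recurse(i: int) -> None:
        if i == len(order):
            results.append(dict(partial))
            return
        sid = order[i]
        for level in range(model.species_by_id[sid].max_level + 1):
            partial[sid] = level
            ok = True
            for v in checkable_at[i]:
                if target_level(model, v, partial) != partial[v]:
                    ok = False
                    break
            if ok:
                recurse(i + 1)
        del partial[sid]

    recurse(0)
    results.sort(key=model.state_tuple)
    return results


# ---------------------------------------------------------------------------
# Attractors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Attractor:
    """A terminal SCC of the STG: one stable state or a terminal cycle."""

    kind: str  # stable-state | cyclic
    states: frozenset[tuple[int, ...]]
    elementary: Optional[bool] = None  # cyclic only: each edge updates one species

    @property
    def size(self) -> int:
        return len(self.states)


def _hamming(a: tuple[int, ...], b: tuple[int, ...]) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def attractors(stg: STG) -> list[Attractor]:
    """Terminal SCCs of the STG, classified and sorted by smallest state."""
    g = stg.graph
    out = []
    for comp in nx.strongly_connected_components(g):
        comp = frozenset(comp)
        if any(succ not in comp for node in comp for succ in g.successors(node)):
            continue
        if len(comp) == 1:
            out.append(Attractor("stable-state", comp))
        else:
            elementary = all(
                _hamming(a, b) == 1
                for a in comp
                for b in g.successors(a)
                if a != b
            )
            out.append(Attractor("cyclic", comp, elementary=elementary))
    out.sort(key=lambda a: min(a.states))
    return out


# ---------------------------------------------------------------------------
# Hierarchical transition graph
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HTGNode:
    cls: str  # irreversible | transient-cycle | attractor
    states: frozenset[tuple[int, ...]]

    @property
    def size(self) -> int:
        return len(self.states)

    def label(self) -> str:
        prefix = {"irreversible": "i", "transient-cycle": "ct", "attractor": "ca"}[self.cls]
        return f"{prefix}#{self.size}"


class HTG:
    """Condensed view of an STG: nodes are classified sets of states."""

    def __init__(self, stg: STG, nodes: list[HTGNode], graph: nx.DiGraph):
        self.stg = stg
        self.nodes = nodes
        self.graph = graph  # over node indices into `nodes`

    def __len__(self):
        return len(self.nodes)

    def attractor_nodes(self) -> list[HTGNode]:
        return [n for n in self.nodes if n.cls == "attractor"]

    def to_dot(self) -> str:
        lines = ["digraph HTG {"]
        for i, node in enumerate(self.nodes):
            lines.append(f'  n{i} [label="{node.label()}"];')
        for a, b in sorted(self.graph.edges):
            lines.append(f"  n{a} -> n{b};")
        lines.append("}")
        return "\n".join(lines) + "\n"


def _reachable_key_grouping(
    cond: nx.DiGraph, member: dict, trivial: set, special_of: dict
) -> dict:
    """Grouping predicate for irreversible components.

    Key of a trivial state = the set of non-trivial (or terminal) components
    reachable from it. Isolated here so an alternative equivalence can be
    swapped in without touching the HTG construction.
    """
    reach: dict[int, frozenset] = {}
    for cnode in reversed(list(nx.topological_sort(cond))):
        acc = set()
        for succ in cond.successors(cnode):
            acc |= reach[succ]
        if cnode in special_of:
            acc.add(special_of[cnode])
        reach[cnode] = frozenset(acc)
    return {node: reach[member[node]] for node in trivial}


def build_htg(stg: STG) -> HTG:
    """Hierarchical transition graph of a finite STG.

    Non-trivial SCCs become transient-cycle or attractor nodes; terminal
    trivial states are stable-state attractor nodes; the remaining trivial
    states are grouped into maximal weakly connected sets whose members reach
    the identical set of non-trivial/terminal components. Node state sets
    partition the STG's states.
    """
    g = stg.graph
    sccs = list(nx.strongly_connected_components(g))
    special_of: dict[int, int] = {}  # condensation node -> index into special list
    specials: list[HTGNode] = []
    trivial: set = set()

    cond = nx.condensation(g, scc=sccs)
    member = cond.graph["mapping"]
    for ci, comp in enumerate(sccs):
        comp_set = frozenset(comp)
        node = next(iter(comp_set))
        nontrivial = len(comp_set) > 1 or g.has_edge(node, node)
        terminal = cond.out_degree(ci) == 0
        if nontrivial:
            cls = "attractor" if terminal else "transient-cycle"
            special_of[ci] = len(specials)
            specials.append(HTGNode(cls, comp_set))
        elif terminal:
            special_of[ci] = len(specials)
            specials.append(HTGNode("attractor", comp_set))
        else:
            trivial |= comp_set

    keys = _reachable_key_grouping(cond, member, trivial, special_of)
    # split each key-group into weakly connected subgroups
    groups: list[frozenset] = []
    by_key: dict[frozenset, set] = {}
    for node, key in keys.items():
        by_key.setdefault(key, set()).add(node)
    for key in sorted(by_key, key=lambda k: sorted(k)):
        members = by_key[key]
        sub = g.subgraph(members).to_undirected()
        for comp in nx.connected_components(sub):
            groups.append(frozenset(comp))

    nodes = specials + [HTGNode("irreversible", grp) for grp in groups]
    order = sorted(range(len(nodes)), key=lambda i: min(nodes[i].states))
    nodes = [nodes[i] for i in order]
    node_of_state = {}
    for i, n in enumerate(nodes):
        for st in n.states:
            node_of_state[st] = i
    htg_graph = nx.DiGraph()
    htg_graph.add_nodes_from(range(len(nodes)))
    for a, b in g.edges:
        na, nb = node_of_state[a], node_of_state[b]
        if na != nb:
            htg_graph.add_edge(na, nb)
    return HTG(stg, nodes, htg_graph)


# ---------------------------------------------------------------------------
# Pseudo-output reduction
# ---------------------------------------------------------------------------


def reduce_outputs(model: LogicalModel) -> tuple[LogicalModel, list[str]]:
    """Iteratively remove (pseudo-)output species.

    A pseudo-output is a regulated species that no transition (including its
    own) references as a regulator; removing it cannot change the update of
    any remaining species. Removal is iterated to a fixed point. Attractor
    count and the projection of attractor states are preserved.
    """
    from .model import expression_species

    current = model
    removed: list[str] = []
    while True:
        referenced: set[str] = set()
        for tr in current.transitions:
            referenced.update(tr.input_ids)
            for term in tr.function_terms:
                if term.condition is not None:
                    referenced |= expression_species(term.condition)
        sinks = sorted(
            sid
            for sid in current.transition_of
            if sid not in referenced and not current.species_by_id[sid].constant
        )
        if not sinks:
            break
        removed.extend(sinks)
        gone = set(sinks)
        species = tuple(s for s in current.species if s.id not in gone)
        transitions = tuple(
            tr
            for tr in current.transitions
            if not any(out.species in gone for out in tr.outputs)
        )
        current = LogicalModel(species, transitions, name=current.name)
    current.annotations = getattr(model, "annotations", {})
    return current, removed


# ---------------------------------------------------------------------------
# Circuits and functionality
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Circuit:
    """Elementary cycle of the signed regulatory graph."""

    species: tuple[str, ...]  # in cycle order, starting at the smallest id
    edge_signs: tuple[str, ...]  # sign of species[i] -> species[i+1 mod n]

    @property
    def sign(self) -> str:
        return "-" if sum(1 for s in self.edge_signs if s == "-") % 2 else "+"

    def edges(self) -> list[tuple[str, str, str]]:
        n = len(self.species)
        return [
            (self.species[i], self.species[(i + 1) % n], self.edge_signs[i])
            for i in range(n)
        ]


def enumerate_circuits(
    graph: RegulatoryGraph,
    max_len: Optional[int] = None,
    cap: int = 10000,
) -> list[Circuit]:
    """All elementary cycles with signs, in deterministic order.

    Dual edges expand into a positive and a negative signed variant, each
    yielding its own circuit instance.
    """
    g = nx.DiGraph()
    g.add_nodes_from(graph.vertices)
    sign_of: dict[tuple[str, str], str] = {}
    for u, v, s in graph.edges:
        g.add_edge(u, v)
        sign_of[(u, v)] = s
    out: list[Circuit] = []
    for cycle in nx.simple_cycles(g, length_bound=max_len):
        # rotate so the smallest id comes first
        k = cycle.index(min(cycle))
        cycle = cycle[k:] + cycle[:k]
        n = len(cycle)
        raw = [sign_of[(cycle[i], cycle[(i + 1) % n])] for i in range(n)]
        choices = [("+", "-") if s == "dual" else (s,) for s in raw]
        for combo in itertools.product(*choices):
            out.append(Circuit(tuple(cycle), combo))
            if len(out) > cap:
                raise StateSpaceCapError(len(out), cap, what="circuits")
    out.sort(key=lambda c: (len(c.species), c.species, c.edge_signs))
    return out


@dataclass(frozen=True)
class Context:
    """State-space region in which a circuit is functional.

    `constraints` maps non-circuit species to their allowed levels; species
    not listed are unconstrained. `empty` marks a never-functional circuit.
    When the underlying edge-functionality sets are not a product of
    per-species constraints, `exact` is False and `constraints` is their
    rectangular hull.
    """

    constraints: tuple[tuple[str, frozenset[int]], ...] = ()
    empty: bool = False
    exact: bool = True

    def as_dict(self) -> dict[str, frozenset[int]]:
        return dict(self.constraints)

    def admits(self, state) -> bool:
        if self.empty:
            return False
        return all(state[s] in allowed for s, allowed in self.constraints)


def _edge_functionality(
    model: LogicalModel, u: str, v: str, sign: str, cap: int
) -> list[dict[str, int]]:
    """Contexts of v's other regulators where flipping u moves v with `sign`."""
    regs = model.regulators(v)
    if u not in regs:
        raise QualmError(f"{u!r} is not a regulator of {v!r}")
    others = [r for r in regs if r != u]
    n = 1
    for r in others:
        n *= model.species_by_id[r].max_level + 1
    if n > cap:
        raise StateSpaceCapError(n, cap, what="regulator contexts")
    base = {sid: 0 for sid in model.species_by_id}
    good = []
    ranges = [range(model.species_by_id[r].max_level + 1) for r in others]
    for combo in itertools.product(*ranges):
        ctx = dict(zip(others, combo))
        state = dict(base)
        state.update(ctx)
        state[u] = 0
        lo = target_level(model, v, state)
        state[u] = 1
        hi = target_level(model, v, state)
        delta = hi - lo
        if (sign == "+" and delta > 0) or (sign == "-" and delta < 0):
            good.append(ctx)
    return good


def functionality_context(
    model: LogicalModel,
    circuit: Circuit,
    cap: int = 1 << 16,
) -> Context:
    """Region of state space where every edge of a Boolean circuit is functional.

    Per edge u->v, brute force over the joint levels of v's regulators other
    than u finds where flipping u changes v's target with the edge's sign; the
    context is the conjunction of the resulting constraints on the involved
    non-circuit species. An empty context means the circuit is never
    functional.
    """
    if not model.is_boolean:
        raise QualmError("functionality contexts are computed for Boolean models only")
    in_circuit = set(circuit.species)
    merged: dict[str, set[int]] = {}
    exact = True
    for u, v, sign in circuit.edges():
        good = _edge_functionality(model, u, v, sign, cap)
        if not good:
            return Context(empty=True)
        others = sorted(good[0].keys())
        ext = [w for w in others if w not in in_circuit]
        # per-species projections and a rectangularity check
        proj = {w: sorted({g[w] for g in good}) for w in others}
        expected = 1
        for w in others:
            expected *= len(proj[w])
        if len(good) != expected:
            exact = False
        for w in ext:
            allowed = set(proj[w])
            full = set(range(model.species_by_id[w].max_level + 1))
            if allowed == full:
                continue
            if w in merged:
                merged[w] &= allowed
                if not merged[w]:
                    return Context(empty=True)
            else:
                merged[w] = allowed
    constraints = tuple(
        (w, frozenset(vals)) for w, vals in sorted(merged.items())
    )
    return Context(constraints=constraints, exact=exact)
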