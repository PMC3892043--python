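"""Deterministic discrete dynamics and state-transition graphs.

Three updating schemes are supported. Under the synchronous scheme every
unstable species moves at once, giving each state exactly one successor
(fixed points carry a self-loop). Under the asynchronous scheme each unstable
species yields its own successor, modelling unknown, distinct delays; fixed
points have no outgoing edge. Priority schemes rank an ordered partition of
the species: only the highest-ranked class containing an unstable species
fires, synchronously or asynchronously according to its tag.

Multivalued species either jump directly to their target level or, in
``stepwise`` mode, move one level toward it per update — the usual multilevel
convention. Boolean models behave identically in both modes.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence, Union

import networkx as nx

from .errors import QualmError, StateSpaceCapError
from .model import (
    FunctionTerm,
    LogicalModel,
    State,
    Transition,
    TransitionOutput,
    target_level,
)

ALL = "ALL"
DEFAULT_STATE_CAP = 1 << 22

__all__ = [
    "ALL",
    "PriorityClass",
    "UpdateScheme",
    "STG",
    "next_level",
    "successor_sync",
    "successors_async",
    "successors_priority",
    "successors",
    "build_stg",
    "clamp",
]


@dataclass(frozen=True)
class PriorityClass:
    species: tuple[str, ...]
    mode: str = "asynchronous"  # synchronous | asynchronous

    def __post_init__(self):
        if self.mode not in ("synchronous", "asynchronous"):
            raise ValueError(f"bad priority class mode {self.mode!r}")


@dataclass(frozen=True)
class UpdateScheme:
    """Updating policy: synchronous, asynchronous, or ranked priority classes."""

    kind: str  # synchronous | asynchronous | priority
    classes: tuple[PriorityClass, ...] = ()

    @staticmethod
    def synchronous() -> "UpdateScheme":
        return UpdateScheme("synchronous")

    @staticmethod
    def asynchronous() -> "UpdateScheme":
        return UpdateScheme("asynchronous")

    @staticmethod
    def priority(classes: Sequence[PriorityClass]) -> "UpdateScheme":
        if not classes:
            raise ValueError("priority scheme needs at least one class")
        return UpdateScheme("priority", tuple(classes))

    def validate_for(self, model: LogicalModel) -> None:
        if self.kind != "priority":
            return
        updatable = {
            s for s in model.transition_of if not model.species_by_id[s].constant
        }
        covered: set[str] = set()
        for cls in self.classes:
            for sid in cls.species:
                if sid in covered:
                    raise QualmError(f"species {sid!r} appears in two priority classes")
                covered.add(sid)
        missing = updatable - covered
        if missing:
            raise QualmError(
                f"priority classes do not cover species {sorted(missing)}"
            )


def next_level(model: LogicalModel, species: str, state: State, stepwise: bool = False) -> int:
    """Level the species takes at the next update step."""
    cur = state[species]
    tgt = target_level(model, species, state)
    if stepwise and tgt != cur:
        return cur + (1 if tgt > cur else -1)
    return tgt


def unstable_species(model: LogicalModel, state: State) -> list[str]:
    """Species whose target differs from their current level, canonical order."""
    return [
        sid
        for sid in model.species_order
        if target_level(model, sid, state) != state[sid]
    ]


def successor_sync(
    model: LogicalModel, state: State, stepwise: bool = False
) -> dict[str, int]:
    """Unique synchronous successor; equals the state iff it is a fixed point."""
    return {
        sid: next_level(model, sid, state, stepwise=stepwise)
        for sid in model.species_by_id
    }


def successors_async(
    model: LogicalModel, state: State, stepwise: bool = False
) -> list[dict[str, int]]:
    """One successor per unstable species (empty iff the state is stable)."""
    out = []
    for sid in unstable_species(model, state):
        succ = dict(state)
        succ[sid] = next_level(model, sid, state, stepwise=stepwise)
        out.append(succ)
    return out


def successors_priority(
    model: LogicalModel,
    state: State,
    scheme: UpdateScheme,
    stepwise: bool = False,
) -> list[dict[str, int]]:
    """Successors under a priority scheme.

    The highest-ranked class containing an unstable species fires; within it,
    the class tag decides between one synchronous successor (all unstable
    members move) or one successor per unstable member.
    """
    scheme.validate_for(model)
    unstable = set(unstable_species(model, state))
    for cls in scheme.classes:
        members = [s for s in sorted(cls.species) if s in unstable]
        if not members:
            continue
        if cls.mode == "synchronous":
            succ = dict(state)
            for sid in members:
                succ[sid] = next_level(model, sid, state, stepwise=stepwise)
            return [succ]
        out = []
        for sid in members:
            succ = dict(state)
            succ[sid] = next_level(model, sid, state, stepwise=stepwise)
            out.append(succ)
        return out
    return []


def successors(
    model: LogicalModel,
    state: State,
    scheme: UpdateScheme,
    stepwise: bool = False,
) -> list[dict[str, int]]:
    """Successor states under any scheme (sync fixed points excluded their self-loop)."""
    if scheme.kind == "synchronous":
        succ = successor_sync(model, state, stepwise=stepwise)
        return [succ]
    if scheme.kind == "asynchronous":
        return successors_async(model, state, stepwise=stepwise)
    if scheme.kind == "priority":
        return successors_priority(model, state, scheme, stepwise=stepwise)
    raise ValueError(f"unknown scheme kind {scheme.kind!r}")


# ---------------------------------------------------------------------------
# State transition graphs
# ---------------------------------------------------------------------------


class STG:
    """State-transition graph: nodes are level tuples in canonical species order.

    Synchronous fixed points carry a self-loop; asynchronous/priority stable
    states have no outgoing edge. Attractor detection treats both as terminal.
    """

    def __init__(
        self,
        model: LogicalModel,
        scheme: UpdateScheme,
        graph: nx.DiGraph,
        initial: tuple[tuple[int, ...], ...],
        reachable_only: bool,
    ):
        self.model = model
        self.scheme = scheme
        self.graph = graph
        self.initial = initial
        self.reachable_only = reachable_only
        self.species_order = model.species_order

    def __len__(self):
        return self.graph.number_of_nodes()

    def label(self, node: tuple[int, ...]) -> str:
        sep = "" if all(s.max_level <= 9 for s in self.model.species) else "-"
        return sep.join(str(v) for v in node)

    def state_dict(self, node: tuple[int, ...]) -> dict[str, int]:
        return dict(zip(self.species_order, node))

    def to_dot(self) -> str:
        lines = ["digraph STG {"]
        for node in sorted(self.graph.nodes):
            lines.append(f'  "{self.label(node)}";')
        for a, b in sorted(self.graph.edges):
            lines.append(f'  "{self.label(a)}" -> "{self.label(b)}";')
        lines.append("}")
        return "\n".join(lines) + "\n"

    def to_graphml(self) -> bytes:
        import io

        relabelled = nx.relabel_nodes(self.graph, {n: self.label(n) for n in self.graph})
        buf = io.BytesIO()
        nx.write_graphml(relabelled, buf)
        return buf.getvalue()


def build_stg(
    model: LogicalModel,
    initial: Union[str, Iterable[State]] = ALL,
    scheme: Optional[UpdateScheme] = None,
    max_states: int = DEFAULT_STATE_CAP,
    stepwise: bool = False,
) -> STG:
    """Breadth-first closure of successors from the initial states.

    `initial` is either the sentinel ALL (enumerate the whole state space,
    subject to `max_states`) or an iterable of states. Node and edge insertion
    order is deterministic, so equal inputs give identical graphs.
    """
    scheme = scheme or UpdateScheme.asynchronous()
    scheme.validate_for(model)
    g = nx.DiGraph()
    if isinstance(initial, str) and initial == ALL:
        total = model.state_count()
        if total > max_states:
            raise StateSpaceCapError(total, max_states)
        seeds = [model.state_tuple(s) for s in model.iter_states()]
        reachable_only = False
    else:
        seeds = sorted({model.state_tuple(s) for s in initial})
        reachable_only = True
    frontier = deque(seeds)
    g.add_nodes_from(seeds)
    while frontier:
        node = frontier.popleft()
        state = dict(zip(model.species_order, node))
        for succ in successors(model, state, scheme, stepwise=stepwise):
            snode = model.state_tuple(succ)
            if snode not in g:
                if g.number_of_nodes() >= max_states:
                    raise StateSpaceCapError(g.number_of_nodes() + 1, max_states)
                g.add_node(snode)
                frontier.append(snode)
            g.add_edge(node, snode)
    return STG(model, scheme, g, tuple(seeds), reachable_only)


# ---------------------------------------------------------------------------
# Perturbations
# ---------------------------------------------------------------------------


def clamp(model: LogicalModel, assignments: Mapping[str, int]) -> LogicalModel:
    """Model with each given species forced to a fixed level.

    Knock-out is a clamp at 0, ectopic expression a clamp at the species'
    maximum level. The species' transition is replaced by a constant rule
    (default term at the clamped level), so the species converges to and then
    holds that level under every scheme.
    """
    for sid, level in assignments.items():
        sp = model.species_by_id.get(sid)
        if sp is None:
            raise QualmError(f"cannot clamp unknown species {sid!r}")
        if not (0 <= level <= sp.max_level):
            raise QualmError(
                f"clamp level {level} outside [0, {sp.max_level}] for {sid!r}"
            )
    species = tuple(
        replace(sp, constant=False, initial_level=assignments[sp.id])
        if sp.id in assignments
        else sp
        for sp in model.species
    )
    transitions = [
        tr
        for tr in model.transitions
        if not any(out.species in assignments for out in tr.outputs)
    ]
    for sid in sorted(assignments):
        transitions.append(
            Transition(
                id=f"tr_{sid}_clamped",
                inputs=(),
                outputs=(TransitionOutput(species=sid),),
                function_terms=(),
                default_term=FunctionTerm(result_level=assignments[sid]),
            )
        )
    clamped = LogicalModel(species, transitions, name=model.name)
    clamped.annotations = getattr(model, "annotations", {})
    return clamped
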