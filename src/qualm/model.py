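"""Core representation of qualitative logical models.

A logical model is a set of *qualitative species*, each taking a discrete
activity level in ``0..max_level`` (0/1 in the Boolean case), plus one
*transition* per regulated species. A transition carries an ordered list of
function terms — boolean conditions over regulator levels, each with a result
level — and a default term that applies when no condition holds. Species
without a transition (external inputs) keep their level.

States are plain mappings ``species id -> level``; whenever a deterministic
order over species is needed (hashing, serialisation, vector encodings) the
canonical order is lexicographic by species id.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Optional, Sequence

from .errors import EvaluationError, StateSpaceCapError

State = Mapping[str, int]

__all__ = [
    "State",
    "LogicExpression",
    "TrueExpr",
    "FalseExpr",
    "Cmp",
    "Not",
    "And",
    "Or",
    "TRUE",
    "FALSE",
    "QualitativeSpecies",
    "FunctionTerm",
    "TransitionInput",
    "TransitionOutput",
    "Transition",
    "LogicalModel",
    "RegulatoryGraph",
    "Diagnostic",
    "evaluate_expression",
    "expression_species",
    "target_level",
    "infer_regulatory_graph",
    "validate_model",
]


# ---------------------------------------------------------------------------
# Logic expressions
# ---------------------------------------------------------------------------

CMP_OPS = ("eq", "neq", "lt", "leq", "gt", "geq")


@dataclass(frozen=True)
class LogicExpression:
    """Abstract base for condition syntax trees."""


@dataclass(frozen=True)
class TrueExpr(LogicExpression):
    pass


@dataclass(frozen=True)
class FalseExpr(LogicExpression):
    pass


TRUE = TrueExpr()
FALSE = FalseExpr()


@dataclass(frozen=True)
class Cmp(LogicExpression):
    """Comparison of one species' level against an integer constant."""

    op: str
    species: str
    const: int

    def __post_init__(self):
        if self.op not in CMP_OPS:
            raise ValueError(f"unknown comparison operator {self.op!r}")


@dataclass(frozen=True)
class Not(LogicExpression):
    child: LogicExpression


@dataclass(frozen=True)
class And(LogicExpression):
    children: tuple[LogicExpression, ...]

    def __post_init__(self):
        if len(self.children) < 2:
            raise ValueError("AND requires at least two children")


@dataclass(frozen=True)
class Or(LogicExpression):
    children: tuple[LogicExpression, ...]

    def __post_init__(self):
        if len(self.children) < 2:
            raise ValueError("OR requires at least two children")


def evaluate_expression(expr: LogicExpression, state: State) -> bool:
    """Evaluate a condition over a full state; standard boolean semantics."""
    if isinstance(expr, TrueExpr):
        return True
    if isinstance(expr, FalseExpr):
        return False
    if isinstance(expr, Cmp):
        if expr.species not in state:
            raise EvaluationError(expr.species)
        level = state[expr.species]
        c = expr.const
        return {
            "eq": level == c,
            "neq": level != c,
            "lt": level < c,
            "leq": level <= c,
            "gt": level > c,
            "geq": level >= c,
        }[expr.op]
    if isinstance(expr, Not):
        return not evaluate_expression(expr.child, state)
    if isinstance(expr, And):
        return all(evaluate_expression(c, state) for c in expr.children)
    if isinstance(expr, Or):
        return any(evaluate_expression(c, state) for c in expr.children)
    raise TypeError(f"not a LogicExpression: {expr!r}")


def expression_species(expr: LogicExpression) -> frozenset[str]:
    """All species ids referenced anywhere in the expression."""
    if isinstance(expr, Cmp):
        return frozenset((expr.species,))
    if isinstance(expr, Not):
        return expression_species(expr.child)
    if isinstance(expr, (And, Or)):
        return frozenset().union(*(expression_species(c) for c in expr.children))
    return frozenset()


# ---------------------------------------------------------------------------
# Model elements
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QualitativeSpecies:
    """A network component with discrete activity levels 0..max_level."""

    id: str
    max_level: int = 1
    initial_level: Optional[int] = None
    name: Optional[str] = None
    compartment: str = "default"
    constant: bool = False


@dataclass(frozen=True)
class FunctionTerm:
    """A result level guarded by a condition (condition None = default term)."""

    result_level: int
    condition: Optional[LogicExpression] = None


@dataclass(frozen=True)
class TransitionInput:
    """Declared regulator of a transition; its level is never modified."""

    species: str
    sign: Optional[str] = None  # positive | negative | dual | unknown
    threshold_level: Optional[int] = None


@dataclass(frozen=True)
class TransitionOutput:
    """Species whose level the transition assigns."""

    species: str


@dataclass(frozen=True)
class Transition:
    """The logical rule for one (or more) output species.

    Function terms are evaluated in document order; the first true term
    dictates the result level, the default term applies when none holds.
    """

    id: str
    inputs: tuple[TransitionInput, ...]
    outputs: tuple[TransitionOutput, ...]
    function_terms: tuple[FunctionTerm, ...]
    default_term: FunctionTerm

    @property
    def input_ids(self) -> tuple[str, ...]:
        return tuple(i.species for i in self.inputs)

    @property
    def output_ids(self) -> tuple[str, ...]:
        return tuple(o.species for o in self.outputs)


class LogicalModel:
    """Species plus transitions; the complete definition of a network.

    Each species is the output of at most one transition; a species with no
    transition is treated as constant at its current level.
    """

    def __init__(
        self,
        species: Iterable[QualitativeSpecies],
        transitions: Iterable[Transition] = (),
        name: Optional[str] = None,
    ):
        self.species = tuple(species)
        self.transitions = tuple(transitions)
        self.name = name
        self.species_by_id: dict[str, QualitativeSpecies] = {
            s.id: s for s in self.species
        }
        self.transition_of: dict[str, Transition] = {}
        for tr in self.transitions:
            for out in tr.outputs:
                # validate_model reports duplicates; keep the first here
                self.transition_of.setdefault(out.species, tr)

    # -- canonical order and state helpers ---------------------------------

    @property
    def species_order(self) -> tuple[str, ...]:
        """Species ids in canonical (lexicographic) order."""
        return tuple(sorted(self.species_by_id))

    @property
    def is_boolean(self) -> bool:
        return all(s.max_level == 1 for s in self.species)

    def input_species(self) -> tuple[str, ...]:
        """Species with no transition (external inputs / constants)."""
        return tuple(
            sid for sid in self.species_order if sid not in self.transition_of
        )

    def regulators(self, species: str) -> tuple[str, ...]:
        """Declared regulators of a species, canonical order ('' if input)."""
        tr = self.transition_of.get(species)
        if tr is None:
            return ()
        return tuple(sorted(set(tr.input_ids)))

    def state_tuple(self, state: State) -> tuple[int, ...]:
        return tuple(state[sid] for sid in self.species_order)

    def state_dict(self, levels: Sequence[int]) -> dict[str, int]:
        return dict(zip(self.species_order, levels))

    def iter_states(self, cap: Optional[int] = None) -> Iterator[dict[str, int]]:
        """Enumerate the full state space in canonical order."""
        order = self.species_order
        ranges = [range(self.species_by_id[s].max_level + 1) for s in order]
        n = 1
        for r in ranges:
            n *= len(r)
        if cap is not None and n > cap:
            raise StateSpaceCapError(n, cap)
        for combo in itertools.product(*ranges):
            yield dict(zip(order, combo))

    def state_count(self) -> int:
        n = 1
        for s in self.species:
            n *= s.max_level + 1
        return n

    def zero_state(self) -> dict[str, int]:
        return {sid: 0 for sid in self.species_by_id}

    def initial_state(self) -> dict[str, int]:
        """State from declared initial levels; all must be present."""
        missing = [s.id for s in self.species if s.initial_level is None]
        if missing:
            raise ValueError(
                "no initialLevel declared for species "
                f"{sorted(missing)}; supply an explicit initial state"
            )
        return {s.id: int(s.initial_level) for s in self.species}

    # -- equality used by round-trip tests ----------------------------------

    def __eq__(self, other) -> bool:  # structural, order-insensitive
        if not isinstance(other, LogicalModel):
            return NotImplemented
        if sorted(self.species, key=lambda s: s.id) != sorted(
            other.species, key=lambda s: s.id
        ):
            return False
        key = lambda tr: tr.id
        return sorted(self.transitions, key=key) == sorted(other.transitions, key=key)

    def __hash__(self):
        return hash((self.species, self.transitions))

    def __repr__(self):
        return (
            f"<LogicalModel {self.name or ''} "
            f"{len(self.species)} species, {len(self.transitions)} transitions>"
        )


# ---------------------------------------------------------------------------
# Semantics
# ---------------------------------------------------------------------------


def target_level(model: LogicalModel, species: str, state: State) -> int:
    """Level the update rule assigns to `species` in `state`.

    Constant species and species without a transition return their current
    level. Otherwise function terms are evaluated in document order and the
    first true term's result level is returned, falling back to the default
    term.
    """
    sp = model.species_by_id.get(species)
    if sp is None:
        raise EvaluationError(species)
    tr = model.transition_of.get(species)
    if tr is None or sp.constant:
        return state[species]
    for term in tr.function_terms:
        if evaluate_expression(term.condition, state):
            return term.result_level
    return tr.default_term.result_level


# ---------------------------------------------------------------------------
# Regulatory graph inference
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegulatoryGraph:
    """Signed influence graph: edge (u, v, sign) iff u functionally regulates v."""

    vertices: tuple[str, ...]
    edges: tuple[tuple[str, str, str], ...]  # (source, target, '+'|'-'|'dual')

    def sign(self, u: str, v: str) -> Optional[str]:
        for a, b, s in self.edges:
            if a == u and b == v:
                return s
        return None

    def successors(self, u: str) -> tuple[str, ...]:
        return tuple(b for a, b, _ in self.edges if a == u)

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.vertices)
        for u, v, s in self.edges:
            g.add_edge(u, v, sign=s)
        return g


DEFAULT_CONTEXT_CAP = 1 << 16


def _regulator_contexts(
    model: LogicalModel, regulators: Sequence[str], cap: int
) -> Iterator[dict[str, int]]:
    ranges = [range(model.species_by_id[r].max_level + 1) for r in regulators]
    n = 1
    for r in ranges:
        n *= len(r)
    if n > cap:
        raise StateSpaceCapError(n, cap, what="regulator contexts")
    for combo in itertools.product(*ranges):
        yield dict(zip(regulators, combo))


def _edge_sign(
    model: LogicalModel, u: str, v: str, cap: int = DEFAULT_CONTEXT_CAP
) -> Optional[str]:
    """Functional sign of u on v by brute force over regulator contexts."""
    regs = model.regulators(v)
    if u not in regs:
        return None
    others = [r for r in regs if r != u]
    u_max = model.species_by_id[u].max_level
    increases = decreases = False
    base = {sid: 0 for sid in model.species_by_id}  # non-regulators are irrelevant
    for ctx in _regulator_contexts(model, others, cap):
        state = dict(base)
        state.update(ctx)
        prev = None
        for lvl in range(u_max + 1):
            state[u] = lvl
            t = target_level(model, v, state)
            if prev is not None:
                if t > prev:
                    increases = True
                elif t < prev:
                    decreases = True
            prev = t
    if increases and decreases:
        return "dual"
    if increases:
        return "+"
    if decreases:
        return "-"
    return None


def infer_regulatory_graph(
    model: LogicalModel, max_contexts: int = DEFAULT_CONTEXT_CAP
) -> RegulatoryGraph:
    """Signed influence graph over observed (functional) regulators.

    For each transition output v and declared regulator u, all joint levels of
    v's other regulators are enumerated; u -> v is positive if raising u never
    decreases and somewhere increases the target of v, negative dually, dual
    if both effects occur, and absent if u never affects v.
    """
    edges = []
    for v in model.species_order:
        for u in model.regulators(v):
            s = _edge_sign(model, u, v, cap=max_contexts)
            if s is not None:
                edges.append((u, v, s))
    edges.sort()
    return RegulatoryGraph(vertices=model.species_order, edges=tuple(edges))


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Diagnostic:
    code: str
    location: str
    message: str
    severity: str = "error"  # error | warning


def _check_expression(
    model: LogicalModel, expr: LogicExpression, loc: str, diags: list[Diagnostic]
) -> None:
    if isinstance(expr, Cmp):
        sp = model.species_by_id.get(expr.species)
        if sp is None:
            diags.append(
                Diagnostic(
                    "dangling-ref", loc, f"condition references unknown species {expr.species!r}"
                )
            )
        elif not (0 <= expr.const <= sp.max_level):
            diags.append(
                Diagnostic(
                    "const-out-of-range",
                    loc,
                    f"constant {expr.const} outside [0, {sp.max_level}] for {expr.species!r}",
                )
            )
    elif isinstance(expr, Not):
        _check_expression(model, expr.child, loc, diags)
    elif isinstance(expr, (And, Or)):
        for c in expr.children:
            _check_expression(model, c, loc, diags)


def validate_model(
    model: LogicalModel, overlap_cap: int = 1 << 12
) -> list[Diagnostic]:
    """All invariant violations as (code, location, message) diagnostics.

    An empty list means the model is valid. Overlapping function terms (two
    terms true in the same regulator context) are legal but ambiguous and
    reported as warnings; overlap detection enumerates regulator contexts and
    is skipped above `overlap_cap` contexts.
    """
    diags: list[Diagnostic] = []

    seen: set[str] = set()
    for sp in model.species:
        loc = f"species[{sp.id}]"
        if sp.id in seen:
            diags.append(Diagnostic("duplicate-id", loc, "duplicate species id"))
        seen.add(sp.id)
        if sp.max_level < 0:
            diags.append(Diagnostic("bad-max-level", loc, "maxLevel must be >= 0"))
        if sp.initial_level is not None and not (0 <= sp.initial_level <= sp.max_level):
            diags.append(
                Diagnostic(
                    "bad-initial-level",
                    loc,
                    f"initialLevel {sp.initial_level} outside [0, {sp.max_level}]",
                )
            )

    outputs_seen: dict[str, str] = {}
    for tr in model.transitions:
        loc = f"transition[{tr.id}]"
        if tr.default_term is None:
            diags.append(Diagnostic("missing-default", loc, "no default term"))
            continue
        if tr.default_term.condition is not None:
            diags.append(
                Diagnostic("bad-default", loc, "default term must not carry a condition")
            )
        if not tr.outputs:
            diags.append(Diagnostic("no-output", loc, "transition has no output"))
        declared = set(tr.input_ids)
        for inp in tr.inputs:
            if inp.species not in model.species_by_id:
                diags.append(
                    Diagnostic("dangling-ref", loc, f"unknown input species {inp.species!r}")
                )
        for out in tr.outputs:
            sp = model.species_by_id.get(out.species)
            if sp is None:
                diags.append(
                    Diagnostic("dangling-ref", loc, f"unknown output species {out.species!r}")
                )
                continue
            if sp.constant:
                diags.append(
                    Diagnostic(
                        "constant-output",
                        loc,
                        f"constant species {sp.id!r} is a transition output",
                    )
                )
            if out.species in outputs_seen:
                diags.append(
                    Diagnostic(
                        "multiple-transitions",
                        loc,
                        f"species {out.species!r} already output of "
                        f"transition {outputs_seen[out.species]!r}",
                    )
                )
            outputs_seen.setdefault(out.species, tr.id)
            for term in tr.function_terms + (tr.default_term,):
                if term.result_level > sp.max_level or term.result_level < 0:
                    diags.append(
                        Diagnostic(
                            "result-out-of-range",
                            loc,
                            f"resultLevel {term.result_level} outside "
                            f"[0, {sp.max_level}] of output {sp.id!r}",
                        )
                    )
        for i, term in enumerate(tr.function_terms):
            tloc = f"{loc}.functionTerm[{i}]"
            if term.condition is None:
                diags.append(Diagnostic("missing-condition", tloc, "function term has no condition"))
                continue
            _check_expression(model, term.condition, tloc, diags)
            extra = expression_species(term.condition) - declared
            if extra:
                diags.append(
                    Diagnostic(
                        "undeclared-input",
                        tloc,
                        f"condition references species not listed as inputs: {sorted(extra)}",
                    )
                )

        # overlapping-term ambiguity (warning): brute force when cheap
        if len(tr.function_terms) >= 2 and not any(d.severity == "error" and d.location.startswith(loc) for d in diags):
            regs = sorted(
                set().union(
                    *(expression_species(t.condition) for t in tr.function_terms if t.condition)
                )
            )
            if regs and all(r in model.species_by_id for r in regs):
                n_ctx = 1
                for r in regs:
                    n_ctx *= model.species_by_id[r].max_level + 1
                if n_ctx <= overlap_cap:
                    base = {sid: 0 for sid in model.species_by_id}
                    for ctx in _regulator_contexts(model, regs, overlap_cap):
                        st = dict(base)
                        st.update(ctx)
                        true_terms = [
                            i
                            for i, t in enumerate(tr.function_terms)
                            if t.condition is not None and evaluate_expression(t.condition, st)
                        ]
                        if len(true_terms) > 1:
                            diags.append(
                                Diagnostic(
                                    "overlapping-terms",
                                    loc,
                                    f"function terms {true_terms} are simultaneously true "
                                    f"in context {ctx}; first in document order wins",
                                    severity="warning",
                                )
                            )
                            break

    return diags


def is_valid(model: LogicalModel) -> bool:
    return not any(d.severity == "error" for d in validate_model(model))
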