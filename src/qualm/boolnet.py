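"""BoolNet-style text format and truth-table export.

The BoolNet format is one ``target, factors`` line per species, with logical
functions written using ``&``, ``|``, ``!`` and the constants ``0``/``1``.
External inputs are written as self-lines (``A, A``). Export synthesises a
minterm disjunction from the species' update table over its declared
regulators, so a round-trip preserves the update table (not the syntactic
shape of the original conditions).
"""

from __future__ import annotations

import itertools
import re
from typing import Iterator

import pandas as pd

from .errors import ParseError, QualmError
from .model import (
    And,
    Cmp,
    FALSE,
    FunctionTerm,
    LogicalModel,
    LogicExpression,
    Not,
    Or,
    QualitativeSpecies,
    TRUE,
    Transition,
    TransitionInput,
    TransitionOutput,
    target_level,
)

DEFAULT_CONTEXT_CAP = 1 << 16

__all__ = ["export_boolnet", "import_boolnet", "export_truth_tables", "truth_table"]


def _contexts(model: LogicalModel, regulators) -> Iterator[dict[str, int]]:
    ranges = [range(model.species_by_id[r].max_level + 1) for r in regulators]
    for combo in itertools.product(*ranges):
        yield dict(zip(regulators, combo))


def truth_table(model: LogicalModel, species: str, cap: int = DEFAULT_CONTEXT_CAP) -> pd.DataFrame:
    """Update table of one species over its declared regulators.

    Columns are the regulators (canonical order) plus the species itself
    (the assigned target level); rows enumerate regulator contexts in
    canonical order.
    """
    regs = model.regulators(species)
    n = 1
    for r in regs:
        n *= model.species_by_id[r].max_level + 1
    if n > cap:
        from .errors import StateSpaceCapError

        raise StateSpaceCapError(n, cap, what="regulator contexts")
    base = {sid: 0 for sid in model.species_by_id}
    rows = []
    for ctx in _contexts(model, regs):
        state = dict(base)
        state.update(ctx)
        rows.append([ctx[r] for r in regs] + [target_level(model, species, state)])
    return pd.DataFrame(rows, columns=list(regs) + [species])


def export_truth_tables(
    model: LogicalModel, cap: int = DEFAULT_CONTEXT_CAP
) -> tuple[dict[str, pd.DataFrame], list[str]]:
    """One truth table per regulated species; constants are omitted with a note."""
    tables: dict[str, pd.DataFrame] = {}
    notes: list[str] = []
    for sid in model.species_order:
        sp = model.species_by_id[sid]
        if sid not in model.transition_of or sp.constant:
            notes.append(f"{sid}: constant species, no truth table")
            continue
        tables[sid] = truth_table(model, sid, cap=cap)
    return tables, notes


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def _minterm(regs, row) -> str:
    lits = [r if v else f"!{r}" for r, v in zip(regs, row)]
    return " & ".join(lits)


def export_boolnet(model: LogicalModel) -> str:
    """Serialise a Boolean model as BoolNet ``targets, factors`` text."""
    if not model.is_boolean:
        raise QualmError("BoolNet export requires a Boolean model (all maxLevel 1)")
    lines = ["targets, factors"]
    for sid in model.species_order:
        sp = model.species_by_id[sid]
        if sid not in model.transition_of or sp.constant:
            lines.append(f"{sid}, {sid}")
            continue
        table = truth_table(model, sid)
        regs = list(table.columns[:-1])
        true_rows = table[table[sid] == 1]
        if len(true_rows) == 0:
            expr = "0"
        elif len(true_rows) == len(table):
            expr = "1"
        else:
            minterms = [_minterm(regs, row[:-1]) for row in true_rows.itertuples(index=False)]
            if len(minterms) == 1:
                expr = minterms[0]
            else:
                expr = " | ".join(f"({m})" if " & " in m else m for m in minterms)
        lines.append(f"{sid}, {expr}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Import
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*([A-Za-z_][A-Za-z0-9_.]*|[01]|[()!&|])")


def _tokenize(text: str, lineno: int) -> list[str]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip():
                raise ParseError(
                    "boolnet-syntax", f"unexpected character {text[pos]!r}", f"line {lineno}"
                )
            break
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, tokens: list[str], lineno: int):
        self.tokens = tokens
        self.pos = 0
        self.lineno = lineno

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def fail(self, msg: str):
        raise ParseError("boolnet-syntax", msg, f"line {self.lineno}")

    def parse(self) -> LogicExpression:
        expr = self.disjunction()
        if self.peek() is not None:
            self.fail(f"trailing tokens starting at {self.peek()!r}")
        return expr

    def disjunction(self) -> LogicExpression:
        parts = [self.conjunction()]
        while self.peek() == "|":
            self.take()
            parts.append(self.conjunction())
        return parts[0] if len(parts) == 1 else Or(tuple(parts))

    def conjunction(self) -> LogicExpression:
        parts = [self.atom()]
        while self.peek() == "&":
            self.take()
            parts.append(self.atom())
        return parts[0] if len(parts) == 1 else And(tuple(parts))

    def atom(self) -> LogicExpression:
        tok = self.take()
        if tok is None:
            self.fail("unexpected end of expression")
        if tok == "!":
            return Not(self.atom())
        if tok == "(":
            inner = self.disjunction()
            if self.take() != ")":
                self.fail("missing closing parenthesis")
            return inner
        if tok == "0":
            return FALSE
        if tok == "1":
            return TRUE
        if re.fullmatch(r"[A-Za-z_][A-Za-z0-9_.]*", tok):
            return Cmp("eq", tok, 1)
        self.fail(f"unexpected token {tok!r}")


def import_boolnet(text: str) -> LogicalModel:
    """Parse BoolNet ``targets, factors`` text into a Boolean LogicalModel.

    A self-line (``A, A``) declares an external input without a transition;
    every other line becomes a transition with a single function term
    (condition true -> level 1) and default 0.
    """
    rules: dict[str, tuple[LogicExpression, int]] = {}
    inputs: set[str] = set()
    mentioned: set[str] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if lineno == 1 or line.lower().replace(" ", "") == "targets,factors":
            if line.lower().replace(" ", "") == "targets,factors":
                continue
        if "," not in line:
            raise ParseError("boolnet-syntax", "expected 'target, factors'", f"line {lineno}")
        target, factors = line.split(",", 1)
        target = target.strip()
        if not re.fullmatch(r"[A-Za-z_][A-Za-z0-9_.]*", target):
            raise ParseError("boolnet-syntax", f"bad target name {target!r}", f"line {lineno}")
        if target in rules or target in inputs:
            raise ParseError("boolnet-syntax", f"duplicate target {target!r}", f"line {lineno}")
        if factors.strip() == target:
            inputs.add(target)
            mentioned.add(target)
            continue
        expr = _Parser(_tokenize(factors, lineno), lineno).parse()
        rules[target] = (expr, lineno)
        mentioned.add(target)
        from .model import expression_species

        mentioned |= expression_species(expr)

    species = [QualitativeSpecies(id=sid) for sid in sorted(mentioned)]
    transitions = []
    for target in sorted(rules):
        expr, lineno = rules[target]
        from .model import expression_species

        regs = sorted(expression_species(expr))
        terms: tuple[FunctionTerm, ...]
        if expr == TRUE:
            terms = (FunctionTerm(result_level=1, condition=TRUE),)
        elif expr == FALSE:
            terms = ()
        else:
            terms = (FunctionTerm(result_level=1, condition=expr),)
        transitions.append(
            Transition(
                id=f"tr_{target}",
                inputs=tuple(TransitionInput(species=r) for r in regs),
                outputs=(TransitionOutput(species=target),),
                function_terms=terms,
                default_term=FunctionTerm(result_level=0),
            )
        )
    return LogicalModel(species, transitions)
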