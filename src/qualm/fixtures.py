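"""Built-in toy models and a seeded random-model generator.

The toy network is the classic three-component example: Boolean species A, B
and C, where C is activated by A and inhibited by B (C becomes 1 exactly when
A = 1 and B = 0, default 0) and A, B are external inputs without transitions.
The motif library adds the analytic two-species feedback loops (a positive
loop for multi-stability, a negative loop for sustained oscillation), linear
cascades, and a gated loop whose circuit functionality depends on an external
inhibitor.

The random generator draws, per regulated species, a regulator set and an
update table (uniform, or monotone with per-regulator signs) and synthesises
one function term per table row with a non-zero result; the same seed always
yields the same model.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .errors import QualmError
from .model import (
    And,
    Cmp,
    FunctionTerm,
    LogicalModel,
    LogicExpression,
    Not,
    QualitativeSpecies,
    TRUE,
    Transition,
    TransitionInput,
    TransitionOutput,
)

__all__ = [
    "toy_network",
    "motif_library",
    "chain",
    "GeneratorParams",
    "random_model",
]


def _bool_species(*ids: str) -> list[QualitativeSpecies]:
    return [QualitativeSpecies(id=i, max_level=1) for i in ids]


def _term(cond: LogicExpression, level: int = 1) -> FunctionTerm:
    return FunctionTerm(result_level=level, condition=cond)


def _transition(target: str, regulators: list[str], terms, default: int = 0) -> Transition:
    return Transition(
        id=f"tr_{target}",
        inputs=tuple(TransitionInput(species=r) for r in sorted(set(regulators))),
        outputs=(TransitionOutput(species=target),),
        function_terms=tuple(terms),
        default_term=FunctionTerm(result_level=default),
    )


def toy_network() -> LogicalModel:
    """Three Boolean species; C = A AND NOT B, A and B are free inputs."""
    species = _bool_species("A", "B", "C")
    tr = _transition(
        "C",
        ["A", "B"],
        [_term(And((Cmp("eq", "A", 1), Cmp("eq", "B", 0))))],
    )
    return LogicalModel(species, [tr], name="toy_AB_C")


def positive_2loop() -> LogicalModel:
    """X <- Y, Y <- X: a positive circuit with two stable states."""
    species = _bool_species("X", "Y")
    return LogicalModel(
        species,
        [
            _transition("X", ["Y"], [_term(Cmp("eq", "Y", 1))]),
            _transition("Y", ["X"], [_term(Cmp("eq", "X", 1))]),
        ],
        name="positive_2loop",
    )


def negative_2loop() -> LogicalModel:
    """X <- NOT Y, Y <- X: a negative circuit sustaining a 4-state oscillation."""
    species = _bool_species("X", "Y")
    return LogicalModel(
        species,
        [
            _transition("X", ["Y"], [_term(Cmp("eq", "Y", 0))]),
            _transition("Y", ["X"], [_term(Cmp("eq", "X", 1))]),
        ],
        name="negative_2loop",
    )


def chain(k: int) -> LogicalModel:
    """Linear activation cascade S1 -> S2 -> ... -> Sk; S1 is a free input."""
    if k < 1:
        raise QualmError("chain length must be >= 1")
    ids = [f"S{i}" for i in range(1, k + 1)]
    species = _bool_species(*ids)
    transitions = [
        _transition(ids[i], [ids[i - 1]], [_term(Cmp("eq", ids[i - 1], 1))])
        for i in range(1, k)
    ]
    return LogicalModel(species, transitions, name=f"chain_{k}")


def gated_loop() -> LogicalModel:
    """X <- (Y AND NOT Z), Y <- X, input Z gates the positive X-Y circuit."""
    species = _bool_species("X", "Y", "Z")
    return LogicalModel(
        species,
        [
            _transition(
                "X", ["Y", "Z"], [_term(And((Cmp("eq", "Y", 1), Cmp("eq", "Z", 0))))]
            ),
            _transition("Y", ["X"], [_term(Cmp("eq", "X", 1))]),
        ],
        name="gated_loop",
    )


def motif_library() -> dict[str, LogicalModel]:
    """The analytic motifs used throughout the test suite."""
    return {
        "positive_2loop": positive_2loop(),
        "negative_2loop": negative_2loop(),
        "chain3": chain(3),
        "gated_loop": gated_loop(),
    }


# ---------------------------------------------------------------------------
# Random models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the seeded random-model generator."""

    n_species: int = 6
    max_level: int = 1
    max_regulators: int = 3
    function_sampler: str = "uniform"  # uniform | monotone
    input_fraction: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_species < 1:
            raise QualmError("need at least one species")
        if self.max_level < 1:
            raise QualmError("max_level must be >= 1")
        if not (0 <= self.input_fraction < 1):
            raise QualmError("input_fraction must lie in [0, 1)")
        if self.max_regulators < 1 or self.max_regulators > self.n_species - 1:
            if not (self.max_regulators >= 1 and self.n_species == 1):
                raise QualmError(
                    "max_regulators must lie in [1, n_species - 1]"
                )
        if self.function_sampler not in ("uniform", "monotone"):
            raise QualmError(f"unknown function sampler {self.function_sampler!r}")


def _minterm_condition(regs: list[str], levels: tuple[int, ...]) -> LogicExpression:
    cmps: list[LogicExpression] = [
        Cmp("eq", r, lvl) for r, lvl in zip(regs, levels)
    ]
    if len(cmps) == 1:
        return cmps[0]
    return And(tuple(cmps))


def _table_to_terms(
    regs: list[str], ranges: list[int], table: dict[tuple[int, ...], int]
) -> list[FunctionTerm]:
    """One function term per context with a non-zero result; default 0."""
    terms = []
    for ctx in itertools.product(*(range(r + 1) for r in ranges)):
        lvl = table[ctx]
        if lvl > 0:
            terms.append(FunctionTerm(result_level=lvl, condition=_minterm_condition(regs, ctx)))
    return terms


def random_model(params: GeneratorParams) -> LogicalModel:
    """Seeded random logical model satisfying every core invariant.

    A fraction of the species become transition-less inputs; each remaining
    species receives 1..max_regulators regulators and an update table drawn
    by the chosen sampler. The `monotone` sampler assigns each regulator a
    sign and draws a table that is non-decreasing in activators and
    non-increasing in inhibitors, so the inferred influence graph carries no
    dual edges.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    ids = [f"g{i:02d}" for i in range(params.n_species)]
    n_inputs = int(round(params.input_fraction * params.n_species))
    n_inputs = min(n_inputs, params.n_species - 1) if params.n_species > 1 else 0
    input_ids = set(rng.choice(ids, size=n_inputs, replace=False)) if n_inputs else set()

    species = [QualitativeSpecies(id=i, max_level=params.max_level) for i in ids]
    transitions = []
    for sid in ids:
        if sid in input_ids:
            continue
        pool = [x for x in ids if x != sid]
        k = int(rng.integers(1, min(params.max_regulators, len(pool)) + 1)) if pool else 0
        if k == 0:
            continue
        regs = sorted(rng.choice(pool, size=k, replace=False).tolist())
        ranges = [params.max_level] * len(regs)
        contexts = list(itertools.product(*(range(r + 1) for r in ranges)))
        if params.function_sampler == "uniform":
            values = rng.integers(0, params.max_level + 1, size=len(contexts))
            table = dict(zip(contexts, (int(v) for v in values)))
        else:
            table = _monotone_table(rng, regs, ranges, contexts, params.max_level)
        if all(v == 0 for v in table.values()):
            # force at least one active context so the species is not trivially dead
            ctx = contexts[int(rng.integers(0, len(contexts)))]
            table[ctx] = int(rng.integers(1, params.max_level + 1))
        terms = _table_to_terms(regs, ranges, table)
        transitions.append(_transition(sid, regs, terms))
    return LogicalModel(species, transitions, name=f"random_{params.seed}")


def _monotone_table(rng, regs, ranges, contexts, max_level) -> dict:
    """Sign-consistent table: non-decreasing in activators after sign-flips."""
    signs = rng.integers(0, 2, size=len(regs))  # 1 = activator, 0 = inhibitor
    # draw a random table, then monotonize by taking the max over the
    # sign-adjusted lower cone of each context (preserves monotonicity)
    raw = {ctx: int(v) for ctx, v in zip(contexts, rng.integers(0, max_level + 1, size=len(contexts)))}

    def oriented(ctx):
        return tuple(c if s else r - c for c, s, r in zip(ctx, signs, ranges))

    table = {}
    for ctx in contexts:
        o = oriented(ctx)
        dominated = [
            c for c in contexts if all(a <= b for a, b in zip(oriented(c), o))
        ]
        table[ctx] = max(raw[c] for c in dominated)
    return table
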