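"""Exception hierarchy shared across the package."""

from __future__ import annotations


class QualmError(Exception):
    """Base class for all errors raised by qualm."""


class EvaluationError(QualmError):
    """A logic expression referenced a species absent from the state."""

    def __init__(self, species: str):
        self.species = species
        super().__init__(f"unresolved species reference: {species!r}")


class ValidationError(QualmError):
    """An operation refused an invalid model; carries the diagnostics."""

    def __init__(self, diagnostics):
        self.diagnostics = list(diagnostics)
        lines = "; ".join(f"[{d.code}] {d.location}: {d.message}" for d in self.diagnostics)
        super().__init__(f"invalid model: {lines}")


class StateSpaceCapError(QualmError):
    """An enumeration exceeded its configured cap."""

    def __init__(self, reached: int, cap: int, what: str = "states"):
        self.reached = reached
        self.cap = cap
        super().__init__(
            f"enumeration exceeded cap: reached {reached} {what} (cap {cap}); "
            "raise the cap explicitly to proceed"
        )


class ParseError(QualmError):
    """A document could not be parsed into a logical model."""

    def __init__(self, code: str, message: str, path: str = ""):
        self.code = code
        self.path = path
        loc = f" at {path}" if path else ""
        super().__init__(f"[{code}]{loc}: {message}")
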