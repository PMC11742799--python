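"""Exception hierarchy shared by all phasensor modules."""


class PhasensorError(Exception):
    """Base class for all package-specific errors."""


class DomainError(PhasensorError):
    """A candidate curve was evaluated outside its mathematical domain.

    Carries the structure id and the offending input so callers (and the
    optimizer, which treats these points as infeasible) can report precisely
    what went wrong.
    """

    def __init__(self, structure_id: int, message: str):
        self.structure_id = structure_id
        super().__init__(f"model {structure_id}: {message}")


class InputError(PhasensorError):
    """User-supplied data violates a precondition (empty set, bad shape...)."""


class FitError(PhasensorError):
    """No feasible starting point exists for a candidate structure."""

    def __init__(self, structure_id: int, message: str = "all starts infeasible"):
        self.structure_id = structure_id
        super().__init__(f"model {structure_id}: {message}")


class SelectionError(PhasensorError):
    """No candidate structure could be fitted to the data."""


class ParseError(PhasensorError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(PhasensorError):
    """Parsed data is structurally valid but semantically impossible."""
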