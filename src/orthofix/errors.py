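"""Exception hierarchy for orthofix."""


class OrthofixError(Exception):
    """Base class for all orthofix errors."""


class NewickParseError(OrthofixError):
    """Malformed Newick input.

    Carries the 0-based character ``offset`` at which parsing failed.
    """

    def __init__(self, message: str, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (at character {offset})"
        super().__init__(message)


class TreeValidationError(OrthofixError):
    """A tree violates a structural invariant (duplicate leaves, non-binary...)."""


class ConstraintError(OrthofixError):
    """An orthology/clade constraint is invalid for the given trees."""


class InfeasibleError(OrthofixError):
    """No tree can satisfy the clade constraint set (strict COC mode).

    ``violations`` is a list of human-readable descriptions of the offending
    clades or clade pairs.
    """

    def __init__(self, message: str, violations: list[str] | None = None):
        self.violations = violations or []
        super().__init__(message)


class ResolutionLimitError(OrthofixError):
    """Binary-resolution enumeration would exceed the configured yield limit."""
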