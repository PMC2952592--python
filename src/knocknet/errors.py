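"""Exception hierarchy.

Every error raised on a user-facing path derives from :class:`KnocknetError`
so the CLI can map failure stages to distinct exit codes.
"""


class KnocknetError(Exception):
    """Base class for all knocknet errors."""


class ParseError(KnocknetError):
    """A text file could not be parsed (bad cell, bad shape on disk)."""


class ValidationError(KnocknetError):
    """Parsed input violates a structural invariant (shapes, labels, signs)."""


class ConvergenceError(KnocknetError):
    """A steady-state computation failed to reach the residual tolerance."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class EvaluationError(KnocknetError):
    """A requested metric is undefined for the given inputs."""
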