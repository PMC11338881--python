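"""Exception hierarchy shared across the toolkit."""


class RelframeError(Exception):
    """Base class for all toolkit errors."""


class ConfigurationError(RelframeError):
    """Invalid registry, mapping or parameter configuration."""


class ValidationError(RelframeError):
    """Input data violates a structural invariant (normalization, stochasticity)."""


class DomainError(RelframeError):
    """A query refers to an element outside the relevant domain."""


class DegenerateQueryError(DomainError):
    """A query that is ill-posed by construction (e.g. relating a stimulus to itself)."""


class MissingStateError(DomainError):
    """An agent/time combination has no recorded state."""


class DegeneratePopulationError(RelframeError):
    """Replicator update undefined: mean fitness is zero."""


class InputFormatError(RelframeError):
    """A file could not be parsed into the expected structure."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
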