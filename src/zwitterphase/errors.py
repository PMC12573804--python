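"""Exception types shared across the pipeline stages."""


class ZwitterphaseError(Exception):
    """Base class for all package errors."""


class DomainError(ZwitterphaseError, ValueError):
    """A coordinate lies outside the domain of an analytic model."""


class ParseError(ZwitterphaseError, ValueError):
    """A text file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class SchemaError(ZwitterphaseError, ValueError):
    """A parsed record violates the expected schema (e.g. a missing atom role)."""


class ConvergenceError(ZwitterphaseError, RuntimeError):
    """An iterative solver failed to converge; carries the last residual."""

    def __init__(self, message: str, residual: float | None = None):
        self.residual = residual
        super().__init__(message)


class DataCoverageError(ZwitterphaseError, ValueError):
    """Requested statistic needs data in a region that is entirely unpopulated."""


class MappingError(ZwitterphaseError, KeyError):
    """A frame references a window with no known alignment constant."""
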