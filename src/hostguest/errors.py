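"""Exception hierarchy shared across the package."""


class HostGuestError(Exception):
    """Base class for all package errors."""


class InvalidInputError(HostGuestError, ValueError):
    """Input violates an operation precondition (lengths, emptiness, ranges)."""


class ParseError(HostGuestError, ValueError):
    """A structure/trajectory/table file could not be parsed."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class DomainError(HostGuestError, ValueError):
    """Arguments are outside the mathematical domain of an operation."""


class ClassificationError(HostGuestError, ValueError):
    """An isotherm does not admit the requested classification (e.g. not AL)."""


class GenerationError(HostGuestError, RuntimeError):
    """A synthetic generator could not satisfy its constraints after retries."""
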