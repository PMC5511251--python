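"""Exception hierarchy shared across the package."""


class FiberDiffError(Exception):
    """Base class for all package-specific errors."""


class ParseError(FiberDiffError):
    """A text file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class FormatError(FiberDiffError):
    """Structurally malformed input (e.g. ragged matrix rows)."""


class ConfigError(FiberDiffError):
    """Missing or invalid configuration value."""


class InputError(FiberDiffError):
    """Input data violate an operation's preconditions."""


class DegenerateDataError(InputError):
    """Data are technically valid but carry no usable signal (e.g. flat curve)."""


class AnalysisError(FiberDiffError):
    """A numerical analysis step failed (non-convergence, empty selection...).

    ``diagnostics`` optionally carries the best state reached before failure.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        self.diagnostics = diagnostics or {}
        super().__init__(message)
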