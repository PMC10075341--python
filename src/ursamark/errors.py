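"""Exception types shared across the package."""


class UrsamarkError(Exception):
    """Base class for package-specific errors."""


class SchemaError(UrsamarkError):
    """An input table is missing a required column or uses an unknown code."""


class RowParseError(UrsamarkError):
    """A row of an input table could not be parsed.

    Carries the 1-based line number of the offending row when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class EmptyDataError(UrsamarkError):
    """An operation that needs at least one observation received none."""


class DataConsistencyError(UrsamarkError):
    """Inputs contradict each other (e.g. events recorded with zero survey effort)."""


class UnsupportedLatitudeError(UrsamarkError):
    """Solar events are undefined (polar day/night) at the requested latitude/date."""


class SeparationError(UrsamarkError):
    """A logistic fit is degenerate because a covariate separates the response."""


class ConvergenceError(UrsamarkError):
    """An iterative fit failed to converge within its iteration budget."""
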