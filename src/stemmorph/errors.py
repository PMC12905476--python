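"""Exception hierarchy shared across the package."""


class StemmorphError(Exception):
    """Base class for all package-specific errors."""


class FormatError(StemmorphError):
    """A file or record does not conform to the expected format."""


class ParameterError(StemmorphError, ValueError):
    """An argument is outside its admissible range."""


class DegeneracyError(StemmorphError):
    """Input geometry is degenerate (zero area, zero first harmonic, ...)."""


class DataError(StemmorphError):
    """A data value violates a domain constraint (e.g. nonpositive length)."""


class CalibrationError(StemmorphError):
    """A calibration target cannot be reached; carries the achieved value."""

    def __init__(self, message: str, achieved: float | None = None):
        super().__init__(message)
        self.achieved = achieved
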