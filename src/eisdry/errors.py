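"""Exception hierarchy.

Everything raised on purpose by this package derives from :class:`EisdryError`
so callers (and the CLI) can catch one base class.
"""


class EisdryError(Exception):
    """Base class for all eisdry errors."""


class DomainError(EisdryError, ValueError):
    """An argument is outside its mathematical/physical domain."""


class SpectrumFormatError(EisdryError, ValueError):
    """A spectrum table does not have a recognised column set."""


class ValidationError(EisdryError, ValueError):
    """Input data violates a stated invariant (duplicate frequency, ...)."""


class CircuitParseError(EisdryError, ValueError):
    """Circuit expression could not be parsed; carries the failing position."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


class ParameterError(EisdryError, ValueError):
    """A circuit parameter is missing or outside its allowed range."""


class WeightingError(EisdryError, ValueError):
    """Residual weighting undefined (zero-modulus measured point)."""


class AlignmentError(EisdryError, ValueError):
    """Two spectra do not share a frequency grid."""


class MetricError(EisdryError, ValueError):
    """A relative-error metric is undefined (zero measured component)."""


class InitializationError(EisdryError, ValueError):
    """The fit objective is non-finite at the initial point."""


class CalibrationError(EisdryError, ValueError):
    """Calibration regression is degenerate or under-determined."""


class FrequencyLookupError(EisdryError, KeyError):
    """A requested frequency is absent from a spectrum's grid."""


class ConfigError(EisdryError, ValueError):
    """A simulation or run configuration is invalid."""
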