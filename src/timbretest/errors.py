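"""Exception hierarchy shared across the toolkit."""


class TimbreTestError(Exception):
    """Base class for all toolkit-specific errors."""


class SliderRangeError(TimbreTestError, ValueError):
    """Slider position outside the 0-100 scale."""


class AudioInputError(TimbreTestError, ValueError):
    """Invalid synthesis input (non-positive f0, duration, ...)."""


class UndefinedMeasurementError(TimbreTestError, ValueError):
    """An acoustic measurement is undefined for this signal (e.g. silence)."""


class ResponseParseError(TimbreTestError, ValueError):
    """A response table could not be parsed."""


class ResponseValidationError(TimbreTestError, ValueError):
    """A response table parsed but violates a range or type constraint."""


class SessionConfigError(TimbreTestError, ValueError):
    """Inconsistent session configuration or session/bin-table mismatch."""


class BinningInfeasibleError(TimbreTestError, ValueError):
    """Too few observations to form the requested number of bins."""


class DegenerateDistributionError(TimbreTestError, ValueError):
    """Distance distribution too degenerate for equal-frequency binning."""


class DegenerateDataError(TimbreTestError, ValueError):
    """A psychometric coefficient is undefined for this input (zero variance...)."""


class FactorConvergenceError(TimbreTestError, RuntimeError):
    """The factor solution did not converge within the iteration limit."""


class ValidationWarning(UserWarning):
    """Non-fatal data issue (e.g. memory trial with multiple stimulus playbacks)."""
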