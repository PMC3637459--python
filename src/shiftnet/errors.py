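"""Exception hierarchy for shiftnet.

All shiftnet-specific failures derive from :class:`ShiftNetError` so callers
can catch the package's errors with a single ``except`` clause while still
distinguishing malformed input files from undefined statistics.
"""


class ShiftNetError(Exception):
    """Base class for all shiftnet errors."""


class ConfigurationError(ShiftNetError, ValueError):
    """A configuration object or parameter value is invalid."""


class FormatError(ShiftNetError, ValueError):
    """An input file violates the roster/survey/attendance CSV dialect."""


class UndefinedMetricError(ShiftNetError, ValueError):
    """A network statistic is undefined for the given input.

    Raised, e.g., for density on fewer than two nodes or centralization on
    fewer than three, rather than silently returning NaN.
    """


class UndefinedNetworkError(UndefinedMetricError):
    """Every row of a survey matrix is missing; no network is observable."""


class UndefinedCorrelationError(ShiftNetError, ValueError):
    """A matrix correlation is undefined (too few joint cells or zero variance)."""
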