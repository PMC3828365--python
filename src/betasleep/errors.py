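"""Exception types raised across the pipeline.

Each stage raises a narrow subclass of ValueError/KeyError so callers can
distinguish malformed inputs from genuine bugs.
"""


class BetasleepError(Exception):
    """Base class for all package-specific errors."""


class ChannelError(BetasleepError, KeyError):
    """A required named channel is missing from a recording or file."""


class FormatError(BetasleepError, ValueError):
    """A file violates its format contract (inconsistent lengths, bad header)."""


class InputSizeError(BetasleepError, ValueError):
    """An input is too short for the requested operation."""


class AlignmentError(BetasleepError, ValueError):
    """Epoch/window grids of two inputs do not line up."""


class RangeError(BetasleepError, ValueError):
    """A requested frequency band is empty or outside the available axis."""


class EmptyStateError(BetasleepError, ValueError):
    """No spectrogram window falls in the requested vigilance state."""


class InsufficientDataError(BetasleepError, ValueError):
    """Fewer observations than the minimum the statistic requires."""


class ConfigError(BetasleepError, ValueError):
    """A generator or pipeline configuration is internally inconsistent."""


class DesignError(BetasleepError, ValueError):
    """A statistical design cannot be estimated (e.g. empty cell with interaction)."""


class JoinError(BetasleepError, KeyError):
    """A cross-table join failed (e.g. mouse missing from the clasping table)."""


class DegenerateTableError(BetasleepError, ValueError):
    """A contingency table has a zero margin."""
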