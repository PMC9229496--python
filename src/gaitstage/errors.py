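"""Exception hierarchy shared across the pipeline.

Every anticipated failure mode raises a subclass of :class:`GaitError` so the
command-line layer can catch one type, print the diagnostic, and exit nonzero.
"""


class GaitError(Exception):
    """Base class for all gaitstage errors."""


class InputFormatError(GaitError):
    """Unparsable or malformed input file."""


class SchemaError(GaitError):
    """Tabular input is missing required columns or violates ordering."""


class PersonIndexError(GaitError):
    """Requested person index is not present in a pose-estimation frame."""


class EmptyInputError(GaitError):
    """No frames / rows / samples found where at least one was required."""


class UnknownLandmarkError(GaitError):
    """A requested landmark name is not in the series' landmark set."""


class TooShortTrackError(GaitError):
    """A landmark track has too few surviving frames to be usable."""


class GridMismatchError(GaitError):
    """Two signals that must share a time grid do not."""


class DegenerateSignalError(GaitError):
    """A signal is constant (zero variance) or all-zero where that is invalid."""


class NonUniformGridError(GaitError):
    """An operation requiring a uniform sample grid received a ragged one."""


class OutOfSupportError(GaitError):
    """A requested time window extends beyond the signal's support."""


class NoOverlapError(GaitError):
    """Two signals have no common time support."""


class InsufficientCyclesError(GaitError):
    """Too few gait cycles (extrema) detected to compute a feature."""


class StratificationError(GaitError):
    """A class has too few rows for the requested stratified CV."""


class ConfigError(GaitError):
    """Invalid configuration value or unknown configuration key."""
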