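"""Exception types raised across the package.

All are ValueError subclasses so callers that only care about "bad input"
can catch one base class.
"""


class CortrackError(ValueError):
    """Base class for all package-specific errors."""


class MisalignedFrequency(CortrackError):
    """A target rate does not fall exactly on a DFT bin of the epoch."""


class OutOfRange(CortrackError):
    """A requested frequency bin has no full set of neighbors."""


class FormatError(CortrackError):
    """On-disk recording/epoch container is malformed or inconsistent."""


class UnknownDialect(CortrackError):
    """Recording header declares an unsupported dtype or layout."""


class ConfigError(CortrackError):
    """Pipeline configuration is missing or has an invalid key.

    The message names the offending key path (dot separated).
    """


class BadBand(CortrackError):
    """Band-pass edges violate 0 < lo < hi < fs/2."""


class MissingChannel(CortrackError):
    """A named channel is absent from the recording."""


class IslandChannel(CortrackError):
    """A bad channel has no good neighbor to interpolate from."""


class NoEvents(CortrackError):
    """No event markers match the epoching filter."""


class NoRetainedEpochs(CortrackError):
    """Every epoch has been rejected; nothing to average."""


class LengthMismatch(CortrackError):
    """Array lengths disagree with each other or with the paradigm."""


class UndefinedBin(CortrackError):
    """Normalized power is undefined at the requested bin."""


class EmptyWindow(CortrackError):
    """A baseline/analysis window contains no samples."""


class MissingCondition(CortrackError):
    """A requested condition has no retained epochs."""


class DegenerateDistribution(CortrackError):
    """A cohort parameter distribution has a negative SD."""


class ConstantVector(CortrackError):
    """An input vector is constant where variation is required."""


class MissingColumn(CortrackError):
    """A requested cohort-table column is absent."""
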