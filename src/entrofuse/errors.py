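"""Exception types raised across the pipeline."""


class EntrofuseError(Exception):
    """Base class for all package errors."""


class ProtocolError(EntrofuseError):
    """Invalid stimulation protocol (e.g. clip count not divisible by 3)."""


class ChannelNotFoundError(EntrofuseError, KeyError):
    """A requested channel label is absent from the recording."""


class UpsampleNotSupportedError(EntrofuseError):
    """Target sampling rate exceeds the recording rate."""


class ProtocolMismatchError(EntrofuseError):
    """Protocol timeline does not fit the recording."""


class NyquistError(EntrofuseError):
    """Sampling rate too low for the requested filter."""


class WrongRateError(EntrofuseError):
    """Operation requires a specific sampling rate."""


class InsufficientDataError(EntrofuseError):
    """Input too short for the requested computation."""


class DegenerateToleranceError(EntrofuseError):
    """Similarity tolerance r is zero or negative."""


class InvalidIndexError(EntrofuseError):
    """Invalid entropic index (q = 1 or q < 0)."""


class EmptyOutputError(EntrofuseError):
    """Coarse-graining scale exceeds the series length."""


class AlignmentError(EntrofuseError):
    """Feature columns and labels (or fused matrices) are misaligned."""


class InvalidSplitError(EntrofuseError):
    """Requested train/test split is impossible."""


class ShapeError(EntrofuseError):
    """Array dimensions do not match the model."""


class EmptyInputError(EntrofuseError):
    """No data supplied."""


class ConfigurationError(EntrofuseError):
    """Invalid or incomplete configuration."""
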