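"""Exception hierarchy for the extraction and analysis pipeline."""


class FluctexError(Exception):
    """Base class for all package errors."""


class FormatError(FluctexError):
    """A file is unreadable or not a well-formed EDF."""


class ContentError(FluctexError):
    """A file is structurally valid but holds no usable EEG."""


class UnsupportedLayoutError(FluctexError):
    """A recording layout the pipeline does not handle (e.g. mixed sampling rates)."""


class ParameterError(FluctexError, ValueError):
    """An analysis parameter is out of its valid range."""


class InsufficientDataError(FluctexError):
    """Too little data to compute the requested quantity."""


class EmptyAnalysisError(FluctexError):
    """No epochs survive screening; nothing left to analyse."""


class RegionEmptyError(FluctexError):
    """A scalp region has no available member channels."""


class InputError(FluctexError, ValueError):
    """Invalid tabular/model input (duplicate ids, constant feature, ...)."""
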