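"""Exception hierarchy for dlsann.

All package errors derive from :class:`DlsAnnError` so callers can catch
everything this library raises with a single except clause.
"""


class DlsAnnError(Exception):
    """Base class for all dlsann errors."""


class ParameterDomainError(DlsAnnError, ValueError):
    """A physical parameter is outside its admissible domain (names the field)."""


class ConfigError(DlsAnnError, ValueError):
    """A configuration object is internally inconsistent."""


class InputSizeError(DlsAnnError, ValueError):
    """An input array is too short / wrongly shaped for the requested operation."""


class DegenerateInputError(DlsAnnError, ValueError):
    """An input is degenerate (e.g. a constant series with zero dynamic range)."""


class NormalizationError(DlsAnnError, ValueError):
    """Autocorrelation normalization is impossible (zero dynamic range)."""


class StateError(DlsAnnError, RuntimeError):
    """An object is in the wrong state for the requested operation."""


class FormatError(DlsAnnError, ValueError):
    """A file could not be parsed in the declared format."""


class TrainingError(DlsAnnError, RuntimeError):
    """Network training cannot proceed (degenerate targets, non-finite maths)."""


class ModelIOError(DlsAnnError, ValueError):
    """A model file is corrupt, truncated, or of an unsupported version."""


class RunError(DlsAnnError, RuntimeError):
    """A monitoring run cannot be processed at all (e.g. empty directory)."""
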