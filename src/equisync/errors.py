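"""Exception hierarchy.

Everything raised on bad data or bad parameters derives from
:class:`EquiSyncError` so callers (and the CLI) can catch one type.
"""


class EquiSyncError(Exception):
    """Base class for all equisync errors."""


class FormatError(EquiSyncError, ValueError):
    """A log, manifest or table violates the expected format."""


class EmptyRecordingError(FormatError):
    """Fewer than two valid samples after cleaning."""


class OrderingError(FormatError):
    """Timestamps are not strictly increasing."""


class MissingChannelError(EquiSyncError, ValueError):
    """A required optional channel (sync pulse, orientation) is absent."""


class NoPulseError(EquiSyncError, ValueError):
    """Sync channel present but contains no 0->1 transition."""


class InsufficientOverlapError(EquiSyncError, ValueError):
    """Two recordings overlap by less than the required duration."""


class ManifestError(FormatError):
    """Session manifest entry is invalid or references a missing file."""


class DuplicateEntryError(ManifestError):
    """Two manifest entries share (participant, session)."""


class ParameterError(EquiSyncError, ValueError):
    """A parameter is out of its valid range."""


class ContractError(EquiSyncError, ValueError):
    """An input does not satisfy an operation's contract."""


class WindowError(EquiSyncError, ValueError):
    """A crop window does not sufficiently overlap the signal."""


class NoPeakError(EquiSyncError, ValueError):
    """No local spectral maximum found in the search band."""


class UndefinedMetricError(EquiSyncError, ValueError):
    """A statistic is undefined for the given group (e.g. n < 2)."""


class CoverageError(EquiSyncError, ValueError):
    """A required session is missing for an entity being averaged."""


class ConfigError(EquiSyncError, ValueError):
    """A run configuration field is invalid."""
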