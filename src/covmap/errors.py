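"""Exception hierarchy.

Invalid scalar arguments raise plain :class:`ValueError`; the classes below
mark structural problems (montage layout, file format, degenerate data) that
callers may want to handle separately.
"""


class CovmapError(Exception):
    """Base class for package-specific errors."""


class FormatError(CovmapError, ValueError):
    """A file could not be parsed as EDF/BrainVision or a sidecar table."""


class InvalidMontageError(CovmapError, ValueError):
    """A montage operation was asked of an unsuitable channel layout."""


class EmptyDataError(CovmapError, ValueError):
    """No usable samples (or weights) remain after masking/filtering."""


class UndefinedCorrelationError(CovmapError, ValueError):
    """A correlation was requested between series with zero variance."""


class AlignmentError(CovmapError, ValueError):
    """Two recordings that must be time-aligned are not."""


class ConfigError(CovmapError, ValueError):
    """A run configuration field is missing, contradictory or out of range."""
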