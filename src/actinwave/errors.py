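"""Exception hierarchy shared across the package."""


class ActinWaveError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(ActinWaveError, ValueError):
    """A simulation or run configuration violates its invariants."""


class MetadataError(ActinWaveError, ValueError):
    """Required imaging metadata (frame interval, pixel size) is missing."""


class GeometryError(ActinWaveError, ValueError):
    """An ROI or reslice line falls outside the image frame."""


class NormalizationError(ActinWaveError, ValueError):
    """Baseline estimation produced a non-positive value; the background
    region was likely wrong (inside the cell or brighter than the signal)."""


class InsufficientDataError(ActinWaveError, ValueError):
    """A trace is too short for the requested analysis."""


class CorrelationError(ActinWaveError, ValueError):
    """Cross-correlation is undefined (flat trace) or inputs are incompatible."""
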