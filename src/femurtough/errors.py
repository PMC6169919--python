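"""Exception hierarchy for femurtough.

All package errors derive from :class:`FemurToughError` so callers can
distinguish validation failures from genuine bugs.
"""


class FemurToughError(Exception):
    """Base class for all femurtough errors."""


class InputError(FemurToughError, ValueError):
    """Invalid numeric input (negative length, non-finite load, ...)."""


class GeometryError(FemurToughError, ValueError):
    """Cross-section or notch geometry violates its invariants."""


class RangeError(FemurToughError, ValueError):
    """Argument outside the supported window of a tabulated solution."""


class EventDetectionError(FemurToughError, ValueError):
    """Crack initiation / peak / instability could not be located."""


class SegmentationError(FemurToughError, ValueError):
    """Thresholding produced an empty cortical mask."""


class TopologyError(FemurToughError, ValueError):
    """Mask topology is not the expected single annulus."""


class CalibrationError(FemurToughError, ValueError):
    """Standard curve or study calibration is unusable."""


class NormalizationError(FemurToughError, ValueError):
    """Normalization denominator (e.g. collagen mass) is not positive."""


class SchemaError(FemurToughError, ValueError):
    """An input file does not match the expected column schema."""
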