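"""Exception hierarchy shared across the package."""


class CordMotionError(Exception):
    """Base class for all package errors."""


class MetadataError(CordMotionError):
    """A required metadata field is missing or unparseable."""


class StructuralError(CordMotionError):
    """On-disk structure disagrees with its own header (e.g. frame count)."""


class RangeError(CordMotionError):
    """A grey value lies outside the encodable range."""


class GeometryError(CordMotionError):
    """ROI outside the image grid or covering no pixels."""


class StateError(CordMotionError):
    """Operation applied to an object in the wrong state (e.g. double drift correction)."""


class SaturationError(CordMotionError):
    """Simulated signal would exceed the encodable velocity range."""


class ConfigurationError(CordMotionError):
    """Invalid simulation or run configuration."""


class InsufficientDataError(CordMotionError):
    """Not enough subjects/segments/pairs for the requested statistic."""
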