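"""Exception hierarchy shared across the pipeline."""


class NematrackError(Exception):
    """Base class for all package errors."""


class DecodeError(NematrackError):
    """A video file could not be read or contains no frames."""


class ConfigurationError(NematrackError):
    """Required configuration (e.g. frame rate) is missing or invalid."""


class ParameterError(NematrackError, ValueError):
    """An operation received an out-of-contract argument."""


class DegenerateShapeError(NematrackError):
    """A contour has no usable elongated midline (e.g. thins to a point)."""


class UndefinedCurvatureError(NematrackError):
    """Curvature requested for coincident points."""


class SpecificationError(NematrackError):
    """A synthetic scene is internally inconsistent (e.g. worm larger than frame)."""
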