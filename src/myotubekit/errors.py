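"""Exception hierarchy for myotubekit.

All package-specific failures derive from :class:`MyotubeKitError` so callers
can catch one base class at the CLI boundary.
"""


class MyotubeKitError(Exception):
    """Base class for all myotubekit errors."""


class UnsupportedFormatError(MyotubeKitError):
    """Raised for image formats the pipeline does not accept (e.g. TIFF)."""


class InvalidWindowError(MyotubeKitError, ValueError):
    """Raised when an intensity window has low >= high."""


class InvalidThresholdError(MyotubeKitError, ValueError):
    """Raised when a threshold lies outside [0, 1]."""


class InvalidParameterError(MyotubeKitError, ValueError):
    """Raised for out-of-range numeric parameters (areas, sizes, widths)."""


class InvalidEditError(MyotubeKitError, ValueError):
    """Raised when an edit-script entry is malformed or out of bounds."""


class CalibrationError(MyotubeKitError, ValueError):
    """Raised when the pixel calibration is too coarse for an operation."""


class ShapeMismatchError(MyotubeKitError, ValueError):
    """Raised when two rasters that must share dimensions do not."""


class NoMatchError(MyotubeKitError, ValueError):
    """Raised when a removal point has no capture-radius match."""


class UndefinedFusionIndexError(MyotubeKitError, ZeroDivisionError):
    """Raised when the fusion index is requested for zero nuclei."""


class DegenerateClusterError(MyotubeKitError, ValueError):
    """Raised when a trendline is requested for coincident points."""


class OffMyotubeError(MyotubeKitError, ValueError):
    """Raised when a diameter sample point falls on background."""


class DependencyError(MyotubeKitError):
    """Raised by resume when a prerequisite artifact is missing."""


class SpecError(MyotubeKitError, ValueError):
    """Raised when a synthetic scene specification is infeasible."""
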