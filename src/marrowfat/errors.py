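"""Exception hierarchy for the marrowfat package."""


class MarrowFatError(Exception):
    """Base class for all package errors."""


class ValidationError(MarrowFatError, ValueError):
    """Invalid parameter or inconsistent input."""


class GeometryError(ValidationError):
    """Phantom or stack geometry is inconsistent (e.g. non-increasing radii)."""


class FormatError(MarrowFatError, IOError):
    """On-disk image container is malformed or has unreadable geometry."""


class AlignmentError(MarrowFatError):
    """Grids do not coincide and no registration was requested."""


class SegmentationError(MarrowFatError):
    """Tissue segmentation failed (e.g. no closed cortical contour)."""


class CalibrationError(MarrowFatError):
    """Threshold calibration cannot proceed (e.g. empty reference region)."""


class DegenerateInputError(MarrowFatError, ValueError):
    """Input has too little structure for the requested operation."""


class UndefinedRatioError(MarrowFatError, ZeroDivisionError):
    """A ratio such as fat/(fat+water) is undefined because both terms are zero."""


class UndefinedEffectError(MarrowFatError, ZeroDivisionError):
    """An effect size is undefined because both group SDs are zero."""
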