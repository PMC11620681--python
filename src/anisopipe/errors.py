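"""Exception hierarchy for the anisotropy pipeline.

Errors are grouped so the CLI can map them onto exit codes:
:class:`ConfigurationError` -> 2, :class:`DataQualityError` -> 3.
"""


class AnisopipeError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(AnisopipeError):
    """Invalid or incomplete run configuration (missing paths, bad values)."""


class DataQualityError(AnisopipeError):
    """Input data unusable for the requested analysis."""


class UnreadableFileError(ConfigurationError):
    """File missing or not a readable TIFF."""


class RectangleOutOfBoundsError(ConfigurationError):
    """A channel rectangle extends beyond the camera frame."""


class RectangleSizeMismatchError(ConfigurationError):
    """Parallel and perpendicular rectangles differ in width or height."""


class RectangleOverlapError(ConfigurationError):
    """Parallel and perpendicular rectangles overlap."""


class FlatImageError(DataQualityError):
    """Channel has no structure (zero variance); registration impossible."""


class ShiftBoundError(DataQualityError):
    """Estimated or requested shift exceeds the configured maximum."""


class UnstableGFactorError(DataQualityError):
    """Perpendicular calibration signal too weak for a stable I_par/I_perp ratio."""


class InsufficientSignalError(DataQualityError):
    """Too few valid pixels in a region of interest."""
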