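"""Core data types and TIFF input/output for dual-channel anisotropy imaging.

An Optosplit emission splitter projects the parallel (I∥) and perpendicular
(I⊥) polarization fields side by side onto one camera sensor, so a single raw
frame contains both channels.  The types here carry a frame through the
pipeline: :class:`OptosplitFrame` (raw camera image plus the two channel
rectangles), :class:`ChannelPair` (cropped, optionally registered and
background-corrected I∥/I⊥ images), :class:`GFactor` (instrument polarization
sensitivity correction) and :class:`AnisotropyMap` (per-pixel anisotropy with
validity mask).

Coordinate convention
---------------------
All coordinates are 0-based with the origin at the top-left of the image.
Rectangles are ``(x, y, w, h)`` half-open boxes: they cover columns
``x .. x+w-1`` and rows ``y .. y+h-1``.  Loading never rescales or otherwise
mutates pixel values; the camera offset is left in place and removed later by
rolling-ball background subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import tifffile

from .errors import (
    RectangleOutOfBoundsError,
    RectangleOverlapError,
    RectangleSizeMismatchError,
    UnreadableFileError,
)

__all__ = [
    "Rect",
    "OptosplitFrame",
    "ChannelPair",
    "GFactor",
    "AnisotropyMap",
    "read_frame",
    "write_frame",
    "write_image",
    "read_image",
]


@dataclass(frozen=True)
class Rect:
    """Half-open pixel rectangle ``(x, y, w, h)``, origin top-left."""

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"rectangle must have positive size, got {self}")

    @classmethod
    def coerce(cls, value: Union["Rect", tuple, list, str]) -> "Rect":
        """Build a Rect from a Rect, 4-sequence, or ``"X,Y,W,H"`` string."""
        if isinstance(value, cls):
            return value
        if isinstance(value, str):
            value = [int(v) for v in value.split(",")]
        x, y, w, h = (int(v) for v in value)
        return cls(x, y, w, h)

    @property
    def slices(self) -> tuple[slice, slice]:
        """(row, col) slices selecting this rectangle from a 2-D array."""
        return slice(self.y, self.y + self.h), slice(self.x, self.x + self.w)

    def within(self, shape: tuple[int, int]) -> bool:
        rows, cols = shape
        return 0 <= self.x and 0 <= self.y and self.x + self.w <= cols and self.y + self.h <= rows

    def overlaps(self, other: "Rect") -> bool:
        return not (
            self.x + self.w <= other.x
            or other.x + other.w <= self.x
            or self.y + self.h <= other.y
            or other.y + other.h <= self.y
        )

    def center_fraction(self, frac: float) -> "Rect":
        """Central sub-rectangle covering ``frac`` of each linear dimension."""
        w = max(1, int(round(self.w * frac)))
        h = max(1, int(round(self.h * frac)))
        return Rect(self.x + (self.w - w) // 2, self.y + (self.h - h) // 2, w, h)


def _validate_rects(shape: tuple[int, int], rect_para: Rect, rect_perp: Rect) -> None:
    if (rect_para.w, rect_para.h) != (rect_perp.w, rect_perp.h):
        raise RectangleSizeMismatchError(
            f"rect_para {rect_para} and rect_perp {rect_perp} differ in size"
        )
    for name, rect in (("rect_para", rect_para), ("rect_perp", rect_perp)):
        if not rect.within(shape):
            raise RectangleOutOfBoundsError(f"{name} {rect} outside image of shape {shape}")
    if rect_para.overlaps(rect_perp):
        raise RectangleOverlapError(f"rect_para {rect_para} overlaps rect_perp {rect_perp}")


@dataclass
class OptosplitFrame:
    """One raw camera image containing both polarization fields.

    Parameters
    ----------
    pixels
        2-D array of nonnegative intensity counts (camera arbitrary units).
    rect_para, rect_perp
        Rectangles locating the parallel and perpendicular fields. Must have
        identical size, lie within ``pixels`` and not overlap.
    timepoint_min
        Acquisition time in minutes relative to treatment addition; values
        ``<= 0`` are baseline.
    channel_label
        Free text, e.g. the sensor color ("mVenus-cytosolic").
    metadata
        Key -> string map (binning, exposure, LED power, ...).
    """

    pixels: np.ndarray
    rect_para: Rect
    rect_perp: Rect
    timepoint_min: float = 0.0
    channel_label: str = ""
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if np.any(self.pixels < 0):
            raise ValueError("pixel values must be nonnegative")
        self.rect_para = Rect.coerce(self.rect_para)
        self.rect_perp = Rect.coerce(self.rect_perp)
        _validate_rects(self.pixels.shape, self.rect_para, self.rect_perp)


@dataclass
class ChannelPair:
    """Cropped I∥/I⊥ image pair, flagged by processing stage."""

    para: np.ndarray
    perp: np.ndarray
    aligned: bool = False
    background_corrected: bool = False
    shift_applied: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.para = np.asarray(self.para, dtype=np.float64)
        self.perp = np.asarray(self.perp, dtype=np.float64)
        if self.para.shape != self.perp.shape:
            raise ValueError(
                f"channel shapes differ: {self.para.shape} vs {self.perp.shape}"
            )
        if self.background_corrected and (self.para.min() < 0 or self.perp.min() < 0):
            raise ValueError("background-corrected channels must be nonnegative")


@dataclass
class GFactor:
    """Instrument polarization-sensitivity correction G = I∥/I⊥ (fluorescein).

    ``mode`` is ``"scalar"`` (one value for the whole field, the default used
    throughout) or ``"per-pixel"`` (a smoothed ratio map, for vignetting
    studies).
    """

    value: float
    mode: str = "scalar"
    map: Optional[np.ndarray] = None
    source_frames: int = 0
    estimation_region: Union[Rect, str] = "full"

    def __post_init__(self) -> None:
        if self.mode not in ("scalar", "per-pixel"):
            raise ValueError(f"unknown GFactor mode {self.mode!r}")
        if not self.value > 0:
            raise ValueError("G-factor must be positive")
        if self.mode == "per-pixel":
            if self.map is None:
                raise ValueError("per-pixel mode requires a map")
            self.map = np.asarray(self.map, dtype=np.float64)
            if not np.all(self.map > 0):
                raise ValueError("per-pixel G map must be strictly positive")

    def for_shape(self, shape: tuple[int, int]) -> np.ndarray | float:
        """G as a scalar or an array matching ``shape``."""
        if self.mode == "scalar":
            return float(self.value)
        if self.map.shape != shape:
            raise ValueError(f"G map shape {self.map.shape} != channel shape {shape}")
        return self.map


@dataclass
class AnisotropyMap:
    """Per-pixel anisotropy r with total intensity and validity mask.

    ``valid`` is False wherever total intensity is at or below the threshold
    or the denominator of the anisotropy formula is numerically unsafe; ``r``
    is 0 at invalid pixels (never NaN) and the mask carries the information.
    """

    r: np.ndarray
    total_intensity: np.ndarray
    valid: np.ndarray
    g_used: GFactor
    intensity_threshold: float

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=np.float64)
        self.total_intensity = np.asarray(self.total_intensity, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.r.shape == self.total_intensity.shape == self.valid.shape):
            raise ValueError("r, total_intensity and valid must share one shape")
        if self.valid.any():
            rv = self.r[self.valid]
            if rv.min() < -0.5 - 1e-9 or rv.max() > 1 + 1e-9:
                raise ValueError("valid anisotropy values must lie in [-0.5, 1]")


def read_frame(
    path: Union[str, Path],
    rect_para: Union[Rect, tuple, str],
    rect_perp: Union[Rect, tuple, str],
    timepoint_min: float = 0.0,
    interval_min: float = 5.0,
    channel_label: str = "",
) -> list[OptosplitFrame]:
    """Read a single- or multi-page TIFF into one frame per page.

    Pages of a multi-page TIFF are interpreted as a time series in page
    order: page ``p`` (0-based) gets time ``timepoint_min + interval_min*p``,
    matching a baseline acquisition followed by fixed-interval sampling.
    Pixel values are returned exactly as stored.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            pages = [page.asarray() for page in tif.pages]
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise UnreadableFileError(f"cannot read TIFF {path}: {exc}") from exc
    if not pages:
        raise UnreadableFileError(f"TIFF {path} contains no pages")
    rect_para = Rect.coerce(rect_para)
    rect_perp = Rect.coerce(rect_perp)
    frames = []
    for i, pixels in enumerate(pages):
        if pixels.ndim != 2:
            raise UnreadableFileError(f"page {i} of {path} is not a 2-D grayscale image")
        frames.append(
            OptosplitFrame(
                pixels=pixels,
                rect_para=rect_para,
                rect_perp=rect_perp,
                timepoint_min=timepoint_min + interval_min * i,
                channel_label=channel_label,
                metadata={"source": str(path), "page": str(i)},
            )
        )
    return frames


def write_frame(frame: OptosplitFrame, path: Union[str, Path]) -> None:
    """Write a frame's pixels to TIFF, preserving dtype (uint16 for camera data)."""
    tifffile.imwrite(Path(path), frame.pixels)


def write_image(image: np.ndarray, path: Union[str, Path]) -> None:
    """Write a derived 2-D map (e.g. an r map) as float32 TIFF."""
    arr = np.asarray(image)
    if arr.dtype.kind == "f":
        arr = arr.astype(np.float32)
    tifffile.imwrite(Path(path), arr)


def read_image(path: Union[str, Path]) -> np.ndarray:
    """Read a plain 2-D TIFF image (derived map or label mask)."""
    try:
        return tifffile.imread(Path(path))
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise UnreadableFileError(f"cannot read TIFF {path}: {exc}") from exc
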