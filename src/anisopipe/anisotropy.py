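"""G-factor estimation and pixel-by-pixel anisotropy maps.

Fluorescence anisotropy is computed per pixel from background-corrected
intensities as

    r = (I∥ − G·I⊥) / (I∥ + 2·G·I⊥)

where G corrects the instrument's unequal sensitivity to the two polarization
channels.  G is estimated from fluorescein solution, whose anisotropy is near
zero, which reduces the relation to G = I∥/I⊥.  The denominator
I∥ + 2·G·I⊥ is also the (corrected) total intensity used for masking.
"""

from __future__ import annotations

from typing import Sequence, Union

import numpy as np
from scipy import ndimage as ndi

from .errors import UnstableGFactorError
from .image_model import AnisotropyMap, ChannelPair, GFactor, Rect

__all__ = ["estimate_g_factor", "anisotropy_map", "mask_low_signal"]

DENOMINATOR_EPS = 1e-6  # counts; guards r against 0/0 at empty pixels
DEFAULT_INTENSITY_THRESHOLD = 50.0  # counts, post background subtraction


def _region_slices(shape: tuple[int, int], region: Union[Rect, str]) -> tuple[slice, slice]:
    if region == "full":
        return slice(None), slice(None)
    if region == "center":
        region = Rect(0, 0, shape[1], shape[0]).center_fraction(0.5)
    return Rect.coerce(region).slices


def estimate_g_factor(
    fluorescein_pairs: Sequence[ChannelPair],
    mode: str = "scalar",
    region: Union[Rect, str] = "center",
    min_mean_intensity: float = 10.0,
    smooth_sigma: float = 2.0,
    offset: float = 0.0,
) -> GFactor:
    """Estimate the instrument G-factor from fluorescein calibration pairs.

    Because fluorescein's anisotropy is ≈ 0, the two channels should be
    detected equally bright and their ratio isolates the instrument response:
    G = I∥/I⊥.  Scalar mode (the default used for the whole run) returns the
    ratio of channel means over the estimation region and all pairs;
    per-pixel mode returns the ratio of Gaussian-smoothed mean channels, for
    quantifying vignetting.

    ``region`` is ``"center"`` (central 50% of the field, avoiding edge
    roll-off), ``"full"``, or an explicit :class:`Rect`.  ``offset`` is the
    camera dark level in counts, subtracted from both channels before the
    ratio — at low calibration brightness an uncorrected offset pulls G
    toward 1.
    """
    if len(fluorescein_pairs) == 0:
        raise ValueError("need at least one fluorescein pair")
    if mode not in ("scalar", "per-pixel"):
        raise ValueError(f"unknown mode {mode!r}")
    shape = fluorescein_pairs[0].para.shape
    sl = _region_slices(shape, region)
    para_stack = np.stack([np.asarray(p.para, dtype=np.float64) for p in fluorescein_pairs])
    perp_stack = np.stack([np.asarray(p.perp, dtype=np.float64) for p in fluorescein_pairs])

    mean_para = float(para_stack[(slice(None),) + sl].mean()) - offset
    mean_perp = float(perp_stack[(slice(None),) + sl].mean()) - offset
    if mean_perp < min_mean_intensity or mean_para < min_mean_intensity:
        raise UnstableGFactorError(
            f"calibration signal too weak (means {mean_para:.1f}/{mean_perp:.1f} "
            f"< {min_mean_intensity})"
        )
    value = mean_para / mean_perp

    region_label: Union[Rect, str]
    region_label = region if isinstance(region, str) else Rect.coerce(region)
    if mode == "scalar":
        return GFactor(
            value=value,
            mode="scalar",
            source_frames=len(fluorescein_pairs),
            estimation_region=region_label,
        )

    para_smooth = ndi.gaussian_filter(para_stack.mean(axis=0) - offset, smooth_sigma)
    perp_smooth = ndi.gaussian_filter(perp_stack.mean(axis=0) - offset, smooth_sigma)
    if perp_smooth.min() <= 0:
        raise UnstableGFactorError("smoothed perpendicular channel touches zero")
    gmap = para_smooth / perp_smooth
    return GFactor(
        value=value,
        mode="per-pixel",
        map=gmap,
        source_frames=len(fluorescein_pairs),
        estimation_region=region_label,
    )


def anisotropy_map(
    pair: ChannelPair,
    g: GFactor,
    intensity_threshold: float = DEFAULT_INTENSITY_THRESHOLD,
    eps: float = DENOMINATOR_EPS,
) -> AnisotropyMap:
    """Compute the per-pixel anisotropy map from an aligned, corrected pair.

    r = (I∥ − G·I⊥)/(I∥ + 2·G·I⊥); total intensity is the denominator.
    Pixels whose total intensity is at or below ``intensity_threshold``, or
    whose denominator is below ``eps``, are marked invalid and carry r = 0
    (never NaN).  For nonnegative channels every valid r lies in [−0.5, 1]
    by algebra.
    """
    if not pair.aligned or not pair.background_corrected:
        raise ValueError("anisotropy expects an aligned, background-corrected pair")
    gval = g.for_shape(pair.para.shape)
    ipar = pair.para
    iperp_g = gval * pair.perp
    total = ipar + 2.0 * iperp_g
    valid = (total > intensity_threshold) & (total > eps)
    r = np.zeros_like(total)
    np.divide(ipar - iperp_g, total, out=r, where=valid)
    return AnisotropyMap(
        r=r,
        total_intensity=total,
        valid=valid,
        g_used=g,
        intensity_threshold=float(intensity_threshold),
    )


def mask_low_signal(amap: AnisotropyMap, threshold: float) -> AnisotropyMap:
    """Invalidate additional pixels whose total intensity falls below ``threshold``.

    Dim pixels — cell rims, out-of-focus haze — carry unreliable anisotropy;
    this tightens the mask without touching the r values.  ``threshold=0``
    leaves the mask unchanged.
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    valid = amap.valid & (amap.total_intensity >= threshold) if threshold > 0 else amap.valid.copy()
    return AnisotropyMap(
        r=amap.r.copy(),
        total_intensity=amap.total_intensity.copy(),
        valid=valid,
        g_used=amap.g_used,
        intensity_threshold=amap.intensity_threshold,
    )
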