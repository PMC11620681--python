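import numpy as np
import pytest

from anisopipe.image_model import ChannelPair, OptosplitFrame, Rect


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def half_split_frame(rng):
    """A 100x200 uint16 frame split into two side-by-side 100x100 fields."""
    pixels = rng.integers(0, 4000, size=(100, 200)).astype(np.uint16)
    return OptosplitFrame(
        pixels=pixels,
        rect_para=Rect(0, 0, 100, 100),
        rect_perp=Rect(100, 0, 100, 100),
    )


def make_pair(para, perp=None, aligned=True, corrected=True):
    """ChannelPair helper for tests that synthesize channels directly."""
    para = np.asarray(para, dtype=float)
    perp = para.copy() if perp is None else np.asarray(perp, dtype=float)
    return ChannelPair(
        para=para, perp=perp, aligned=aligned, background_corrected=corrected
    )


def brute_force_opening(image, radius):
    """Independent grayscale-opening oracle: explicit min/max over a disk.

    Boundaries use symmetric (edge-mirroring) padding at each stage.
    """
    img = np.asarray(image, dtype=float)
    r = int(np.ceil(radius))
    offsets = [
        (dy, dx)
        for dy in range(-r, r + 1)
        for dx in range(-r, r + 1)
        if dy * dy + dx * dx <= radius * radius
    ]

    def _scan(arr, fn):
        padded = np.pad(arr, r, mode="symmetric")
        out = np.empty_like(arr)
        for i in range(arr.shape[0]):
            for j in range(arr.shape[1]):
                out[i, j] = fn(padded[i + r + dy, j + r + dx] for dy, dx in offsets)
        return out

    return _scan(_scan(img, min), max)
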