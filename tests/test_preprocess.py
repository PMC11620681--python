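import numpy as np
import pytest

from anisopipe.errors import FlatImageError, ShiftBoundError
from anisopipe.image_model import OptosplitFrame, Rect
from anisopipe.preprocess import (
    ShiftEstimate,
    apply_shift,
    estimate_shift,
    rolling_ball_background,
    split_channels,
    subtract_background,
)

from conftest import brute_force_opening, make_pair


def smooth_test_image(rng, shape=(64, 64), margin=8):
    """Structured image whose content stays away from the borders."""
    import scipy.ndimage as ndi

    img = rng.random(shape)
    img = ndi.gaussian_filter(img, 3)
    img[:margin] = img[-margin:] = 0
    img[:, :margin] = img[:, -margin:] = 0
    return img * 1000


class TestSplitChannels:
    def test_ramp_image_direct_indexing(self):
        pixels = (np.arange(6)[:, None] * 12 + np.arange(12)[None, :]).astype(np.uint16)
        frame = OptosplitFrame(
            pixels=pixels, rect_para=Rect(0, 0, 6, 6), rect_perp=Rect(6, 0, 6, 6)
        )
        pair = split_channels(frame)
        assert pair.para[0, 0] == 0
        assert pair.perp[0, 0] == 6
        assert pair.para.shape == pair.perp.shape == (6, 6)

    def test_identical_rects_give_identical_subimages(self, rng):
        # validation bypassed: frame built without invariant checks
        frame = object.__new__(OptosplitFrame)
        frame.pixels = rng.integers(0, 100, (20, 20)).astype(np.uint16)
        frame.rect_para = Rect(2, 2, 10, 10)
        frame.rect_perp = Rect(2, 2, 10, 10)
        pair = split_channels(frame, validate=False)
        np.testing.assert_array_equal(pair.para, pair.perp)

    def test_mirror_symmetric_frame(self, rng):
        half = rng.integers(0, 1000, (32, 32)).astype(np.uint16)
        pixels = np.concatenate([half, np.fliplr(half)], axis=1)
        frame = OptosplitFrame(
            pixels=pixels, rect_para=Rect(0, 0, 32, 32), rect_perp=Rect(32, 0, 32, 32)
        )
        pair = split_channels(frame)
        np.testing.assert_array_equal(pair.para, np.fliplr(pair.perp))

    def test_photon_conservation(self, half_split_frame):
        pair = split_channels(half_split_frame)
        src = half_split_frame.pixels
        assert pair.para.sum() == src[:, :100].sum()
        assert pair.perp.sum() == src[:, 100:].sum()


class TestEstimateShift:
    def test_identical_channels_give_zero(self, rng):
        img = smooth_test_image(rng)
        s = estimate_shift(make_pair(img, img.copy(), aligned=False, corrected=False))
        assert (s.dy, s.dx) == (0.0, 0.0)

    @pytest.mark.parametrize("dy,dx", [(3, -2), (-5, 5), (1, 4)])
    def test_integer_displacement_recovered_exactly(self, rng, dy, dx):
        img = smooth_test_image(rng)
        perp = np.roll(img, (dy, dx), axis=(0, 1))  # content displaced by (dy, dx)
        s = estimate_shift(make_pair(img, perp, aligned=False, corrected=False))
        assert (s.dy, s.dx) == (-dy, -dx)  # correction undoes the displacement

    def test_flat_image_rejected(self):
        with pytest.raises(FlatImageError):
            estimate_shift(make_pair(np.full((32, 32), 7.0), aligned=False, corrected=False))

    def test_out_of_bound_shift_rejected(self, rng):
        img = smooth_test_image(rng, shape=(96, 96), margin=24)
        perp = np.roll(img, (15, 0), axis=(0, 1))
        with pytest.raises(ShiftBoundError):
            estimate_shift(make_pair(img, perp, aligned=False, corrected=False), max_shift=10)


class TestApplyShift:
    def test_zero_shift_bit_exact(self, rng):
        pair = make_pair(rng.random((16, 16)), rng.random((16, 16)),
                         aligned=False, corrected=False)
        out = apply_shift(pair, ShiftEstimate(0.0, 0.0))
        np.testing.assert_array_equal(out.perp, pair.perp)
        assert out.aligned

    def test_integer_shift_moves_bright_pixel(self):
        perp = np.zeros((32, 32))
        perp[10, 10] = 255.0
        pair = make_pair(np.ones((32, 32)), perp, aligned=False, corrected=False)
        out = apply_shift(pair, ShiftEstimate(3.0, -2.0))
        assert out.perp[13, 8] == 255.0
        assert out.perp[10, 10] == 0.0

    def test_round_trip_residual_shift_small(self, rng):
        img = smooth_test_image(rng)
        perp = np.roll(img, (4, -3), axis=(0, 1))
        pair = make_pair(img, perp, aligned=False, corrected=False)
        s = estimate_shift(pair)
        aligned = apply_shift(pair, s)
        resid = estimate_shift(aligned)
        assert abs(resid.dy) <= 0.25 and abs(resid.dx) <= 0.25

    def test_bound_enforced(self, rng):
        pair = make_pair(rng.random((16, 16)), aligned=False, corrected=False)
        with pytest.raises(ShiftBoundError):
            apply_shift(pair, ShiftEstimate(12.0, 0.0), max_shift=10)


class TestRollingBall:
    def test_constant_image_returns_constant(self):
        img = np.full((32, 32), 10.0)
        np.testing.assert_allclose(rolling_ball_background(img, 7), 10.0)

    def test_matches_brute_force_oracle_on_random_image(self, rng):
        img = rng.integers(0, 500, (32, 32)).astype(float)
        expected = brute_force_opening(img, 5)
        np.testing.assert_allclose(rolling_ball_background(img, 5), expected)

    def test_spike_on_pedestal_removed(self):
        img = np.full((32, 32), 10.0)
        img[16, 16] = 100.0
        bg = rolling_ball_background(img, 5)
        np.testing.assert_allclose(bg, 10.0)
        np.testing.assert_allclose(bg, brute_force_opening(img, 5))

    def test_wide_disk_retained_in_background(self):
        # structure wider than the ball is background (diameter 40 vs radius 10)
        yy, xx = np.mgrid[0:64, 0:64]
        img = np.where((yy - 32) ** 2 + (xx - 32) ** 2 <= 20**2, 50.0, 0.0)
        bg = rolling_ball_background(img, 10)
        interior = (yy - 32) ** 2 + (xx - 32) ** 2 <= 8**2
        np.testing.assert_allclose(bg[interior], 50.0)

    def test_background_never_exceeds_image(self, rng):
        img = rng.integers(0, 1000, (40, 40)).astype(float)
        bg = rolling_ball_background(img, 6)
        assert np.all(bg <= img + 1e-9)

    def test_idempotent_as_background_operator(self, rng):
        img = rng.integers(0, 500, (32, 32)).astype(float)
        once = rolling_ball_background(img, 5)
        twice = rolling_ball_background(once, 5)
        np.testing.assert_allclose(twice, once)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            rolling_ball_background(np.zeros((8, 8)), 0)


class TestSubtractBackground:
    def test_constant_channels_become_zero(self):
        pair = make_pair(np.full((32, 32), 40.0), np.full((32, 32), 25.0),
                         aligned=True, corrected=False)
        out = subtract_background(pair, radius=6)
        np.testing.assert_allclose(out.para, 0.0)
        np.testing.assert_allclose(out.perp, 0.0)
        assert out.background_corrected

    def test_spike_amplitude_preserved_within_one_count(self):
        img = np.full((48, 48), 100.0)
        img[24, 24] = 400.0
        pair = make_pair(img, img.copy(), aligned=True, corrected=False)
        out = subtract_background(pair, radius=6)
        assert abs(out.para[24, 24] - 300.0) <= 1.0
        assert abs(out.para[10, 10]) <= 1.0

    def test_output_never_negative(self, rng):
        pair = make_pair(rng.integers(0, 300, (40, 40)).astype(float),
                         rng.integers(0, 300, (40, 40)).astype(float),
                         aligned=True, corrected=False)
        out = subtract_background(pair, radius=5)
        assert out.para.min() >= 0.0
        assert out.perp.min() >= 0.0

    def test_requires_alignment(self, rng):
        pair = make_pair(rng.random((16, 16)), aligned=False, corrected=False)
        with pytest.raises(ValueError):
            subtract_background(pair, radius=5)
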