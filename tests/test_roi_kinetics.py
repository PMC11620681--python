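import numpy as np
import pytest

from anisopipe.anisotropy import anisotropy_map
from anisopipe.errors import DataQualityError, InsufficientSignalError
from anisopipe.image_model import GFactor
from anisopipe.roi_kinetics import (
    KineticSeries,
    ROI,
    ROIMeasurement,
    assemble_series,
    compare_conditions,
    estimate_rate,
    final_concentration,
    rasterize_roi,
    read_rois_csv,
    roi_mean_anisotropy,
    rois_from_label_mask,
    write_rois_csv,
)

from conftest import make_pair


def square_roi(label="cell", x0=2.0, y0=2.0, size=10.0):
    return ROI(
        label=label,
        geometry=np.array(
            [[x0, y0], [x0 + size, y0], [x0 + size, y0 + size], [x0, y0 + size]]
        ),
    )


def uniform_map(r_value=0.25, shape=(20, 20), total=400.0):
    s = np.full(shape, total)
    para = s * (1 + 2 * r_value) / 3
    perp = s * (1 - r_value) / 3
    return anisotropy_map(make_pair(para, perp), GFactor(value=1.0), intensity_threshold=1)


def measurement(t, r, label="roi"):
    return ROIMeasurement(
        roi_label=label, timepoint_min=t, mean_r=r, sd_r=0.0,
        n_valid_pixels=100, mean_total_intensity=1e4,
    )


def series_from(times, values, treatment=0.0):
    return assemble_series(
        [measurement(t, v) for t, v in zip(times, values)],
        condition="test", treatment_time_min=treatment,
    )


class TestRoiMean:
    def test_uniform_map_any_roi(self):
        m = roi_mean_anisotropy(uniform_map(0.25), square_roi(), min_valid=10)
        assert m.mean_r == pytest.approx(0.25)
        assert m.sd_r == 0.0

    def test_two_population_hand_count(self):
        amap = uniform_map(0.2, shape=(20, 20))
        # overwrite 10 of the 40 pixels inside a 10x4 ROI with r = 0.4
        amap.r[2:6, 2:12] = 0.2
        amap.r[2, 2:12] = 0.4
        roi = ROI(label="r", geometry=np.array([[1.6, 1.6], [11.4, 1.6], [11.4, 5.4], [1.6, 5.4]]))
        member = rasterize_roi(roi, amap.r.shape)
        assert member.sum() == 40
        m = roi_mean_anisotropy(amap, roi, min_valid=10)
        assert m.mean_r == pytest.approx((30 * 0.2 + 10 * 0.4) / 40)

    def test_roi_over_masked_region_raises(self):
        amap = uniform_map(0.25)
        amap.valid[:] = False
        with pytest.raises(InsufficientSignalError):
            roi_mean_anisotropy(amap, square_roi(), min_valid=10)

    def test_vertex_order_and_translation_invariance(self):
        amap = uniform_map(0.25, shape=(40, 40))
        amap.r[:] = np.arange(40)[None, :] / 100.0
        roi = square_roi(x0=5, y0=5)
        reversed_roi = ROI(label="rev", geometry=roi.geometry[::-1])
        m1 = roi_mean_anisotropy(amap, roi, min_valid=10)
        m2 = roi_mean_anisotropy(amap, reversed_roi, min_valid=10)
        assert m1.mean_r == m2.mean_r
        # translate scene and ROI together
        shifted_map = uniform_map(0.25, shape=(40, 40))
        shifted_map.r[:] = np.roll(amap.r, 7, axis=1)
        shifted_roi = ROI(label="t", geometry=roi.geometry + [7.0, 0.0])
        m3 = roi_mean_anisotropy(shifted_map, shifted_roi, min_valid=10)
        assert m3.mean_r == pytest.approx(m1.mean_r)

    def test_nucleus_exclusion(self):
        amap = uniform_map(0.25, shape=(30, 30))
        roi = ROI(
            label="c",
            geometry=np.array([[2, 2], [22, 2], [22, 22], [2, 22]], dtype=float),
            exclude_geometry=np.array([[8, 8], [16, 8], [16, 16], [8, 16]], dtype=float),
        )
        member = rasterize_roi(roi, amap.r.shape)
        assert not member[12, 12]
        assert member[4, 4]

    def test_ensemble_estimator_weights_by_intensity(self):
        amap = uniform_map(0.2, shape=(20, 20))
        amap.r[2:12, 2:7] = 0.4
        amap.total_intensity[2:12, 2:7] = 800.0  # bright half
        roi = square_roi(x0=2, y0=2, size=10)
        pix = roi_mean_anisotropy(amap, roi, min_valid=10, estimator="pixelwise")
        ens = roi_mean_anisotropy(amap, roi, min_valid=10, estimator="ensemble")
        assert ens.mean_r > pix.mean_r  # bright pixels carry higher r here


class TestSeriesAssembly:
    def test_baseline_plus_five_posts(self):
        s = series_from([0, 5, 10, 15, 20, 25], [0.32, 0.30, 0.28, 0.27, 0.26, 0.25])
        assert len(s.measurements) == 6
        assert s.times.tolist() == [0, 5, 10, 15, 20, 25]

    def test_unordered_input_sorted(self):
        s = series_from([10, 0, 5], [0.28, 0.32, 0.30])
        assert s.times.tolist() == [0, 5, 10]

    def test_duplicate_timepoints_rejected(self):
        with pytest.raises(DataQualityError):
            series_from([0, 5, 5], [0.3, 0.29, 0.29])

    def test_missing_baseline_rejected(self):
        with pytest.raises(DataQualityError):
            series_from([5, 10, 15], [0.3, 0.29, 0.28])

    def test_inconsistent_interval_rejected(self):
        with pytest.raises(DataQualityError):
            series_from([0, 5, 13], [0.3, 0.29, 0.28])


class TestRateEstimation:
    def test_constant_series_zero_rate(self):
        s = series_from([0, 5, 10, 15], [0.3] * 4)
        for model in ("linear", "exponential"):
            est = estimate_rate(s, model)
            assert est.rate == 0.0
            assert est.se_rate == 0.0

    def test_linear_slope_exact(self):
        times = [0, 5, 10, 15, 20, 25]
        values = [0.30 - 0.002 * t for t in times]
        est = estimate_rate(series_from(times, values), "linear")
        assert est.rate == pytest.approx(-0.002, abs=1e-12)

    def test_linear_matches_closed_form_on_three_points(self, rng):
        t = np.array([5.0, 10.0, 15.0])
        y = rng.normal(0.3, 0.01, 3)
        s = series_from([0, 5, 10, 15], [0.31, *y])
        est = estimate_rate(s, "linear")
        # independent closed-form least squares on the post-treatment points
        slope = ((t - t.mean()) * (y - y.mean())).sum() / ((t - t.mean()) ** 2).sum()
        assert est.rate == pytest.approx(slope, abs=1e-12)

    def test_exponential_recovers_decay_constant(self):
        times = np.array([0, 5, 10, 15, 20, 25], dtype=float)
        values = 0.20 + 0.10 * np.exp(-0.05 * times)
        est = estimate_rate(series_from(times, values), "exponential")
        assert est.rate == pytest.approx(0.05, abs=1e-6)
        assert est.r_inf == pytest.approx(0.20, abs=1e-6)

    def test_monotone_decline_gives_negative_linear_rate(self):
        s = series_from([0, 5, 10, 15, 20], [0.32, 0.30, 0.29, 0.27, 0.26])
        assert estimate_rate(s, "linear").rate < 0
        assert estimate_rate(s, "exponential").rate > 0  # decay constant positive

    def test_too_few_post_points_rejected(self):
        s = series_from([0, 5, 10], [0.3, 0.29, 0.28])
        with pytest.raises(DataQualityError):
            estimate_rate(s, "linear")


class TestCompareConditions:
    @staticmethod
    def _rates(values):
        from anisopipe.roi_kinetics import RateEstimate

        return [
            RateEstimate(model="exponential", rate=v, intercept_or_r0=0.3,
                         se_rate=0.001, n_points=5)
            for v in values
        ]

    def test_identical_lists_difference_zero(self):
        a = self._rates([0.04, 0.05, 0.06])
        cmp = compare_conditions(a, a, n_boot=500, seed=1)
        assert cmp.difference == 0.0
        assert cmp.ci_low <= 0.0 <= cmp.ci_high

    def test_separated_conditions_ci_excludes_zero(self, rng):
        a = self._rates(rng.normal(0.06, 0.005, 20))
        b = self._rates(rng.normal(0.03, 0.005, 20))
        cmp = compare_conditions(a, b, n_boot=2000, seed=2)
        assert cmp.ci_low > 0.0

    def test_single_roi_list_rejected(self):
        with pytest.raises(DataQualityError):
            compare_conditions(self._rates([0.05]), self._rates([0.04, 0.05, 0.06]))


class TestFinalConcentration:
    def test_stock_mixture_worked_example(self):
        # 1 mL of 500 mM into 1 mL -> 250 mM
        assert final_concentration(500, 1.0, 1.0) == pytest.approx(250.0)

    def test_treatment_dilution_worked_example(self):
        # 100 uL of 250 mM mixture into 900 uL -> 25 mM
        assert final_concentration(250, 100, 900) == pytest.approx(25.0)

    def test_small_volume_limit(self):
        assert final_concentration(250, 1e-9, 1.0) == pytest.approx(0.0, abs=1e-6)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            final_concentration(250, 0.0, 1.0)


class TestRoiIO:
    def test_csv_round_trip_with_exclusion(self, tmp_path):
        rois = [
            ROI(
                label="cell01",
                geometry=np.array([[1.0, 2.0], [10.0, 2.0], [5.0, 9.0]]),
                exclude_geometry=np.array([[4.0, 4.0], [6.0, 4.0], [5.0, 6.0]]),
            ),
            ROI(label="cell02", geometry=np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 3.0]])),
        ]
        path = tmp_path / "rois.csv"
        write_rois_csv(rois, path)
        loaded = read_rois_csv(path)
        assert [r.label for r in loaded] == ["cell01", "cell02"]
        np.testing.assert_allclose(loaded[0].geometry, rois[0].geometry)
        np.testing.assert_allclose(loaded[0].exclude_geometry, rois[0].exclude_geometry)
        assert loaded[1].exclude_geometry is None

    def test_label_mask_rois(self):
        mask = np.zeros((10, 10), dtype=np.uint16)
        mask[1:4, 1:4] = 3
        mask[6:9, 6:9] = 7
        rois = rois_from_label_mask(mask)
        assert [r.label for r in rois] == ["roi3", "roi7"]
        m = rasterize_roi(rois[1], mask.shape, label_mask=mask)
        assert m.sum() == 9

    def test_polygon_needs_three_vertices(self):
        with pytest.raises(ValueError):
            ROI(label="bad", geometry=np.array([[0.0, 0.0], [1.0, 1.0]]))
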