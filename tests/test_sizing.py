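"""Circle detection and diameter distributions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import phantomlab as pl
from phantomlab.errors import ConfigurationError, ParameterError

from conftest import match_circles


def render_disks(centers, radii, shape=(256, 256), noise=0.02, seed=0):
    rng = np.random.default_rng(seed)
    img = np.full(shape, 0.15)
    for (cy, cx), r in zip(centers, radii):
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        img += 0.7 * np.clip(r + 0.5 - np.hypot(yy - cy, xx - cx), 0, 1)
    return np.clip(img + rng.normal(0, noise, shape), 0, 1)


class TestDetection:
    def test_blank_image_no_detections(self):
        det = pl.detect_circles(np.full((128, 128), 0.5), (5, 20))
        assert len(det) == 0

    def test_single_disk_found_accurately(self):
        img = render_disks([(100.0, 120.0)], [20.0])
        det = pl.detect_circles(img, (10, 35), sensitivity=0.9)
        assert len(det) == 1
        assert abs(det.radii[0] - 20.0) <= 2.0
        assert np.hypot(det.centers[0, 0] - 100, det.centers[0, 1] - 120) <= 2.0

    def test_many_disks_recall_precision(self):
        d = np.arange(10.0, 80.5, 1.0)
        nf = np.full(d.size, 1 / d.size)
        vf = nf * d**3
        flat = pl.SizeDistribution(d, nf, vf / vf.sum())
        img, truth = pl.synth_disk_image(
            flat, 60, (900, 900), scale_um_per_px=1.0, noise_sd=0.02, seed=4
        )
        det = pl.detect_circles(img, (4, 45), sensitivity=0.9)
        tp, fp, fn, rerr = match_circles(
            det, truth.truth["centers_px"], truth.truth["radii_px"]
        )
        assert tp / (tp + fn) >= 0.95
        assert tp / max(tp + fp, 1) >= 0.95

    def test_invalid_radius_range(self):
        with pytest.raises(ParameterError):
            pl.detect_circles(np.zeros((64, 64)), (20, 10))

    def test_invalid_sensitivity(self):
        with pytest.raises(ParameterError):
            pl.detect_circles(np.zeros((64, 64)), (5, 10), sensitivity=1.5)


class TestDistribution:
    def test_single_value_single_bin(self):
        dist = pl.build_distribution([10.0] * 7, 0.5)
        assert dist.number_fraction.max() == pytest.approx(1.0)
        assert dist.volume_fraction.max() == pytest.approx(1.0)

    def test_cubed_weighting_1_to_8(self):
        dist = pl.build_distribution([10.0, 10.0, 20.0, 20.0], 1.0)
        nz = dist.volume_fraction[dist.volume_fraction > 0]
        np.testing.assert_allclose(sorted(nz), [1 / 9, 8 / 9], rtol=1e-12)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        dist = pl.build_distribution(rng.uniform(1, 30, 500), 0.5)
        assert dist.number_fraction.sum() == pytest.approx(1.0, abs=1e-12)
        assert dist.volume_fraction.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_and_invalid_inputs(self):
        with pytest.raises(ParameterError):
            pl.build_distribution([], 0.5)
        with pytest.raises(ParameterError):
            pl.build_distribution([-1.0], 0.5)

    @given(
        st.lists(st.floats(min_value=1.0, max_value=50.0), min_size=2, max_size=60)
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_volume_mean_never_below_number_mean(self, diams):
        dist = pl.build_distribution(diams, 0.5)
        mean_n, _ = pl.summarize(dist, "number")
        mean_v, _ = pl.summarize(dist, "volume")
        assert mean_v >= mean_n - 1e-9


class TestSmoothing:
    def test_window_one_is_identity(self):
        dist = pl.build_distribution([5.0, 6.0, 6.0, 9.0], 0.5)
        out = pl.smooth_distribution(dist, 1)
        np.testing.assert_allclose(out.number_fraction, dist.number_fraction)

    def test_point_mass_spreads_over_window(self):
        d = np.arange(1.0, 8.0)
        nf = np.zeros(7)
        nf[3] = 1.0
        dist = pl.SizeDistribution(d, nf, nf.copy())
        out = pl.smooth_distribution(dist, 3)
        assert np.count_nonzero(out.number_fraction) == 3
        assert out.number_fraction.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(out.number_fraction[2:5], 1 / 3)

    def test_two_peaks_survive_narrow_window(self):
        # the number mode stays small-diameter and the volume mode
        # large-diameter after smoothing with a window << peak separation
        dist = pl.synth_size_distribution()
        out = pl.smooth_distribution(dist, 5)
        assert out.diameters_um[np.argmax(out.number_fraction)] < 6.0
        assert out.diameters_um[np.argmax(out.volume_fraction)] > 9.0

    def test_even_window_rejected(self):
        dist = pl.build_distribution([5.0, 9.0], 0.5)
        with pytest.raises(ParameterError):
            pl.smooth_distribution(dist, 4)

    def test_oversized_window_rejected(self):
        dist = pl.build_distribution([5.0, 5.4], 0.5)
        with pytest.raises(ParameterError):
            pl.smooth_distribution(dist, 99)


class TestSummarize:
    def test_point_mass(self):
        dist = pl.build_distribution([10.0] * 3, 0.5)
        mean, sd = pl.summarize(dist, "number")
        assert mean == pytest.approx(10.0, abs=0.25)  # bin-center quantization
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_volume_weighted_mean_10_20(self):
        d = np.array([10.0, 20.0])
        nf = np.array([0.5, 0.5])
        vf = nf * d**3
        dist = pl.SizeDistribution(d, nf, vf / vf.sum())
        mean, _ = pl.summarize(dist, "volume")
        assert mean == pytest.approx((10 + 20 * 8) / 9, rel=1e-12)

    def test_weighting_agrees_for_single_bin(self):
        dist = pl.build_distribution([12.0] * 5, 1.0)
        assert pl.summarize(dist, "number") == pl.summarize(dist, "volume")

    def test_unknown_weighting(self):
        dist = pl.build_distribution([12.0], 1.0)
        with pytest.raises(ParameterError):
            pl.summarize(dist, "mass")


class TestPixelsToUm:
    def test_scale_conversion(self):
        det = pl.DetectedCircles(
            np.array([[10.0, 10.0]]), np.array([10.0]), scale_um_per_px=0.5
        )
        np.testing.assert_allclose(pl.pixels_to_um(det), [10.0])

    def test_unit_scale(self):
        det = pl.DetectedCircles(
            np.array([[5.0, 5.0]]), np.array([7.0]), scale_um_per_px=1.0
        )
        np.testing.assert_allclose(pl.pixels_to_um(det), [14.0])

    def test_empty_detections(self):
        det = pl.DetectedCircles(np.empty((0, 2)), np.empty(0), scale_um_per_px=1.0)
        assert pl.pixels_to_um(det).size == 0

    def test_missing_scale_rejected(self):
        det = pl.DetectedCircles(np.array([[5.0, 5.0]]), np.array([7.0]))
        with pytest.raises(ConfigurationError):
            pl.pixels_to_um(det)
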