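import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucdyn.fluctuations import (
    circularity_fluctuation,
    detrend_area_series,
    edge_fluctuations,
    fluctuation_amplitude,
)

# Frozen oracle: areas = 100*(1 + 0.03*sin(2*pi*t/period)), 60 samples at
# 30 s spanning 5 periods, detrended by an independent np.polyfit cubic on
# the [-1, 1] axis; SD (ddof=1) of the percentage residuals.
SINE_ORACLE_SD = 2.0566799233290944


class TestDetrend:
    def test_exact_cubic_leaves_zero_residuals(self):
        t = np.arange(40) * 30.0
        areas = 5.0 + 0.01 * t - 2e-5 * t**2 + 1e-8 * t**3
        trend, resid = detrend_area_series(areas, t)
        assert np.abs(resid).max() < 1e-8 * np.abs(areas).max()

    def test_constant_series(self):
        t = np.arange(10) * 1.0
        trend, resid = detrend_area_series(np.full(10, 80.0), t)
        np.testing.assert_allclose(trend, 80.0)
        np.testing.assert_allclose(resid, 0.0, atol=1e-10)

    def test_sine_series_matches_independent_oracle(self):
        t = np.arange(60) * 30.0
        period = (t[-1] - t[0]) / 5
        areas = 100 * (1 + 0.03 * np.sin(2 * np.pi * t / period))
        _, amp_sd, _ = fluctuation_amplitude(areas, t)
        assert amp_sd == pytest.approx(SINE_ORACLE_SD, rel=1e-9)

    def test_raw_residuals_sum_to_zero(self):
        rng = np.random.default_rng(0)
        t = np.arange(30) * 30.0
        areas = 100 + rng.standard_normal(30)
        _, resid = detrend_area_series(areas, t)
        assert abs(resid.sum()) < 1e-8

    def test_too_short_series_rejected_with_minimum(self):
        with pytest.raises(ValueError, match="4"):
            detrend_area_series(np.ones(4), np.arange(4.0))

    def test_non_increasing_times_rejected(self):
        with pytest.raises(ValueError):
            detrend_area_series(np.ones(10), np.zeros(10))


class TestAmplitude:
    def test_variance_is_exactly_sd_squared(self):
        rng = np.random.default_rng(1)
        t = np.arange(60) * 30.0
        areas = 100 * (1 + 0.02 * rng.standard_normal(60))
        _, sd, var = fluctuation_amplitude(areas, t)
        assert var == sd**2

    def test_sd_two_gives_variance_four(self):
        # construct a series whose percentage-residual SD is exactly 2
        t = np.arange(60) * 30.0
        rng = np.random.default_rng(2)
        raw = rng.standard_normal(60)
        from numpy.polynomial import polynomial as P

        x = np.linspace(-1, 1, 60)
        resid = raw - P.polyval(x, P.polyfit(x, raw, 3))
        pct = resid / np.std(resid, ddof=1) * 2.0  # exact 2% residuals
        areas = 100.0 * (1 + pct / 100)
        _, sd, var = fluctuation_amplitude(areas, t)
        assert sd == pytest.approx(2.0, rel=1e-6)
        assert var == pytest.approx(4.0, rel=1e-6)

    @given(scale=st.floats(0.1, 10.0))
    @settings(max_examples=20, deadline=None)
    def test_scale_invariance_of_percentage_residuals(self, scale):
        rng = np.random.default_rng(3)
        t = np.arange(30) * 30.0
        areas = 90 * (1 + 0.03 * rng.standard_normal(30))
        _, sd1, _ = fluctuation_amplitude(areas, t)
        _, sd2, _ = fluctuation_amplitude(areas * scale, t)
        assert sd2 == pytest.approx(sd1, rel=1e-9)

    def test_added_cubic_drift_absorbed_into_trend(self):
        """An exact cubic added to the series moves the fitted trend, not the
        raw residuals."""
        rng = np.random.default_rng(4)
        t = np.arange(50) * 30.0
        base = 100 * (1 + 0.02 * rng.standard_normal(50))
        drift = 10 + 0.005 * t + 1e-6 * t**2 - 1e-10 * t**3
        _, resid1 = detrend_area_series(base, t)
        _, resid2 = detrend_area_series(base + drift, t)
        np.testing.assert_allclose(resid1, resid2, atol=1e-7)

    def test_frozen_nucleus_amplitude_below_quantization_floor(self, frozen_nucleus_movie):
        from nucdyn.segmentation import segment_movie

        _, movie, _, _ = frozen_nucleus_movie
        track = segment_movie(movie)
        _, sd, _ = fluctuation_amplitude(track.areas, track.times)
        assert sd < 0.3

    def test_generator_amplitude_recovered(self, nucleus_movie):
        from nucdyn.segmentation import segment_movie

        cfg, movie, _, truth = nucleus_movie
        track = segment_movie(movie)
        _, sd, _ = fluctuation_amplitude(track.areas, track.times)
        assert sd == pytest.approx(truth.true_amp_pct, rel=0.25)


def _cubic(t, y):
    x = 2 * (t - t[0]) / (t[-1] - t[0]) - 1
    return np.polyval(np.polyfit(x, y, 3), x)


class TestCircularity:
    def test_constant_series_has_zero_fluctuation(self):
        mu, sigma, s = circularity_fluctuation(np.full(10, 0.9))
        assert (mu, sigma, s) == (0.9, 0.0, 0.0)

    def test_two_point_hand_computation(self):
        mu, sigma, s = circularity_fluctuation(np.array([0.8, 1.0]))
        assert mu == pytest.approx(0.9)
        assert sigma == pytest.approx(0.1414213562, rel=1e-8)
        assert s == pytest.approx(15.7134840264, rel=1e-8)

    @given(c=st.floats(0.1, 10.0))
    @settings(max_examples=20, deadline=None)
    def test_cv_scale_invariance(self, c):
        series = np.array([0.7, 0.8, 0.95, 0.85])
        _, _, s1 = circularity_fluctuation(series)
        _, _, s2 = circularity_fluctuation(series * c)
        assert s2 == pytest.approx(s1, rel=1e-9)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            circularity_fluctuation(np.array([1.0, -1.0]))


class TestEdgeFluctuations:
    def square(self, x0, y0, side=10, shape=(40, 40)):
        m = np.zeros(shape, dtype=bool)
        m[y0 : y0 + side, x0 : x0 + side] = True
        return m

    def test_identical_masks_give_zero(self):
        masks = np.stack([self.square(5, 5)] * 4)
        np.testing.assert_allclose(edge_fluctuations(masks), 0.0)

    def test_disjoint_equal_masks_give_two(self):
        masks = np.stack([self.square(2, 2), self.square(25, 25)])
        ratio = edge_fluctuations(masks, align_centroids=False)
        assert ratio[0] == pytest.approx(2.0)

    def test_half_shift_gives_one_without_alignment(self):
        masks = np.stack([self.square(10, 10, side=10), self.square(15, 10, side=10)])
        ratio = edge_fluctuations(masks, align_centroids=False)
        assert ratio[0] == pytest.approx(1.0)

    def test_centroid_alignment_cancels_pure_translation(self):
        masks = np.stack([self.square(5, 5), self.square(12, 9)])
        ratio = edge_fluctuations(masks, align_centroids=True)
        assert ratio[0] == pytest.approx(0.0)

    def test_bad_lag_rejected(self):
        masks = np.stack([self.square(5, 5)] * 3)
        with pytest.raises(ValueError):
            edge_fluctuations(masks, lag=3)
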