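import dataclasses

import numpy as np
import pytest

from nucdyn.chromatin import (
    crop_window,
    intensity_correlation,
    normalize_intensity,
    window_bounds,
)

from conftest import disc_mask, small_nucleus_config


def brute_force_pearson(a, b):
    """Naive double-loop implementation of the pixelwise coefficient."""
    a_ave = sum(a[i, j] for i in range(a.shape[0]) for j in range(a.shape[1])) / a.size
    b_ave = sum(b[i, j] for i in range(b.shape[0]) for j in range(b.shape[1])) / b.size
    num = 0.0
    va = vb = 0.0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            num += (a[i, j] - a_ave) * (b[i, j] - b_ave)
            va += (a[i, j] - a_ave) ** 2
            vb += (b[i, j] - b_ave) ** 2
    return num / (a.size * np.sqrt(va / a.size) * np.sqrt(vb / b.size))


class TestNormalize:
    def test_uniform_disc_gives_reciprocal_count(self):
        mask = disc_mask()
        frame = np.where(mask, 5.0, 0.0)
        norm = normalize_intensity(frame, mask)
        n = mask.sum()
        np.testing.assert_allclose(norm[mask], 1.0 / n)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        frame = rng.uniform(1, 10, size=(32, 32))
        mask = disc_mask((32, 32), (16, 16), 10)
        np.testing.assert_allclose(
            normalize_intensity(frame, mask), normalize_intensity(frame * 7.3, mask)
        )

    def test_in_mask_sum_is_one(self):
        rng = np.random.default_rng(1)
        frame = rng.uniform(0, 100, size=(40, 40))
        mask = disc_mask((40, 40), (20, 20), 12)
        assert normalize_intensity(frame, mask)[mask].sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            normalize_intensity(np.ones((8, 8)), np.zeros((8, 8), dtype=bool))


class TestCropWindow:
    def test_centered_window_coordinates(self):
        frame = np.arange(256 * 256).reshape(256, 256)
        assert window_bounds(frame.shape, (128, 128), 100) == (78, 178, 78, 178)
        assert crop_window(frame, (128, 128)).shape == (100, 100)

    def test_window_clamped_at_edge(self):
        frame = np.zeros((256, 256))
        assert window_bounds(frame.shape, (10, 128), 100) == (78, 178, 0, 100)
        assert window_bounds(frame.shape, (250, 250), 100) == (156, 256, 156, 256)

    def test_frame_smaller_than_window_rejected(self):
        with pytest.raises(ValueError):
            window_bounds((64, 64), (32, 32), 100)


class TestIntensityCorrelation:
    def test_identical_frames_give_one(self):
        rng = np.random.default_rng(2)
        frame = rng.uniform(size=(20, 20))
        res = intensity_correlation(np.stack([frame] * 5))
        np.testing.assert_allclose(res.per_frame_c, 1.0, atol=1e-12)
        assert res.c_mean == pytest.approx(1.0)

    def test_shuffled_pixels_decorrelate(self):
        rng = np.random.default_rng(3)
        frame = rng.uniform(size=(100, 100))
        shuffled = rng.permutation(frame.ravel()).reshape(frame.shape)
        res = intensity_correlation(np.stack([frame, shuffled]))
        assert abs(res.per_frame_c[0]) < 3 / np.sqrt(frame.size)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(4)
        series = rng.uniform(size=(3, 16, 16))
        res = intensity_correlation(series)
        for n in range(1, 3):
            assert res.per_frame_c[n - 1] == pytest.approx(
                brute_force_pearson(series[0], series[n]), abs=1e-10
            )

    def test_affine_intensity_change_invariance(self):
        rng = np.random.default_rng(5)
        a, b = rng.uniform(size=(2, 24, 24))
        r1 = intensity_correlation(np.stack([a, b])).per_frame_c[0]
        r2 = intensity_correlation(np.stack([a, 3.0 * b + 11.0])).per_frame_c[0]
        assert r2 == pytest.approx(r1, abs=1e-12)

    def test_zero_variance_frame_skipped_with_flag(self):
        rng = np.random.default_rng(6)
        a = rng.uniform(size=(10, 10))
        series = np.stack([a, np.full((10, 10), 0.5), a * 2])
        res = intensity_correlation(series)
        assert res.skipped[0] and not res.skipped[1]
        assert res.c_mean == pytest.approx(1.0)


class TestGeneratorLimits:
    @staticmethod
    def _c_mean(turnover, seed, frames=16, window=40):
        from nucdyn.chromatin import chromatin_correlation
        from nucdyn.segmentation import segment_movie
        from nucdyn.simulate import generate_nucleus_movie

        cfg = small_nucleus_config(
            seed=seed, frames=frames, texture_turnover=turnover,
            drift_speed=0.0, area_fluct_target=0.0,
            noise_gain=1e9, read_noise_sd=0.0,
        )
        movie, _, _ = generate_nucleus_movie(cfg)
        track = segment_movie(movie)
        return chromatin_correlation(movie, track, size=window).c_mean

    def test_static_texture_gives_unit_correlation(self):
        assert self._c_mean(0.0, seed=1) == pytest.approx(1.0, abs=1e-6)

    def test_full_turnover_decorrelates(self):
        assert abs(self._c_mean(1.0, seed=1)) < 0.25

    def test_c_mean_decreases_with_turnover(self):
        """Short movies keep the compared lags small, where the geometric
        decay of the texture autocorrelation separates the turnover levels
        well above the windowing noise floor."""
        means = []
        for turnover in (0.0, 0.25, 0.5, 0.75, 1.0):
            vals = [self._c_mean(turnover, seed=s, frames=6, window=48) for s in range(8)]
            means.append(np.mean(vals))
        assert all(a > b for a, b in zip(means, means[1:]))
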