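"""Generator self-consistency: every truth record must be verifiable by
independent re-computation, and fixed seeds must reproduce bit-identical
output."""

import numpy as np
import pytest

from nucdyn import simulate
from nucdyn.simulate import (
    SyntheticConfig,
    condition_preset,
    cytoskeleton_preset,
    draw_population_params,
    generate_brightfield_movie,
    generate_cytoskeleton_zstack,
    generate_nucleus_movie,
    generate_population,
    polyline_length,
)

from conftest import small_nucleus_config


class TestPresets:
    def test_reported_condition_amplitudes(self):
        assert condition_preset("unstrained", "1h").area_fluct_target == 3.0
        assert condition_preset("strained", "24h").area_fluct_target == 2.0
        assert condition_preset("strained", "48h").area_fluct_target == 2.0
        assert condition_preset("unstrained", "48h").area_fluct_target == 2.0

    def test_migration_presets_encode_fifty_percent_reduction_at_1h(self):
        un = condition_preset("unstrained", "1h", modality="brightfield")
        st = condition_preset("strained", "1h", modality="brightfield")
        assert un.mean_path_um / un.duration_min * 60 == pytest.approx(60.0)
        assert st.drift_speed == pytest.approx(0.5 * un.drift_speed)

    def test_unknown_label_lists_valid_labels(self):
        with pytest.raises(ValueError) as err:
            condition_preset("strained", "96h")
        msg = str(err.value)
        assert msg.count("strained_") >= 3 and "unstrained_1h" in msg

    def test_cytoskeleton_preset_ratios(self):
        un = cytoskeleton_preset("unstrained", "24h")
        st = cytoskeleton_preset("strained", "24h")
        assert st["tubulin"] / un["tubulin"] == pytest.approx(1.70)
        assert st["actin"] / un["actin"] == pytest.approx(0.85)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("frames", 3),
            ("area_fluct_target", -1.0),
            ("texture_turnover", 1.5),
            ("coupling_rho", -2.0),
            ("pixel_size", 0.0),
        ],
    )
    def test_invalid_config_rejected_before_simulation(self, field, value):
        cfg = small_nucleus_config()
        setattr(cfg, field, value)
        with pytest.raises(ValueError):
            generate_nucleus_movie(cfg)

    def test_seed_required(self):
        cfg = small_nucleus_config()
        cfg.seed = None
        with pytest.raises(ValueError, match="seed"):
            generate_nucleus_movie(cfg)


class TestNucleusMovie:
    def test_same_seed_is_bit_identical(self):
        cfg = small_nucleus_config(seed=3)
        m1, k1, t1 = generate_nucleus_movie(cfg)
        m2, k2, t2 = generate_nucleus_movie(small_nucleus_config(seed=3))
        np.testing.assert_array_equal(m1.frames, m2.frames)
        np.testing.assert_array_equal(k1, k2)
        assert t1.true_trajectory_len == t2.true_trajectory_len

    def test_frozen_dynamics_give_identical_frames_up_to_noise(self):
        cfg = small_nucleus_config(
            seed=1, area_fluct_target=0.0, drift_speed=0.0, texture_turnover=0.0,
            noise_gain=1e9, read_noise_sd=0.0,
        )
        movie, masks, truth = generate_nucleus_movie(cfg)
        assert truth.true_amp_pct == 0.0
        assert truth.true_trajectory_len == 0.0
        # residual shot noise at this gain has sd ~4e-4 intensity units
        np.testing.assert_allclose(
            movie.frames[1:], np.broadcast_to(movie.frames[0], movie.frames[1:].shape),
            atol=5e-3,
        )
        assert (masks[1:] == masks[:1]).all()

    def test_truth_amplitude_matches_independent_cubic_fit(self, nucleus_movie):
        """Oracle: direct polynomial regression on the emitted truth series."""
        cfg, movie, masks, truth = nucleus_movie
        t = movie.times
        x = 2 * (t - t[0]) / (t[-1] - t[0]) - 1
        coef = np.polyfit(x, truth.true_area_series, 3)
        trend = np.polyval(coef, x)
        pct = (truth.true_area_series - trend) / trend * 100
        assert np.std(pct, ddof=1) == pytest.approx(truth.true_amp_pct, rel=1e-6)
        assert truth.true_amp_pct == cfg.area_fluct_target

    def test_truth_trajectory_is_polyline_length_of_centroids(self, nucleus_movie):
        _, _, _, truth = nucleus_movie
        seg = np.sqrt((np.diff(truth.true_centroid_series, axis=0) ** 2).sum(axis=1))
        assert seg.sum() == pytest.approx(truth.true_trajectory_len, rel=1e-12)

    def test_mask_boundary_keeps_border_margin(self, nucleus_movie):
        _, _, masks, _ = nucleus_movie
        assert not masks[:, :2].any() and not masks[:, -2:].any()
        assert not masks[:, :, :2].any() and not masks[:, :, -2:].any()


class TestPopulation:
    def test_population_smaller_than_two_rejected(self):
        with pytest.raises(ValueError):
            draw_population_params(small_nucleus_config(seed=0), 1)

    def test_uncoupled_population_is_independent(self):
        n = 2000
        cfg = small_nucleus_config(seed=2, coupling_rho=0.0)
        params = draw_population_params(cfg, n)
        r = np.corrcoef(params["amp_pct"], params["traj_len_um"])[0, 1]
        assert abs(r) < 3 / np.sqrt(n)

    def test_latent_correlation_matches_coupling_rho(self):
        """Oracle: correlation of the generator's own latent draws."""
        cfg = small_nucleus_config(seed=4, coupling_rho=0.63)
        params = draw_population_params(cfg, 1000)
        r_latent = np.corrcoef(params["latent_amp"], params["latent_traj"])[0, 1]
        assert r_latent == pytest.approx(0.63, abs=3 / np.sqrt(1000))
        assert params["amp_pct"].mean() == pytest.approx(cfg.area_fluct_target, rel=0.05)

    def test_child_seeds_are_order_independent(self):
        cfg = small_nucleus_config(seed=9)
        a = draw_population_params(cfg, 5)
        b = draw_population_params(cfg, 10)
        assert list(a["seed"]) == list(b["seed"][:5])

    def test_rendered_population_truths_match_params(self):
        cfg = small_nucleus_config(seed=6)
        cells, params = generate_population(cfg, 3)
        for (_, _, truth), amp in zip(cells, params["amp_pct"]):
            assert truth.true_amp_pct == pytest.approx(amp, rel=1e-9)


class TestBrightfield:
    def test_zero_drift_gives_zero_length_and_static_projection(self):
        cfg = condition_preset("unstrained", "1h", modality="brightfield")
        cfg.seed, cfg.drift_speed, cfg.frames = 1, 0.0, 20
        movie, truth = generate_brightfield_movie(cfg, 3)
        assert (truth["true_traj_len_um"] == 0).all()
        proj = np.min(movie.frames, axis=0)
        # projection differs from a single frame only by noise
        assert np.median(np.abs(proj - movie.frames[0])) < 4 * cfg.read_noise_sd

    def test_straight_line_polyline_arithmetic(self):
        pts = np.column_stack([np.arange(100.0), np.zeros(100)])
        assert polyline_length(pts) == pytest.approx(99.0)

    def test_population_mean_path_length(self):
        cfg = condition_preset("unstrained", "1h", modality="brightfield")
        cfg.seed, cfg.frames = 2, 10
        lengths = []
        for i in range(20):
            cfg.seed = 100 + i
            _, truth = generate_brightfield_movie(cfg, 4)
            lengths.extend(truth["true_traj_len_um"])
        # nominal mean scaled to the 10-frame duration
        expect = cfg.mean_path_um
        se = np.std(lengths, ddof=1) / np.sqrt(len(lengths))
        assert np.mean(lengths) == pytest.approx(expect, abs=3 * se + 0.02 * expect)

    def test_field_too_small_rejected(self):
        cfg = condition_preset("unstrained", "1h", modality="brightfield")
        cfg.seed, cfg.image_size = 0, (32, 32)
        with pytest.raises(ValueError, match="too small"):
            generate_brightfield_movie(cfg, 9)


class TestZStack:
    def test_equal_densities_give_equal_normalized_intensity(self):
        from nucdyn.cytoskeleton import channel_normalized_intensity

        a, b, _ = generate_cytoskeleton_zstack(120.0, 120.0, seed=0)
        ra = channel_normalized_intensity(a).normalized
        rb = channel_normalized_intensity(b).normalized
        assert ra == pytest.approx(rb, rel=0.02)

    def test_zero_noise_recovers_density_exactly(self):
        from nucdyn.cytoskeleton import channel_normalized_intensity

        a, _, truth = generate_cytoskeleton_zstack(80.0, 80.0, seed=1, noise_sd=0.0)
        res = channel_normalized_intensity(a)
        assert res.normalized == pytest.approx(80.0, rel=1e-6)
        assert res.volume == pytest.approx(truth["actin"]["volume_um3"], rel=1e-9)

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            generate_cytoskeleton_zstack(-1.0, 10.0)

    def test_truth_density_ratio_propagates(self):
        _, _, truth = generate_cytoskeleton_zstack(100.0, 170.0, seed=2)
        ratio = truth["tubulin"]["density"] / truth["actin"]["density"]
        assert (ratio - 1) * 100 == pytest.approx(70.0)
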