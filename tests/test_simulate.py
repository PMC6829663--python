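"""Simulator: rendering, noise statistics, kinetics and determinism."""

import json

import numpy as np
import pytest

import tirfgran as tg
from tirfgran.simulate import render_frame


def noiseless_cfg(**kw):
    kw.setdefault("poisson_noise", False)
    kw.setdefault("read_noise_sd", 0.0)
    return tg.SimConfig(**kw)


class TestMovieRendering:
    def test_noiseless_spot_maximum_at_injected_center(self):
        cfg = noiseless_cfg(image_shape=(31, 31), n_frames=1, seed=3)
        res = tg.ResidenceModel(confinement_sd=0.0)
        movie, gt = tg.simulate_movie(cfg, res, n_granules=0, n_initial=1)
        x, y = gt.spots[0].trajectory[0]
        row, col = np.unravel_index(movie[0].argmax(), movie[0].shape)
        assert (row, col) == (round(y), round(x))

    def test_degenerate_mixture_all_docked(self):
        cfg = tg.SimConfig(image_shape=(64, 64), n_frames=40, seed=1)
        res = tg.ResidenceModel(p_dock=1.0, dock_residence=120.0)
        _, gt = tg.simulate_movie(cfg, res, n_granules=8)
        assert gt.kinds() == ["docked"] * 8

    def test_fixed_seed_gives_bit_identical_output(self, tmp_path):
        cfg = tg.SimConfig(image_shape=(48, 48), n_frames=20, seed=7)
        res = tg.ResidenceModel()
        m1, gt1 = tg.simulate_movie(cfg, res, n_granules=5)
        m2, gt2 = tg.simulate_movie(cfg, res, n_granules=5)
        assert np.array_equal(m1, m2)
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        gt1.to_json(p1)
        gt2.to_json(p2)
        assert p1.read_text() == p2.read_text()

    def test_noiseless_spot_mean_over_99pct_support(self):
        # mean over the 99% PSF support disk ~ amplitude * 2 pi sigma^2 * 0.99 / area
        sigma, amp = 1.3, 100.0
        frame = render_frame((41, 41), 0.0, [(20.0, 20.0)], [amp], sigma)
        r99 = sigma * np.sqrt(2 * np.log(100))
        yy, xx = np.mgrid[0:41, 0:41]
        disk = (xx - 20.0) ** 2 + (yy - 20.0) ** 2 <= r99**2
        measured_mean = frame[disk].mean()
        expected_mean = amp * 2 * np.pi * sigma**2 / disk.sum()
        assert measured_mean == pytest.approx(expected_mean, rel=0.02)

    def test_poisson_noise_variance_matches_mean(self):
        # static empty scene, Poisson only: variance tracks the mean
        cfg = tg.SimConfig(image_shape=(16, 16), n_frames=1000,
                           read_noise_sd=0.0, background_level=80.0, seed=11)
        movie, _ = tg.simulate_movie(cfg, tg.ResidenceModel(), n_granules=0)
        movie = movie.astype(float)
        mean_of_means = movie.mean(axis=0).mean()
        mean_of_vars = movie.var(axis=0, ddof=1).mean()
        assert mean_of_vars == pytest.approx(mean_of_means, rel=0.05)

    def test_overflow_config_rejected(self):
        with pytest.raises(ValueError, match="overflow"):
            tg.SimConfig(background_level=60000, spot_amplitude=10000)


class TestFusionMovies:
    def test_zero_events_gives_empty_ground_truth(self):
        cfg = tg.SimConfig(image_shape=(64, 64), n_frames=30, seed=5)
        _, gt = tg.simulate_fusion_movie(cfg, n_events=0, n_distractors=4)
        assert gt.fusion_events == []

    def test_event_count_and_intensity_collapse(self, fusion_movie30):
        cfg, movie, gt = fusion_movie30
        assert len(gt.fusion_events) == 30
        bg = cfg.background_level
        by_id = {s.id: s for s in gt.spots}
        for ev in gt.fusion_events:
            x, y = by_id[ev.id].trajectory[0]
            r, c = round(y), round(x)
            patch = movie[:, r - 1:r + 2, c - 1:c + 2].mean(axis=(1, 2)) - bg
            pre = patch[max(0, ev.frame - 6):ev.frame - 1].mean()
            post = patch[ev.frame + 2:ev.frame + 7].mean()
            assert pre > 3 * abs(post)

    def test_single_frame_loss_completes_between_consecutive_frames(self):
        cfg = noiseless_cfg(image_shape=(96, 96), n_frames=40, seed=9)
        movie, gt = tg.simulate_fusion_movie(cfg, n_events=4, loss_frames=1,
                                             n_distractors=0, confinement_sd=0.0)
        by_id = {s.id: s for s in gt.spots}
        for ev in gt.fusion_events:
            x, y = by_id[ev.id].trajectory[0]
            r, c = round(y), round(x)
            before = float(movie[ev.frame - 1, r, c]) - cfg.background_level
            at = float(movie[ev.frame, r, c]) - cfg.background_level
            assert before > 0.8 * cfg.spot_amplitude * np.exp(-0.5)  # near-center pixel
            assert at < 1.0

    def test_too_many_events_for_the_field_rejected(self):
        cfg = tg.SimConfig(image_shape=(40, 40), n_frames=30, seed=2)
        with pytest.raises(ValueError, match="place"):
            tg.simulate_fusion_movie(cfg, n_events=500)


class TestCropPairs:
    def test_unbound_probe_has_no_central_narrow_component(self):
        ch1, ch2, _ = tg.simulate_crop_pair(
            3, granule_amplitude=200.0, bound_fraction=0.0, wide_bg_sigma=8.0,
            seed=0, noise=False)
        crop = ch2[0]
        # center value explained by the wide component alone: smooth, no spike
        center = crop[14:16, 14:16].mean()
        ring = crop[11, 14]  # ~3.7 px off-center: narrow component would be gone here
        assert center < 1.15 * ring

    def test_fully_bound_probe_is_scaled_marker_plus_baseline(self):
        baseline = 50.0
        ch1, ch2, _ = tg.simulate_crop_pair(
            2, granule_amplitude=200.0, bound_fraction=1.0, wide_bg_sigma=8.0,
            seed=0, baseline=baseline, noise=False)
        a = (ch2[0] - baseline) / np.maximum(ch1[0] - baseline, 1e-12)
        center = ch1[0] > baseline + 1.0  # where the marker has signal
        assert np.allclose(a[center], a[center].flat[0], rtol=1e-6)

    def test_reproducible_pairs(self):
        kw = dict(granule_amplitude=150.0, bound_fraction=0.5, wide_bg_sigma=6.0, seed=4)
        a1, b1, _ = tg.simulate_crop_pair(20, **kw)
        a2, b2, _ = tg.simulate_crop_pair(20, **kw)
        assert a1.shape[0] == 20
        assert np.array_equal(a1, a2) and np.array_equal(b1, b2)

    def test_bound_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            tg.simulate_crop_pair(5, 100.0, 1.5, 8.0, seed=0)


class TestFootprintTraces:
    def test_zero_amplitude_noiseless_trace_is_constant(self):
        tr = tg.simulate_footprint_trace(100.0, 30.0, 0.0, 60.0, 20.0, 0.0)
        assert np.allclose(tr.raw, 100.0)

    def test_plateau_reaches_step_amplitude(self):
        tr = tg.simulate_footprint_trace(100.0, 10.0, 80.0, 120.0, 20.0, 0.0,
                                         rise_tau=2.0)
        t_off = tr.stimulus_window[1]
        value_at_off = tr.raw[np.searchsorted(tr.time, t_off) - 1]
        assert value_at_off == pytest.approx(180.0, rel=0.01)

    def test_decay_halves_every_tau_ln2(self):
        tau = 10.0
        tr = tg.simulate_footprint_trace(100.0, 10.0, 80.0, 60.0, tau, 0.0, dt=0.1)
        t_off = tr.stimulus_window[1]
        above = tr.raw - 100.0
        t0 = t_off + 5.0
        v0 = np.interp(t0, tr.time, above)
        v1 = np.interp(t0 + tau * np.log(2), tr.time, above)
        assert v1 == pytest.approx(v0 / 2, rel=1e-3)

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError):
            tg.simulate_footprint_trace(100.0, 10.0, 80.0, 60.0, -5.0, 0.0)
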