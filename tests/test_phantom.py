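"""Synthetic fetal scene and acquisition simulator."""

import numpy as np
import pytest

from fetalcine.moco import mutual_information
from fetalcine.phantom import (PhantomConfig, SceneGeometry,
                               generate_motion_traces, generate_rr_series,
                               ground_truth_masks, render_scene,
                               simulate_acquisition)
from fetalcine.trajectory import SpiralProtocol


class TestRRSeries:
    def test_zero_sd_is_constant(self):
        rr = generate_rr_series(10, 433.0, 0.0, seed=1)
        assert np.all(rr == 433.0)

    def test_reproducible_under_seed(self):
        a = generate_rr_series(50, 433.0, 10.0, seed=7)
        b = generate_rr_series(50, 433.0, 10.0, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_sample_mean_near_target(self):
        rr = generate_rr_series(400, 433.0, 10.0, seed=2)
        assert abs(rr.mean() - 433.0) < 2.0  # ~ 4 sd / sqrt(n)

    def test_truncation_bounds(self):
        rr = generate_rr_series(1000, 433.0, 24.0, seed=3)
        assert rr.min() >= 433.0 - 3 * 24.0 and rr.max() <= 433.0 + 3 * 24.0

    def test_mean_below_floor_rejected(self):
        with pytest.raises(ValueError):
            generate_rr_series(5, 150.0, 5.0)


class TestMotionTraces:
    def test_no_motion_is_identically_zero(self):
        cfg = PhantomConfig(resp_amp_mm=0.0, noise_sd=0.0)
        trace, _ = generate_motion_traces(cfg, 10000.0)
        t = np.linspace(0, 10000, 100)
        np.testing.assert_array_equal(trace(t), np.zeros((100, 2)))

    def test_dominant_frequency_matches_respiration(self):
        cfg = PhantomConfig(resp_amp_mm=2.5, resp_period_s=4.0)
        trace, _ = generate_motion_traces(cfg, 32000.0)
        t = np.arange(0, 32000.0, 20.0)
        x = trace(t)[:, 0]
        power = np.abs(np.fft.rfft(x - x.mean()))
        freqs = np.fft.rfftfreq(t.size, d=0.020)  # seconds
        peak = freqs[np.argmax(power)]
        assert abs(peak - 0.25) <= freqs[1]  # one bin of 1/4 Hz

    def test_peak_to_peak_range(self):
        cfg = PhantomConfig(resp_amp_mm=2.5, resp_period_s=4.0,
                            resp_axis_deg=0.0)
        trace, _ = generate_motion_traces(cfg, 8000.0)
        t = np.linspace(0, 8000, 4001)
        assert np.ptp(trace(t)[:, 0]) == pytest.approx(5.0, abs=1e-3)

    def test_gross_step_is_cumulative(self):
        cfg = PhantomConfig(resp_amp_mm=0.0,
                            gross_events=((1000.0, (2.0, -1.0)),))
        trace, _ = generate_motion_traces(cfg, 5000.0)
        np.testing.assert_allclose(trace(500.0), (0.0, 0.0))
        np.testing.assert_allclose(trace(1500.0), (2.0, -1.0))

    def test_window_outside_scan_rejected(self):
        cfg = PhantomConfig(throughplane_windows=((0.0, 20000.0),))
        with pytest.raises(ValueError):
            generate_motion_traces(cfg, 10000.0)


class TestRenderScene:
    N, FOV = 96, 240.0

    def lv_area(self, cfg, phase):
        img = render_scene(cfg, self.N, self.FOV, phase)
        g = cfg.geometry
        return np.sum(img > 0.8 * g.blood_intensity)

    def test_end_diastole_larger_than_end_systole(self):
        cfg = PhantomConfig()
        assert self.lv_area(cfg, 0.0) > self.lv_area(cfg, 0.35)

    def test_translation_moves_centroid(self):
        cfg = PhantomConfig()
        g = cfg.geometry
        px = self.FOV / self.N
        a = render_scene(cfg, self.N, self.FOV, 0.0, (0.0, 0.0))
        b = render_scene(cfg, self.N, self.FOV, 0.0, (3.0, 4.0))
        # intensity-weighted centroid of the blood signal: soft edges give
        # subpixel precision that a binary mask cannot
        def centroid(img):
            w = np.clip(img - g.myo_intensity, 0.0, None)
            iy, ix = np.mgrid[0:self.N, 0:self.N]
            return np.array([np.sum(w * ix), np.sum(w * iy)]) / w.sum() * px
        d = centroid(b) - centroid(a)
        assert abs(d[0] - 3.0) < 0.1 and abs(d[1] - 4.0) < 0.1

    def test_throughplane_lowers_mutual_information(self):
        cfg = PhantomConfig()
        _, roi = ground_truth_masks(cfg, self.N, self.FOV)
        base = render_scene(cfg, self.N, self.FOV, 0.1)
        other = render_scene(cfg, self.N, self.FOV, 0.6, (1.0, -0.5))
        corr = render_scene(cfg, self.N, self.FOV, 0.1, throughplane=True)
        mi_clean = mutual_information(base, other, roi)
        mi_corr = mutual_information(base, corr, roi)
        assert mi_corr < mi_clean

    def test_invalid_phase_rejected(self):
        with pytest.raises(ValueError):
            render_scene(PhantomConfig(), self.N, self.FOV, 1.5)


class TestSimulateAcquisition:
    def test_scan_duration_matches_protocol(self, small_protocol):
        cfg = PhantomConfig(n_arms=250, noise_sd=0.0, seed=0)
        ds, _ = simulate_acquisition(small_protocol, cfg)
        tr = small_protocol.tr_ms
        assert ds.timestamps_ms[-1] + tr == pytest.approx(250 * tr)
        assert 250 * tr == pytest.approx(1425.0)  # 5.7 ms TR

    def test_noiseless_static_samples_equal_forward(self, static_dataset):
        from fetalcine.encoding import NonuniformFourier
        ds, gt, cfg = static_dataset
        prot = ds.protocol
        op = NonuniformFourier(prot.grid_size,
                               ds.trajectory.coords * prot.res_mm,
                               width=6)  # simulator kernel
        scene = render_scene(cfg, prot.grid_size, prot.fov_mm, 0.0)
        y = op.forward(scene.astype(complex))
        np.testing.assert_allclose(ds.samples.ravel(), y, atol=1e-9)

    def test_trigger_rr_consistency(self, small_protocol):
        cfg = PhantomConfig(n_arms=400, seed=5)
        _, gt = simulate_acquisition(small_protocol, cfg)
        np.testing.assert_allclose(np.diff(gt.trigger_times_ms),
                                   gt.rr_series_ms, atol=1e-9)
        assert np.all(np.diff(gt.trigger_times_ms) > 0)

    def test_corrupted_mask_matches_schedule(self, small_protocol):
        tr = small_protocol.tr_ms
        win = (100 * tr, 150 * tr)
        cfg = PhantomConfig(n_arms=300, throughplane_windows=(win,), seed=5)
        ds, gt = simulate_acquisition(small_protocol, cfg)
        expected = (ds.timestamps_ms >= win[0]) & (ds.timestamps_ms < win[1])
        np.testing.assert_array_equal(gt.corrupted_arm_mask, expected)

    def test_noise_level_in_corner_of_gridded_recon(self, small_protocol):
        """Corner-ROI noise sd of the gridding recon matches a noise-only
        prediction within 15% (Monte-Carlo over 20 draws)."""
        from fetalcine.encoding import NonuniformFourier
        from fetalcine.trajectory import default_trajectory
        sd = 0.5
        cfg0 = PhantomConfig(n_arms=144, noise_sd=sd, rr_sd_ms=0.0,
                             resp_amp_mm=0.0, seed=0)
        traj = default_trajectory(small_protocol, 144)
        n = small_protocol.grid_size
        op = NonuniformFourier(n, traj.coords * small_protocol.res_mm)
        w = traj.dcf.ravel()
        scale = None
        corner = (slice(2, 12), slice(2, 12))
        rng = np.random.default_rng(42)
        noise_sds = []
        for _ in range(20):
            noise = sd * (rng.standard_normal(w.size)
                          + 1j * rng.standard_normal(w.size))
            img = op.adjoint(w * noise)
            noise_sds.append(np.abs(img[corner]).std())
        measured = np.mean(noise_sds)
        # prediction: linear propagation of unit-variance noise, scaled by sd
        unit = []
        for _ in range(20):
            noise = (rng.standard_normal(w.size)
                     + 1j * rng.standard_normal(w.size))
            unit.append(np.abs(op.adjoint(w * noise)[corner]).std())
        predicted = sd * np.mean(unit)
        assert abs(measured - predicted) / predicted < 0.15

    def test_ground_truth_cine_periodic_and_rr_independent(self, small_protocol):
        cfg1 = PhantomConfig(n_arms=200, rr_sd_ms=0.0, seed=1, noise_sd=0.0)
        cfg2 = PhantomConfig(n_arms=200, rr_sd_ms=0.0, seed=2, noise_sd=0.0)
        _, g1 = simulate_acquisition(small_protocol, cfg1)
        _, g2 = simulate_acquisition(small_protocol, cfg2)
        np.testing.assert_array_equal(g1.cine, g2.cine)
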