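"""Metric-optimized gating: triggers, phase binning, entropy, optimization."""

import numpy as np
import pytest

from fetalcine.containers import ImageSeries, Roi
from fetalcine.mog import (image_entropy, mog_optimize, phase_assignment,
                           resort_cine, triggers_from_rr)


class TestTriggers:
    def test_cumulative_sum(self):
        np.testing.assert_allclose(triggers_from_rr(0.0, [433.0, 433.0]),
                                   [0.0, 433.0, 866.0])

    def test_beat_count_over_scan(self):
        rr = np.full(40, 433.0)
        trig = triggers_from_rr(0.0, rr)
        complete = np.sum(trig[1:] <= 14250.0)
        assert complete == 14250 // 433 == 32

    def test_nominal_phase_duration(self):
        # mean RR 433 ms over 20 phases ~ 22 ms temporal resolution
        assert round(433.0 / 20) == 22

    def test_nonpositive_rr_rejected(self):
        with pytest.raises(ValueError):
            triggers_from_rr(0.0, [433.0, -1.0])


class TestPhaseAssignment:
    def test_timestamp_at_trigger_is_phase_zero(self):
        trig = np.array([0.0, 400.0, 800.0])
        assert phase_assignment(np.array([400.0]), trig, 20)[0] == 0

    def test_uniform_timestamps_fill_phases_evenly(self):
        trig = np.array([0.0, 400.0])
        t = np.linspace(0.0, 400.0, 200, endpoint=False)
        ph = phase_assignment(t, trig, 20)
        counts = np.bincount(ph, minlength=20)
        assert counts.min() >= 200 // 20 - 1 and counts.max() <= 200 // 20 + 1

    def test_matches_brute_force_beat_search(self, rng):
        trig = np.cumsum(rng.uniform(350, 500, 30))
        t = rng.uniform(trig[0], trig[-1] - 1e-9, 200)
        ph = phase_assignment(t, trig, 20)
        for ti, pi in zip(t, ph):
            n = max(i for i in range(len(trig)) if trig[i] <= ti)
            rr = trig[n + 1] - trig[n]
            assert pi == int(20 * (ti - trig[n]) / rr)

    def test_outside_coverage_dropped_with_warning(self):
        trig = np.array([100.0, 500.0])
        with pytest.warns(UserWarning, match="outside"):
            ph = phase_assignment(np.array([50.0, 200.0, 600.0]), trig, 20)
        assert ph[0] == -1 and ph[2] == -1 and ph[1] >= 0

    def test_invariant_to_common_time_offset(self, rng):
        trig = np.cumsum(rng.uniform(350, 500, 10))
        t = rng.uniform(trig[0], trig[-1] - 1e-6, 50)
        a = phase_assignment(t, trig, 20)
        b = phase_assignment(t + 12345.0, trig + 12345.0, 20)
        np.testing.assert_array_equal(a, b)


class TestResortCine:
    def test_identical_frames_reproduce_frame(self, rng):
        frame = rng.random((8, 8))
        frames = np.repeat(frame[None], 40, axis=0)
        ph = np.arange(40) % 20
        cine = resort_cine(frames, ph, 20)
        for p in range(20):
            np.testing.assert_allclose(cine[p], frame)

    def test_noise_averaging(self, rng):
        m = 30
        frames = rng.standard_normal((20 * m, 8, 8))
        ph = np.arange(20 * m) % 20
        cine = resort_cine(frames, ph, 20)
        # mean of |N(0,1)| has sd sqrt((1-2/pi))/sqrt(m) per pixel; just check
        # the variance drop of the averaged maps is ~m within 20 %
        ratio = np.abs(frames).var() / cine.var()
        assert 0.6 * m < ratio < 1.4 * m

    def test_empty_phase_bin_raises(self, rng):
        frames = rng.random((10, 4, 4))
        ph = np.zeros(10, dtype=int)
        with pytest.raises(ValueError, match="phase bin"):
            resort_cine(frames, ph, 20)


class TestImageEntropy:
    def test_single_nonzero_pixel_zero_entropy(self):
        img = np.zeros((1, 8, 8))
        img[0, 3, 3] = 5.0
        assert image_entropy(img) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_pixels_log_n(self):
        img = np.full((2, 4, 4), 0.7)
        assert image_entropy(img) == pytest.approx(np.log(32), abs=1e-12)

    def test_scale_invariance(self, rng):
        img = rng.random((3, 8, 8))
        assert image_entropy(img) == pytest.approx(image_entropy(17.0 * img),
                                                   abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            image_entropy(np.zeros((2, 4, 4)))


def _synthetic_rt_series(rr_ms=433.0, n_frames=160, spacing_ms=28.5,
                         n=32, seed=0):
    """Frames of a pulsating disc with known constant RR."""
    rng = np.random.default_rng(seed)
    times = np.arange(n_frames) * spacing_ms
    yy, xx = np.mgrid[0:n, 0:n]
    frames = np.empty((n_frames, n, n), dtype=complex)
    for i, t in enumerate(times):
        phase = (t % rr_ms) / rr_ms
        r = 6.0 * (1.0 - 0.35 * 0.5 * (1 - np.cos(2 * np.pi * phase)))
        disc = (np.hypot(xx - n / 2, yy - n / 2) <= r).astype(float)
        frames[i] = disc * 3.0 + 0.02 * rng.standard_normal((n, n))
    return ImageSeries(frames=frames, times_ms=times,
                       frame_spacing_ms=spacing_ms, res_mm=1.5)


class TestMogOptimize:
    def test_recovers_constant_rr(self):
        series = _synthetic_rt_series(rr_ms=433.0)
        roi = Roi(4, 28, 4, 28)
        rec = mog_optimize(series, roi, segment_len_ms=5000.0)
        assert abs(rec.rr_series_ms.mean() - 433.0) <= 2.0

    def test_entropy_lower_at_truth_than_perturbed(self):
        from fetalcine.mog import resort_cine, image_entropy, phase_assignment
        series = _synthetic_rt_series(rr_ms=433.0)
        roi = Roi(4, 28, 4, 28)

        def entropy_at(rr):
            trig = np.arange(0.0, series.times_ms[-1] + 2 * rr, rr)
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ph = phase_assignment(series.times_ms, trig, 20)
            ok = ph >= 0
            cine = resort_cine(series.frames[ok], ph[ok], 20)
            return image_entropy(cine, roi)

        assert entropy_at(433.0) < entropy_at(463.0)

    def test_descent_from_truth_does_not_worsen(self):
        series = _synthetic_rt_series(rr_ms=420.0)
        roi = Roi(4, 28, 4, 28)
        rec = mog_optimize(series, roi, segment_len_ms=5000.0)
        assert np.isfinite(rec.entropy_at_solution)
        assert abs(rec.rr_series_ms.mean() - 420.0) <= 2.0
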