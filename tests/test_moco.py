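"""Data rejection, mutual information, and translational motion estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fetalcine.containers import Roi
from fetalcine.moco import (estimate_translations, mutual_information,
                            reject_frames, rejected_fraction, shifts_to_arms,
                            temporal_smooth)


@pytest.fixture()
def roi64():
    return Roi(0, 64, 0, 64)


class TestTemporalSmooth:
    def test_window_one_is_identity(self, rng):
        s = rng.standard_normal((6, 8, 8)) + 1j * rng.standard_normal((6, 8, 8))
        np.testing.assert_allclose(temporal_smooth(s, 1), np.abs(s))

    def test_constant_series_unchanged(self):
        s = np.full((7, 4, 4), 3.0)
        np.testing.assert_allclose(temporal_smooth(s, 5), s)

    def test_noise_variance_reduction(self, rng):
        s = rng.standard_normal((200, 16, 16)) + 10.0
        out = temporal_smooth(s, 5)
        inner = out[50:150]
        ratio = s.var() / inner.var()
        assert 4.0 < ratio < 6.0  # 5x +/- 20%

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            temporal_smooth(np.zeros((5, 2, 2)), 4)


class TestMutualInformation:
    def test_self_mi_equals_marginal_entropy(self, rng, roi64):
        img = rng.random((64, 64))
        mi = mutual_information(img, img, roi64)
        hist, _ = np.histogram((img - img.min()) / np.ptp(img), bins=32,
                               range=(0, 1))
        p = hist / hist.sum()
        h = -np.sum(p[p > 0] * np.log(p[p > 0]))
        assert mi == pytest.approx(h, abs=1e-9)

    def test_symmetry(self, rng, roi64):
        a, b = rng.random((64, 64)), rng.random((64, 64))
        assert mutual_information(a, b, roi64) \
            == pytest.approx(mutual_information(b, a, roi64), abs=1e-12)

    def test_independent_noise_has_low_mi(self, rng, roi64):
        for _ in range(20):
            a, b = rng.random((64, 64)), rng.random((64, 64))
            assert mutual_information(a, b, roi64) \
                < 0.1 * mutual_information(a, a, roi64)

    def test_invariant_to_joint_linear_rescaling(self, rng, roi64):
        a, b = rng.random((64, 64)), rng.random((64, 64))
        mi1 = mutual_information(a, b, roi64)
        mi2 = mutual_information(5.0 * a + 2.0, 5.0 * b + 2.0, roi64)
        assert mi1 == pytest.approx(mi2, abs=1e-12)

    def test_constant_roi_warns_and_returns_zero(self, roi64):
        with pytest.warns(UserWarning):
            assert mutual_information(np.ones((64, 64)),
                                      np.ones((64, 64)), roi64) == 0.0


class TestRejectFrames:
    def test_identical_frames_none_rejected(self, roi64, rng):
        frame = rng.random((64, 64)) + 0.5
        series = np.repeat(frame[None], 10, axis=0)
        keep, _ = reject_frames(series, roi64)
        assert keep.all()

    def test_two_frames_rejected(self, roi64):
        with pytest.raises(ValueError):
            reject_frames(np.random.default_rng(0).random((2, 64, 64)), roi64)

    def test_outlier_run_detected(self, roi64, rng):
        base = rng.random((64, 64)) + 0.5
        series = np.repeat(base[None], 40, axis=0)
        series += 0.02 * rng.standard_normal(series.shape)
        series[18:24] = rng.random((6, 64, 64))  # structurally unrelated run
        keep, mi = reject_frames(series, roi64)
        assert not keep[18:24].any()
        assert keep[:18].all() and keep[24:].all()

    def test_all_rejected_raises(self, roi64, rng):
        series = rng.random((10, 64, 64))
        with pytest.raises(ValueError, match="threshold"):
            # every frame independent noise: mutual MI ~ equal; force an
            # impossible threshold instead
            reject_frames(series, roi64, threshold_frac=1e9)


class TestEstimateTranslations:
    def test_static_series_zero_shifts(self, rng):
        frame = rng.random((64, 64))
        series = np.repeat(frame[None], 5, axis=0)
        shifts, ref = estimate_translations(series, Roi(8, 56, 8, 56), 1.0)
        assert np.nanmax(np.abs(shifts)) < 0.05

    def test_integer_circular_shift_recovered(self, rng):
        frame = rng.random((64, 64))
        series = np.stack([frame, np.roll(frame, (0, 3), axis=(0, 1)),
                           np.roll(frame, (2, 0), axis=(0, 1))])
        shifts, ref = estimate_translations(series, Roi(0, 64, 0, 64), 1.0)
        assert ref == 0
        np.testing.assert_allclose(shifts[1], (3.0, 0.0), atol=1e-6)
        np.testing.assert_allclose(shifts[2], (0.0, 2.0), atol=1e-6)

    def test_needs_two_retained_frames(self, rng):
        series = rng.random((3, 64, 64))
        with pytest.raises(ValueError):
            estimate_translations(series, Roi(0, 64, 0, 64), 1.0,
                                  keep_mask=np.array([True, False, False]))


class TestShiftsToArms:
    def test_constant_shifts_stay_constant(self):
        fs = np.tile([1.5, -2.0], (4, 1))
        out = shifts_to_arms(fs, np.array([0.0, 10, 20, 30]),
                             np.linspace(-5, 35, 9))
        np.testing.assert_allclose(out, np.tile([1.5, -2.0], (9, 1)))

    def test_midpoint_is_mean(self):
        fs = np.array([[0.0, 0.0], [2.0, 4.0]])
        out = shifts_to_arms(fs, np.array([0.0, 10.0]), np.array([5.0]))
        np.testing.assert_allclose(out[0], (1.0, 2.0))

    def test_clamped_outside_range(self):
        fs = np.array([[1.0, 2.0], [3.0, 4.0]])
        out = shifts_to_arms(fs, np.array([10.0, 20.0]),
                             np.array([0.0, 30.0]))
        np.testing.assert_allclose(out[0], (1.0, 2.0))
        np.testing.assert_allclose(out[1], (3.0, 4.0))


class TestRejectedFraction:
    @pytest.mark.parametrize("n_rej,n_tot,expect", [
        (163, 1250, 13),   # printed worked example
        (2319, 2721, 85),  # printed worked example
        (0, 100, 0),
        (1, 200, 1),       # 0.5% rounds half up to 1
    ])
    def test_bookkeeping(self, n_rej, n_tot, expect):
        mask = np.ones(n_tot, dtype=bool)
        mask[:n_rej] = False
        assert rejected_fraction(mask) == expect

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            rejected_fraction(np.array([], dtype=bool))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(n_rej=st.integers(0, 4000), n_keep=st.integers(1, 4000))
    def test_half_up_rounding_property(self, n_rej, n_keep):
        """Integer percent equals exact-fraction rounding with ties going up."""
        from fractions import Fraction
        mask = np.ones(n_rej + n_keep, dtype=bool)
        mask[:n_rej] = False
        frac = Fraction(100 * n_rej, n_rej + n_keep)
        expect = int(frac) + (1 if frac - int(frac) >= Fraction(1, 2) else 0)
        assert rejected_fraction(mask) == expect
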