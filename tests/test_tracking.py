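"""Block-matching speckle tracker: correlation, displacement, drift, spectra."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hifufusion.motion import MotionTrace, ventilator_motion
from hifufusion.phantom import ScattererPhantom, render_speckle
from hifufusion.tracking import (
    TrackedTrace,
    TrackingConfig,
    UndefinedCorrelationError,
    UndefinedFrequencyError,
    correct_drift,
    detectability_limits,
    dominant_frequency,
    ncc,
    track_pair,
    track_sequence,
)


def ncc_oracle(a, b):
    """Independent double-sum evaluation of the correlation coefficient."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    am, bm = a.mean(), b.mean()
    num = sum((a.flat[i] - am) * (b.flat[i] - bm) for i in range(a.size))
    da = sum((a.flat[j] - am) ** 2 for j in range(a.size))
    db = sum((b.flat[k] - bm) ** 2 for k in range(b.size))
    return num / np.sqrt(da * db)


SMALL_CFG = TrackingConfig(
    rr_mm=(1.5, 1.5), sa_mm=(2.9, 2.9), roi_mm=(6.0, 6.0), overlap=(0.5, 0.5), pitch=9.6
)


@pytest.fixture(scope="module")
def speckle_frame():
    phantom = ScattererPhantom.random(fov=(14.0, 14.0), seed=11)
    seq = render_speckle(phantom, None, n_frames=1, noise_sd=0.0, seed=0)
    return seq.frames[0].astype(float)


class TestNcc:
    def test_identical_blocks_give_unity(self):
        a = np.arange(9.0).reshape(3, 3)
        assert ncc(a, a) == pytest.approx(1.0, abs=1e-12)

    def test_negated_block_gives_minus_one(self):
        a = np.arange(9.0).reshape(3, 3)
        b = 2.0 * a.mean() - a
        assert ncc(a, b) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_hand_computed_double_sum(self):
        a = np.array([[3, 1, 4], [1, 5, 9], [2, 6, 5]], dtype=float)
        b = np.array([[2, 7, 1], [8, 2, 8], [1, 8, 2]], dtype=float)
        assert ncc(a, b) == pytest.approx(ncc_oracle(a, b), abs=1e-12)

    def test_matches_skimage_template_matching(self, speckle_frame):
        # independent route: skimage's normalized cross-correlation
        from skimage.feature import match_template

        tmpl = speckle_frame[40:55, 40:55]
        img = speckle_frame[38:60, 38:60]
        corr = match_template(img, tmpl)
        ours = np.array(
            [
                [ncc(tmpl, img[i : i + 15, j : j + 15]) for j in range(corr.shape[1])]
                for i in range(corr.shape[0])
            ]
        )
        assert np.allclose(corr, ours, atol=1e-6)

    def test_both_constant_blocks_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            ncc(np.ones((3, 3)), np.full((3, 3), 7.0))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            ncc(np.ones((3, 3)), np.ones((3, 4)))

    @given(
        alpha=st.floats(0.1, 50.0),
        beta=st.floats(-100.0, 100.0),
        seed=st.integers(0, 2**16),
    )
    @settings(max_examples=30, deadline=None)
    def test_invariant_to_positive_affine_rescaling(self, alpha, beta, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(5, 5))
        b = rng.normal(size=(5, 5))
        base = ncc(a, b)
        assert abs(ncc(alpha * a + beta, b) - base) < 1e-9
        assert abs(base) <= 1.0
        assert ncc(b, a) == pytest.approx(base, abs=1e-12)


class TestTrackPair:
    def test_identical_frames_give_zero_displacement(self, speckle_frame):
        fld = track_pair(speckle_frame, speckle_frame, SMALL_CFG)
        assert np.allclose(fld.dx, 0.0) and np.allclose(fld.dz, 0.0)
        assert np.all(fld.rho[np.isfinite(fld.rho)] > 0.999)

    @pytest.mark.parametrize("shift", [(3, -2), (1, 4), (-5, 0)])
    def test_integer_translation_recovered_exactly(self, speckle_frame, shift):
        kx, kz = shift
        b = np.roll(np.roll(speckle_frame, kz, axis=0), kx, axis=1)
        fld = track_pair(speckle_frame, b, SMALL_CFG)
        px = SMALL_CFG.pitch
        assert np.allclose(fld.dx * px, kx, atol=1e-9)
        assert np.allclose(fld.dz * px, kz, atol=1e-9)

    def test_subpixel_shift_recovered_within_bias_bound(self):
        phantom = ScattererPhantom.random(fov=(14.0, 14.0), seed=3)
        pitch = 9.6
        motion = MotionTrace(np.array([0.0, 0.04]), np.array([0.0, 0.4 / pitch]), np.zeros(2))
        seq = render_speckle(phantom, motion, n_frames=2, pitch=pitch, noise_sd=0.0, seed=0)
        fld = track_pair(seq.frames[0].astype(float), seq.frames[1].astype(float), SMALL_CFG)
        mean_px = np.nanmean(fld.dx) * pitch
        assert mean_px == pytest.approx(0.4, abs=0.15)

    def test_frame_shape_mismatch_rejected(self, speckle_frame):
        with pytest.raises(ValueError):
            track_pair(speckle_frame, speckle_frame[:-1], SMALL_CFG)

    def test_oversized_roi_rejected(self, speckle_frame):
        cfg = TrackingConfig(rr_mm=(8.0, 8.0), sa_mm=(13.0, 13.0), roi_mm=(10.0, 10.0))
        with pytest.raises(ValueError):
            track_pair(speckle_frame, speckle_frame, cfg)


class TestTrackSequence:
    def test_zero_motion_gives_zero_trace(self):
        phantom = ScattererPhantom.random(fov=(12.0, 12.0), seed=5)
        seq = render_speckle(phantom, None, n_frames=4, seed=0)
        _, trace = track_sequence(seq, SMALL_CFG)
        assert np.allclose(trace.dx, 0.0) and np.allclose(trace.dz, 0.0)

    def test_forward_then_reversed_motion_returns_to_zero(self):
        phantom = ScattererPhantom.random(fov=(12.0, 12.0), seed=6)
        pitch = 9.6
        steps = np.array([0.0, 0.23, 0.46, 0.23, 0.0])  # mm, out and back
        motion = MotionTrace(np.arange(5) / 25.0, steps, np.zeros(5))
        seq = render_speckle(phantom, motion, n_frames=5, pitch=pitch, seed=0)
        _, trace = track_sequence(seq, SMALL_CFG)
        assert abs(trace.dx[-1]) <= 2 * 0.15 / pitch

    def test_ventilator_excursion_recovered_within_5pct(self):
        # full-scale breathing fixture on the truncated tracking field of
        # view, tracked with the respiratory window geometry
        phantom = ScattererPhantom.random(fov=(27.0, 18.5), seed=8)
        motion = ventilator_motion(duration=5.5, amp_cc=13.3, amp_ap=1.9)
        seq = render_speckle(phantom, motion, n_frames=131, seed=0)
        _, trace = track_sequence(seq, TrackingConfig())
        assert trace.dx.max() - trace.dx.min() == pytest.approx(13.3, rel=0.05)
        assert trace.dz.max() - trace.dz.min() == pytest.approx(1.9, rel=0.10)
        assert trace.meta["mean_correlation"] >= 0.95

    def test_correlation_degrades_with_noise(self):
        phantom = ScattererPhantom.random(fov=(12.0, 12.0), seed=9)
        rhos = []
        for sd in (0.0, 0.15, 0.4):
            seq = render_speckle(phantom, None, n_frames=3, noise_sd=sd, seed=1)
            _, trace = track_sequence(seq, SMALL_CFG)
            rhos.append(trace.meta["mean_correlation"])
        assert rhos[0] > rhos[1] > rhos[2]

    def test_elastic_map_localizes_vessel_pulsation(self):
        from hifufusion.motion import vessel_pulsation

        fov = (16.0, 16.0)
        phantom = ScattererPhantom.random(fov=fov, seed=10)
        pitch = 9.6
        W = int(fov[0] * pitch)
        gx = np.arange(W) / pitch
        gz = np.arange(int(fov[1] * pitch)) / pitch
        dense = vessel_pulsation(0.96, 0.6, (8.0, 8.0), 1.5, gx, gz, 0.26, sample_rate=3.84)
        seq = render_speckle(phantom, dense, n_frames=2, frame_rate=3.84, pitch=pitch, seed=0)
        cfg = TrackingConfig(
            rr_mm=(1.3, 1.3), sa_mm=(2.5, 2.5), roi_mm=(11.0, 11.0),
            overlap=(0.9, 0.9), mode="elastic-map",
        )
        fld = track_pair(seq.frames[0].astype(float), seq.frames[1].astype(float), cfg)
        mag = np.hypot(np.nan_to_num(fld.dx), np.nan_to_num(fld.dz))
        i, j = np.unravel_index(np.argmax(mag), mag.shape)
        r_peak = np.hypot(fld.centers_x_mm[j] - 8.0, fld.centers_z_mm[i] - 8.0)
        assert 0.75 <= r_peak <= 3.0  # maximal motion at the vessel boundary


class TestDriftCorrection:
    def _periodic_trace(self, ramp=0.0, n=300, fs=25.0):
        t = np.arange(n) / fs
        dx = 5.0 * np.sin(2 * np.pi * 0.5 * t) + ramp * t
        return TrackedTrace(t, dx - dx[0], np.zeros(n), np.full(n, np.nan))

    def test_zero_trend_unchanged(self):
        tr = self._periodic_trace(0.0)
        out = correct_drift(tr)
        assert abs(out.drift_rate[0]) < 0.01
        assert np.allclose(out.dx, tr.dx, atol=0.2)

    def test_ramp_rate_recovered(self):
        out = correct_drift(self._periodic_trace(0.10))
        assert out.drift_rate[0] == pytest.approx(0.10, abs=0.02)

    def test_pure_ramp_detrended_exactly(self):
        t = np.arange(100) / 25.0
        tr = TrackedTrace(t, 0.3 * t, np.zeros(100), np.full(100, np.nan))
        out = correct_drift(tr)
        assert np.max(np.abs(out.dx)) < 1e-6

    def test_short_trace_is_noop_with_warning(self):
        t = np.arange(20) / 25.0  # 0.8 s of a 0.5 Hz tone: < 2 periods
        dx = np.sin(2 * np.pi * 0.5 * t)
        tr = TrackedTrace(t, dx - dx[0], np.zeros(20), np.full(20, np.nan))
        with pytest.warns(UserWarning, match="2 periods"):
            out = correct_drift(tr)
        assert np.array_equal(out.dx, tr.dx)


class TestDominantFrequency:
    def _tone(self, f, amp=1.0, fs=25.0, dur=20.0):
        t = np.arange(0.0, dur, 1.0 / fs)
        dx = amp * np.sin(2 * np.pi * f * t)
        return TrackedTrace(t, dx - dx[0], np.zeros_like(t), np.full(t.size, np.nan))

    def test_respiratory_tone(self):
        assert dominant_frequency(self._tone(0.2)) == pytest.approx(0.2, abs=1.0 / 20.0)

    def test_heartbeat_tone(self):
        assert dominant_frequency(self._tone(0.96, amp=0.5)) == pytest.approx(0.96, abs=1.0 / 20.0)

    def test_largest_peak_wins_in_mixture(self):
        t = np.arange(0.0, 20.0, 1.0 / 25.0)
        dx = 13.0 * np.sin(2 * np.pi * 0.2 * t) + 0.5 * np.sin(2 * np.pi * 0.96 * t)
        tr = TrackedTrace(t, dx - dx[0], np.zeros_like(t), np.full(t.size, np.nan))
        assert dominant_frequency(tr) == pytest.approx(0.2, abs=1.0 / 20.0)

    def test_constant_trace_undefined(self):
        t = np.arange(10) / 25.0
        tr = TrackedTrace(t, np.zeros(10), np.zeros(10), np.full(10, np.nan))
        with pytest.raises(UndefinedFrequencyError):
            dominant_frequency(tr)


class TestDetectabilityLimits:
    def test_respiratory_window_limits(self):
        cfg = TrackingConfig(rr_mm=(10.3, 4.1), sa_mm=(16.4, 6.2), roi_mm=(10.6, 12.3))
        lim = detectability_limits(cfg)
        assert lim["lateral"]["max_magnitude_mm"] == pytest.approx(8.2)
        assert lim["lateral"]["max_speed_cm_s"] == pytest.approx(20.5)
        assert lim["depth"]["max_magnitude_mm"] == pytest.approx(3.1)
        assert lim["depth"]["max_speed_cm_s"] == pytest.approx(7.8, abs=0.05)

    def test_degenerate_sa_equals_sr(self):
        cfg = TrackingConfig(rr_mm=(4.0, 4.0), sa_mm=(4.0, 4.0), roi_mm=(5.0, 5.0))
        lim = detectability_limits(cfg)
        assert lim["lateral"]["max_magnitude_mm"] == pytest.approx(2.0)
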