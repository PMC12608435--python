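"""Beat detection and HRV metrics on synthetic pulse waveforms."""

from __future__ import annotations

import numpy as np
import pytest

from wearstress.hrv import (
    BeatDetectionError,
    Tachogram,
    _reject_outliers,
    breathing_rate,
    detect_beats,
    hrv_features,
    landmark_features,
    percentile_prune,
)
from wearstress.session_io import Recording

CONTINUOUS = ["bpm", "ibi", "rmssd", "sdnn", "sd1", "sd2"]


class TestTachogram:
    def test_rejects_nonincreasing_beats(self):
        with pytest.raises(ValueError, match="increasing"):
            Tachogram("P", np.array([0.0, 1.0, 1.0]), np.array([1000.0, 0.0]),
                      np.array([True, True]))

    def test_rejects_interval_length_mismatch(self):
        with pytest.raises(ValueError, match="differences"):
            Tachogram("P", np.array([0.0, 1.0]), np.array([1000.0, 900.0]),
                      np.array([True, True]))

    def test_rejects_unknown_landmark(self):
        with pytest.raises(ValueError, match="landmark"):
            Tachogram("X", np.array([0.0, 1.0]), np.array([1000.0]),
                      np.array([True]))


class TestDetection:
    def test_recovers_heart_rate_from_clean_pulse(self, small_session):
        window = small_session.events.level_windows[1]
        tach = detect_beats(small_session.bvp, window)
        truth = np.asarray(small_session.ground_truth["beat_times"])
        in_win = (truth >= window[0]) & (truth < window[1])
        true_ibi = np.mean(np.diff(truth[in_win])) * 1000.0
        est_ibi = np.mean(tach.accepted_intervals)
        assert est_ibi == pytest.approx(true_ibi, rel=0.03)

    def test_onset_and_peak_landmarks_agree_on_clean_signal(self, small_session):
        window = small_session.events.span
        feats = {
            lm: hrv_features(detect_beats(small_session.bvp, window, invert=(lm == "O")))
            for lm in ("P", "O")
        }
        for name in CONTINUOUS:
            p, o = feats["P"][name], feats["O"][name]
            assert abs(p - o) <= 0.05 * max(abs(p), abs(o)), name

    def test_deformed_waveform_breaks_peak_but_not_onset_detection(
        self, deformed_session
    ):
        window = deformed_session.events.span
        p = hrv_features(detect_beats(deformed_session.bvp, window))
        o = hrv_features(detect_beats(deformed_session.bvp, window, invert=True))
        truth_sd = np.std(
            np.asarray(deformed_session.ground_truth["beat_intervals_ms"])
        )
        # the onset series stays close to the true variability while the
        # ambiguous positive peaks inflate it severalfold
        assert o["sdnn"] < 2.0 * truth_sd
        assert p["sdnn"] > 3.0 * o["sdnn"]

    def test_flat_signal_raises(self):
        rec = Recording("BVP", 0.0, 64.0, np.zeros(64 * 30))
        with pytest.raises(BeatDetectionError):
            detect_beats(rec)

    def test_low_rate_and_short_window_rejected(self, small_session):
        with pytest.raises(ValueError, match="too low"):
            detect_beats(Recording("BVP", 0.0, 10.0, np.random.default_rng(0).normal(size=600)))
        with pytest.raises(ValueError, match="10 s"):
            detect_beats(small_session.bvp, (0.0, 5.0))


class TestIntervalCleaning:
    def test_outlier_rejection_drops_implausible_intervals(self):
        intervals = np.array([850.0] * 30 + [2500.0, 100.0] + [850.0] * 10)
        accepted = _reject_outliers(intervals)
        assert not accepted[30]
        assert not accepted[31]
        assert accepted[:30].all()

    def test_percentile_prune_is_strict_and_preserves_bulk(self):
        rng = np.random.default_rng(0)
        intervals = rng.normal(850.0, 30.0, size=200)
        beat_times = np.concatenate([[0.0], np.cumsum(intervals) / 1000.0])
        tach = Tachogram("P", beat_times, intervals, np.ones(200, dtype=bool))
        pruned = percentile_prune(tach)
        lo, hi = np.percentile(intervals, [5, 95])
        kept = pruned.accepted_intervals
        assert kept.size < 200
        assert np.all((kept > lo) & (kept < hi))

    def test_percentile_prune_skips_tiny_series_with_warning(self):
        intervals = np.full(10, 850.0)
        beat_times = np.concatenate([[0.0], np.cumsum(intervals) / 1000.0])
        tach = Tachogram("P", beat_times, intervals, np.ones(10, dtype=bool))
        with pytest.warns(UserWarning, match="skipped"):
            pruned = percentile_prune(tach)
        assert pruned.accepted.sum() == 10


class TestBreathing:
    def test_too_few_intervals_give_nan(self):
        assert np.isnan(breathing_rate(np.arange(5.0), np.full(5, 850.0)))

    def test_session_breathing_frequency_recovered(self, small_session):
        window = small_session.events.span
        feats = hrv_features(detect_beats(small_session.bvp, window))
        assert feats["breathingrate"] == pytest.approx(
            small_session.ground_truth["resp_freq"], abs=0.02
        )


def test_landmark_features_fall_back_to_nan_rows():
    rec = Recording("BVP", 0.0, 64.0, np.zeros(64 * 30))
    feats = landmark_features(rec, (0.0, 30.0), "P")
    assert len(feats) == 28
    assert all(np.isnan(v) for v in feats.values())
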