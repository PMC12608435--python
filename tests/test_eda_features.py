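"""EDA feature battery: closed-form cases and qualitative orderings."""

from __future__ import annotations

import numpy as np
import pytest

from wearstress.eda_features import (
    approximate_entropy,
    complexity_features,
    derivative_features,
    eda_level_features,
    hjorth,
    lyapunov_exponent,
    sample_entropy,
    scr_burst_rate,
    segment_stats,
    shannon_entropy,
    spectral_features,
)
from wearstress.features import FEATURE_INVENTORY


class TestSegmentStats:
    def test_known_values(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        stats = segment_stats(x)
        assert stats["Mean"] == pytest.approx(2.5)
        assert stats["Std"] == pytest.approx(np.std(x))
        assert stats["Median"] == pytest.approx(2.5)
        assert stats["Range"] == pytest.approx(3.0)
        assert stats["Max"] == pytest.approx(4.0)
        assert stats["Skew"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_segment_warns_and_zeroes_shape_moments(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            stats = segment_stats(np.full(10, 3.0))
        assert stats["Skew"] == 0.0
        assert stats["Kurt"] == 0.0

    def test_too_short_segment_raises(self):
        with pytest.raises(ValueError, match="too short"):
            segment_stats(np.array([1.0, 2.0]))


class TestDerivatives:
    def test_linear_increase_has_zero_recovery_speed(self):
        fs = 4.0
        x = np.arange(0, 10, 1 / fs) * 0.2  # slope 0.2 per second
        feats = derivative_features(x, fs)
        assert feats["DerMean"] == pytest.approx(0.2)
        assert feats["Dermax"] == pytest.approx(0.2)
        assert feats["NegDerMean"] == 0.0

    def test_decay_yields_negative_mean_recovery(self):
        fs = 4.0
        x = np.exp(-np.arange(0, 10, 1 / fs))
        feats = derivative_features(x, fs)
        assert feats["NegDerMean"] < 0


class TestHjorth:
    def test_activity_is_variance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        assert hjorth(x)["Activity"] == pytest.approx(np.var(x))

    def test_mobility_larger_for_faster_signal(self):
        t = np.linspace(0, 10, 400)
        slow = np.sin(2 * np.pi * 0.2 * t)
        fast = np.sin(2 * np.pi * 2.0 * t)
        assert hjorth(fast)["Mobility"] > hjorth(slow)["Mobility"]

    def test_flat_segment_raises(self):
        with pytest.raises(ValueError, match="zero-variance"):
            hjorth(np.ones(10))


class TestComplexity:
    def test_shannon_entropy_of_constant_is_zero(self):
        assert shannon_entropy(np.full(100, 1.0)) == 0.0

    def test_shannon_entropy_maximal_for_uniform_spread(self):
        uniform = np.repeat(np.arange(16), 10).astype(float)
        assert shannon_entropy(uniform) == pytest.approx(4.0, abs=1e-9)

    def test_entropies_rank_noise_above_regular_signal(self):
        rng = np.random.default_rng(1)
        t = np.linspace(0, 20, 400)
        regular = np.sin(2 * np.pi * 0.5 * t)
        noise = rng.normal(size=400)
        assert approximate_entropy(noise) > approximate_entropy(regular)
        assert sample_entropy(noise) > sample_entropy(regular)

    def test_lyapunov_finite_on_noise(self):
        rng = np.random.default_rng(2)
        assert np.isfinite(lyapunov_exponent(rng.normal(size=300)))

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            complexity_features(np.ones(10))


class TestSpectral:
    def test_slow_signal_concentrates_power_in_low_band(self):
        fs = 4.0
        t = np.arange(0, 300, 1 / fs)
        x = np.sin(2 * np.pi * 0.1 * t)
        feats = spectral_features(x, fs)
        assert feats["PB5"] > 95.0
        assert feats["Pmax"] == pytest.approx(0.1, abs=0.02)
        assert feats["P90"] <= 0.2

    def test_flat_signal_returns_zeros(self):
        feats = spectral_features(np.full(400, 2.0), 4.0)
        assert feats == {"PB5": 0.0, "P90": 0.0, "Pmax": 0.0, "Pstd": 0.0}


class TestSCRRate:
    def test_counts_distinct_bursts_per_minute(self):
        fs = 4.0
        driver = np.zeros(int(120 * fs))
        for start in (40, 200, 360):  # three bursts in two minutes
            driver[start : start + 4] = 0.3
        assert scr_burst_rate(driver, fs) == pytest.approx(1.5)

    def test_subthreshold_activity_is_ignored(self):
        assert scr_burst_rate(np.full(480, 0.01), 4.0) == 0.0


def test_level_battery_matches_documented_inventory():
    rng = np.random.default_rng(3)
    fs = 4.0
    n = int(30 * fs)
    tonic = np.linspace(0.0, 0.5, n)
    phasic = np.abs(rng.normal(0.1, 0.05, size=n))
    driver = np.where(rng.random(n) > 0.95, 0.2, 0.0)
    z = tonic + phasic + 0.05 * rng.normal(size=n)
    feats = eda_level_features(z, tonic, phasic, driver, fs)
    eda_side = [f for f in FEATURE_INVENTORY if not f.startswith(("pp", "oo"))]
    assert sorted(feats) == sorted(eda_side)
    assert len(feats) == 39
    assert all(np.isfinite(v) for v in feats.values())
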