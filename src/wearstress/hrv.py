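"""BVP beat detection, tachogram pruning and short-term HRV features.

Beats are found with an adaptive-threshold detector: the signal is
standardized, a rolling-mean envelope is raised by a set of candidate
elevations, contiguous supra-threshold regions yield one peak each, and
the elevation giving the most physiologically regular tachogram is kept.
Detection on the inverted signal locates the pulse onsets (O) instead of
the systolic peaks (P) — the onset trough is often better preserved than
the systolic peak when wrist pressure deforms the waveform, so the OO
interval series is a robust alternative to PP.

Interval series are cleaned twice: an adaptive moving-median band plus a
physiologic 300-2000 ms range check at detection time, and an optional
5th-95th percentile pruning (strict inequalities) for the second feature
battery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import interpolate, signal

from wearstress.session_io import Recording

PHYSIO_MIN_MS = 300.0
PHYSIO_MAX_MS = 2000.0


class BeatDetectionError(RuntimeError):
    """Raised when too few beats can be located in a window."""


@dataclass
class Tachogram:
    """Beat landmark times and inter-beat intervals for one window."""

    landmark: str  # "P" (systolic peak) or "O" (onset)
    beat_times: np.ndarray  # seconds, strictly increasing
    intervals: np.ndarray  # ms, successive differences of beat_times
    accepted: np.ndarray  # boolean mask over intervals

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.intervals = np.asarray(self.intervals, dtype=float)
        self.accepted = np.asarray(self.accepted, dtype=bool)
        if self.landmark not in ("P", "O"):
            raise ValueError(f"landmark must be P or O, got {self.landmark!r}")
        if np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat times must be strictly increasing")
        if self.intervals.size != max(self.beat_times.size - 1, 0):
            raise ValueError("intervals must be successive beat-time differences")

    @property
    def accepted_intervals(self) -> np.ndarray:
        return self.intervals[self.accepted]


def _reject_outliers(intervals: np.ndarray) -> np.ndarray:
    """Adaptive moving-median band plus physiologic range check."""
    accepted = (intervals >= PHYSIO_MIN_MS) & (intervals <= PHYSIO_MAX_MS)
    if intervals.size >= 5:
        half = 5
        local_median = np.array(
            [
                np.median(intervals[max(0, i - half) : i + half + 1])
                for i in range(intervals.size)
            ]
        )
        band = np.maximum(0.25 * local_median, 150.0)
        accepted &= np.abs(intervals - local_median) <= band
    return accepted


def detect_beats(
    bvp: Recording,
    window: tuple[float, float] | None = None,
    invert: bool = False,
) -> Tachogram:
    """Detect beats in a BVP window via adaptive-threshold peak search.

    With ``invert`` the detector runs on the negated signal and the
    landmark is the onset (O).  Raises :class:`BeatDetectionError` when
    fewer than 5 beats are found.
    """
    if bvp.fs < 25.0:
        raise ValueError(f"BVP sampling rate {bvp.fs} Hz too low for beat detection")
    if window is None:
        window = (0.0, bvp.duration)
    start, stop = window
    if stop - start < 10.0:
        raise ValueError("analysis window must span at least 10 s")
    x = bvp.slice_window(start, stop).astype(float)
    if invert:
        x = -x
    sd = np.std(x)
    if sd == 0:
        raise BeatDetectionError("insufficient beats: flat signal")
    x = (x - np.mean(x)) / sd
    fs = bvp.fs
    smooth_w = max(int(0.1 * fs), 1)
    x = np.convolve(x, np.ones(smooth_w) / smooth_w, mode="same")
    w = max(int(0.75 * fs), 1)
    rolling = np.convolve(x, np.ones(w) / w, mode="same")
    refractory = max(int(0.3 * fs), 1)  # 300 ms physiologic minimum

    best: tuple[float, np.ndarray] | None = None
    for prominence in (0.3, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0):
        peaks, _ = signal.find_peaks(x, prominence=prominence, distance=refractory)
        peaks = peaks[x[peaks] > rolling[peaks]]  # envelope gate
        if peaks.size < 5:
            continue
        ibis = np.diff(peaks) / fs * 1000.0
        bpm = 60000.0 / np.mean(ibis)
        if not 40.0 <= bpm <= 180.0:
            continue
        score = np.std(ibis)
        if best is None or score < best[0]:
            best = (score, peaks)
    if best is None:
        raise BeatDetectionError("insufficient beats: no acceptable threshold found")
    peaks = best[1]
    # sub-sample localization: parabolic interpolation around each peak
    offsets = np.zeros(peaks.size)
    inner = (peaks > 0) & (peaks < x.size - 1)
    y0, y1, y2 = x[peaks[inner] - 1], x[peaks[inner]], x[peaks[inner] + 1]
    denom = y0 - 2 * y1 + y2
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = 0.5 * (y0 - y2) / denom
    delta = np.where(np.isfinite(delta) & (np.abs(delta) < 1.0), delta, 0.0)
    offsets[inner] = delta
    beat_times = start + (peaks + offsets) / fs
    intervals = np.diff(beat_times) * 1000.0
    accepted = _reject_outliers(intervals)
    return Tachogram(
        landmark="O" if invert else "P",
        beat_times=beat_times,
        intervals=intervals,
        accepted=accepted,
    )


def percentile_prune(tachogram: Tachogram) -> Tachogram:
    """Retain accepted intervals strictly inside the 5th-95th percentiles.

    Skipped with a warning (mask unchanged) when fewer than 20 intervals
    are accepted or when pruning would empty the series.
    """
    accepted = tachogram.accepted
    values = tachogram.intervals[accepted]
    if values.size < 20:
        warnings.warn("fewer than 20 accepted intervals; percentile pruning skipped")
        return tachogram
    lo, hi = np.percentile(values, [5, 95])
    keep = accepted & (tachogram.intervals > lo) & (tachogram.intervals < hi)
    if not keep.any():
        warnings.warn("percentile pruning would drop every interval; skipped")
        return tachogram
    return Tachogram(
        landmark=tachogram.landmark,
        beat_times=tachogram.beat_times,
        intervals=tachogram.intervals,
        accepted=keep,
    )


def breathing_rate(beat_times: np.ndarray, intervals_ms: np.ndarray) -> float:
    """Dominant frequency (Hz) of the interval series in the 0.1-0.4 Hz band.

    The tachogram is cubic-interpolated onto a uniform 4 Hz grid before
    the spectral estimate.
    """
    beat_times = np.asarray(beat_times, dtype=float)
    intervals_ms = np.asarray(intervals_ms, dtype=float)
    if intervals_ms.size < 8 or beat_times.size != intervals_ms.size:
        return np.nan
    t, keep = np.unique(beat_times, return_index=True)
    intervals_ms = intervals_ms[keep]
    interp_fs = 4.0
    grid = np.arange(t[0], t[-1], 1.0 / interp_fs)
    if grid.size < 16:
        return np.nan
    series = interpolate.CubicSpline(t, intervals_ms)(grid)
    series = series - np.mean(series)
    nfft = max(4096, grid.size)
    freqs, psd = signal.periodogram(series, fs=interp_fs, nfft=nfft)
    band = (freqs >= 0.1) & (freqs <= 0.4)
    if not band.any() or psd[band].max() == 0:
        return np.nan
    return float(freqs[band][np.argmax(psd[band])])


def _poincare(intervals: np.ndarray) -> tuple[float, float]:
    var = np.var(intervals)
    sd1 = float(np.sqrt(np.var(np.diff(intervals)) / 2.0))
    sd2_sq = 2.0 * var - sd1**2
    sd2 = float(np.sqrt(max(sd2_sq, 0.0)))
    return sd1, sd2


def hrv_features(tachogram: Tachogram) -> dict[str, float]:
    """Time-domain HRV battery on the accepted intervals (13 features).

    Returns a row of NaNs when fewer than 10 intervals are accepted.
    """
    names = [
        "bpm", "ibi", "sdnn", "sdsd", "rmssd", "pnn20", "pnn50",
        "mad", "sd1", "sd2", "s", "sd1/sd2", "breathingrate",
    ]
    ivl = tachogram.accepted_intervals
    if ivl.size < 10:
        return {name: np.nan for name in names}
    diffs = np.diff(ivl)
    sd1, sd2 = _poincare(ivl)
    return {
        "bpm": 60000.0 / float(np.mean(ivl)),
        "ibi": float(np.mean(ivl)),
        "sdnn": float(np.std(ivl)),
        "sdsd": float(np.std(diffs)),
        "rmssd": float(np.sqrt(np.mean(diffs**2))) if diffs.size else 0.0,
        "pnn20": 100.0 * float(np.mean(np.abs(diffs) > 20.0)) if diffs.size else 0.0,
        "pnn50": 100.0 * float(np.mean(np.abs(diffs) > 50.0)) if diffs.size else 0.0,
        "mad": float(np.median(np.abs(ivl - np.median(ivl)))),
        "sd1": sd1,
        "sd2": sd2,
        "s": float(np.pi * sd1 * sd2),
        "sd1/sd2": sd1 / sd2 if sd2 > 0 else 0.0,
        "breathingrate": breathing_rate(
            tachogram.beat_times[1:][tachogram.accepted], ivl
        ),
    }


def pruned_hrv_features(tachogram: Tachogram) -> dict[str, float]:
    """Descriptors of the percentile-pruned interval series (15 features)."""
    pruned = percentile_prune(tachogram)
    names = [
        "meanPP", "medianPP", "sdPP", "madPP", "iqr", "rangePP", "cvPP",
        "rmssdPP", "sdsdPP", "pnn20PP", "pnn50PP", "sd1PP", "sd2PP",
        "sd1/sd2PP", "sPP",
    ]
    ivl = pruned.accepted_intervals
    if ivl.size < 10:
        return {name: np.nan for name in names}
    diffs = np.diff(ivl)
    sd1, sd2 = _poincare(ivl)
    q25, q75 = np.percentile(ivl, [25, 75])
    mean = float(np.mean(ivl))
    return {
        "meanPP": mean,
        "medianPP": float(np.median(ivl)),
        "sdPP": float(np.std(ivl)),
        "madPP": float(np.median(np.abs(ivl - np.median(ivl)))),
        "iqr": float(q75 - q25),
        "rangePP": float(np.ptp(ivl)),
        "cvPP": float(np.std(ivl)) / mean if mean > 0 else 0.0,
        "rmssdPP": float(np.sqrt(np.mean(diffs**2))) if diffs.size else 0.0,
        "sdsdPP": float(np.std(diffs)),
        "pnn20PP": 100.0 * float(np.mean(np.abs(diffs) > 20.0)) if diffs.size else 0.0,
        "pnn50PP": 100.0 * float(np.mean(np.abs(diffs) > 50.0)) if diffs.size else 0.0,
        "sd1PP": sd1,
        "sd2PP": sd2,
        "sd1/sd2PP": sd1 / sd2 if sd2 > 0 else 0.0,
        "sPP": float(np.pi * sd1 * sd2),
    }


def landmark_features(
    bvp: Recording, window: tuple[float, float], landmark: str
) -> dict[str, float]:
    """Raw + pruned HRV battery for one landmark ("P" or "O") and window."""
    try:
        tach = detect_beats(bvp, window, invert=(landmark == "O"))
    except BeatDetectionError:
        raw = {
            k: np.nan
            for k in [
                "bpm", "ibi", "sdnn", "sdsd", "rmssd", "pnn20", "pnn50",
                "mad", "sd1", "sd2", "s", "sd1/sd2", "breathingrate",
            ]
        }
        pruned = {
            k: np.nan
            for k in [
                "meanPP", "medianPP", "sdPP", "madPP", "iqr", "rangePP", "cvPP",
                "rmssdPP", "sdsdPP", "pnn20PP", "pnn50PP", "sd1PP", "sd2PP",
                "sd1/sd2PP", "sPP",
            ]
        }
        return {**raw, **pruned}
    return {**hrv_features(tach), **pruned_hrv_features(tach)}
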