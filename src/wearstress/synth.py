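"""Synthetic wearable sessions for the four-level exergame protocol.

Each session emulates the study design: a 3-minute eyes-closed rest
baseline followed by four seamless game levels of growing demand.  The
skin-conductance channel is built from three additive parts — a slow tonic
drive that steps up at each level start, a sparse train of skin-conductance
responses (SCRs) convolved with a difference-of-exponentials (Bateman)
kernel, and white measurement noise.  The blood-volume-pulse channel is a
train of pulse templates with the four canonical landmarks (onset O,
systolic peak P, dicrotic notch, diastolic peak D); beat-to-beat intervals
carry white HRV noise and a sinusoidal respiratory modulation, and the
mean rate climbs with the level.  The subject's perceived-stress score
(PSS) slows SCR recovery by inflating the kernel decay time, which is the
only PSS-physiology coupling modelled.

Every stochastic choice is keyed to ``(config.seed, subject_id)``, so a
session is bit-reproducible, and the full construction (tonic drive, SCR
events, beat times, noise realizations) is retained as ground truth.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from wearstress.session_io import (
    N_LEVELS,
    Recording,
    SessionEvents,
    write_channel,
    write_game_log,
)


class ConfigError(ValueError):
    """Raised when a session configuration is internally inconsistent."""


# number of on-screen selections offered per level (level 1 is the
# six-selection tutorial; later levels offer more, faster choices)
SELECTIONS_PER_LEVEL = (6, 8, 10, 10)


@dataclass
class SessionConfig:
    """Knobs of the synthetic study protocol.

    Defaults encode the study conditions: 3-min rest, four ~30 s levels
    (jittered ±20 % per subject), Empatica-E4 hardware rates (EDA 4 Hz,
    BVP 64 Hz), nondecreasing SCR rate and tonic increments across levels,
    and a PSS range matching the observed 6-26 span.
    """

    n_subjects: int = 23
    rest_duration: float = 180.0
    gap_duration: float = 15.0
    level_durations: tuple[float, float, float, float] = (30.0, 30.0, 30.0, 30.0)
    level_jitter: float = 0.2
    eda_fs: float = 4.0
    bvp_fs: float = 64.0
    tonic_baseline: float = 1.0
    tonic_level_increment: float = 0.5
    rest_scr_rate: float = 1.0
    scr_rate_per_level: tuple[float, float, float, float] = (4.0, 6.0, 8.0, 10.0)
    scr_amp_range: tuple[float, float] = (0.1, 0.6)
    scr_rise_tau: float = 0.7
    scr_decay_tau: float = 3.0
    hr_base: float = 70.0
    hr_level_slope: float = 1.5
    hr_level_sd: float = 2.0
    hrv_sd_ms: float = 15.0
    resp_mod_ms: float = 20.0
    resp_freq: float = 0.25
    pss_range: tuple[int, int] = (6, 26)
    pss_recovery_coupling: float = 0.04
    waveform_deformed: bool = False
    noise_sd_eda: float = 0.01
    noise_sd_bvp: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if len(self.level_durations) != N_LEVELS:
            raise ConfigError(f"need {N_LEVELS} level durations")
        positives = {
            "rest_duration": self.rest_duration,
            "eda_fs": self.eda_fs,
            "bvp_fs": self.bvp_fs,
            "scr_rise_tau": self.scr_rise_tau,
            "scr_decay_tau": self.scr_decay_tau,
            "hr_base": self.hr_base,
            "resp_freq": self.resp_freq,
        }
        for name, value in positives.items():
            if value <= 0:
                raise ConfigError(f"{name} must be strictly positive, got {value}")
        if any(d <= 0 for d in self.level_durations):
            raise ConfigError("level durations must be strictly positive")
        if self.scr_amp_range[0] <= 0.05:
            raise ConfigError(
                "scr_amp_range minimum must exceed the 0.05 µS significance floor"
            )
        if self.scr_amp_range[1] < self.scr_amp_range[0]:
            raise ConfigError("scr_amp_range must be (min, max) with min <= max")
        if any(r < 0 for r in self.scr_rate_per_level) or self.rest_scr_rate < 0:
            raise ConfigError("SCR rates must be nonnegative")
        if any(
            b < a
            for a, b in zip(self.scr_rate_per_level[:-1], self.scr_rate_per_level[1:])
        ):
            raise ConfigError("scr_rate_per_level must be nondecreasing across levels")
        if self.tonic_level_increment < 0:
            raise ConfigError("tonic_level_increment must be nonnegative")
        if not 0 <= self.pss_range[0] <= self.pss_range[1] <= 40:
            raise ConfigError("pss_range must lie within 0-40")
        # the bi-exponential SCR kernel needs room inside a level
        support = self.scr_rise_tau + 3.0 * self.scr_decay_tau
        min_dur = min(self.level_durations) * (1.0 - self.level_jitter)
        if min_dur < 2.0 * support:
            raise ConfigError(
                f"level duration {min_dur:.1f} s shorter than two SCR kernel "
                f"supports ({2 * support:.1f} s)"
            )


@dataclass
class SyntheticSession:
    """One generated subject session plus its construction ground truth."""

    subject_id: str
    eda: Recording
    bvp: Recording
    events: SessionEvents
    ground_truth: dict = field(default_factory=dict)


def _subject_rng(seed: int, subject_id: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), zlib.crc32(subject_id.encode())])


def scr_kernel(t: np.ndarray, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Bateman difference-of-exponentials, peak-normalized to 1, zero for t<0."""
    if decay_tau <= rise_tau:
        raise ConfigError("decay tau must exceed rise tau")
    out = np.where(t >= 0, np.exp(-np.maximum(t, 0) / decay_tau) - np.exp(-np.maximum(t, 0) / rise_tau), 0.0)
    t_peak = (np.log(decay_tau) - np.log(rise_tau)) / (1 / rise_tau - 1 / decay_tau)
    peak = np.exp(-t_peak / decay_tau) - np.exp(-t_peak / rise_tau)
    return out / peak


def _pulse_template(
    tau: np.ndarray,
    ibi: np.ndarray,
    deformed: bool,
    amp_scale_p: np.ndarray | float = 1.0,
    amp_scale_d: np.ndarray | float = 1.0,
) -> np.ndarray:
    """Pulse waveform at ``tau`` seconds after the beat onset.

    The systolic peak (P) and diastolic peak (D) sit at fixed delays
    after the onset — as in real pulse waves, where the systolic upstroke
    timing does not stretch with the cardiac cycle — followed by a
    diastolic runoff and a sharp foot (the next onset O) at the end of
    the ``ibi``-long beat.  The normal morphology has a dominant systolic
    peak; the deformed mode flattens P and raises D to near-equal
    amplitude so a naive positive-peak detector locks onto inconsistent
    landmarks, while the onset trough remains well defined.
    """
    if deformed:
        amp_p, sig_p, amp_d, sig_d = 0.52, 0.085, 0.62, 0.08
    else:
        amp_p, sig_p, amp_d, sig_d = 1.0, 0.055, 0.32, 0.09
    wave = amp_p * amp_scale_p * np.exp(-0.5 * ((tau - 0.22) / sig_p) ** 2)
    wave += amp_d * amp_scale_d * np.exp(-0.5 * ((tau - 0.45) / sig_d) ** 2)
    wave += 0.25 * np.exp(-tau / 0.4)
    wave -= 0.4 * np.exp(-0.5 * ((tau - (ibi - 0.08)) / 0.045) ** 2)
    return wave


def _session_timeline(
    config: SessionConfig, rng: np.random.Generator
) -> tuple[SessionEvents, float]:
    """Jittered per-subject protocol windows and the total recording span."""
    durations = [
        d * (1.0 + rng.uniform(-config.level_jitter, config.level_jitter))
        for d in config.level_durations
    ]
    rest = (0.0, config.rest_duration)
    start = config.rest_duration + config.gap_duration
    level_windows: dict[int, tuple[float, float]] = {}
    for lv, dur in enumerate(durations, start=1):
        level_windows[lv] = (start, start + dur)
        start += dur
    total = start + 5.0
    pss = int(rng.integers(config.pss_range[0], config.pss_range[1] + 1))
    skill = rng.beta(8.0, 2.0)
    points: dict[int, int] = {}
    errors: dict[int, int] = {}
    for lv in range(1, N_LEVELS + 1):
        n_sel = SELECTIONS_PER_LEVEL[lv - 1]
        pts = int(rng.binomial(n_sel, skill))
        points[lv] = pts
        errors[lv] = n_sel - pts
    events = SessionEvents(
        rest_window=rest,
        level_windows=level_windows,
        points=points,
        errors=errors,
        pss=pss,
    )
    return events, total


def _generate_eda(
    config: SessionConfig,
    events: SessionEvents,
    total: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict]:
    fs = config.eda_fs
    n = int(round(total * fs))
    t = np.arange(n) / fs

    # tonic drive: baseline + one increment per level start, smoothed
    drive = np.full(n, config.tonic_baseline)
    for lv in range(1, N_LEVELS + 1):
        start, _ = events.level_windows[lv]
        drive[t >= start] = config.tonic_baseline + lv * config.tonic_level_increment
    if config.tonic_level_increment > 0:
        drive = gaussian_filter1d(drive, sigma=8.0 * fs, mode="nearest")

    # sparse SCR train; decay slowed for high-PSS subjects
    decay_tau = config.scr_decay_tau * (1.0 + config.pss_recovery_coupling * events.pss)
    scr_sum = np.zeros(n)
    event_times: list[float] = []
    event_amps: list[float] = []
    event_levels: list[int] = []
    windows = [(0, events.rest_window, config.rest_scr_rate)] + [
        (lv, events.level_windows[lv], config.scr_rate_per_level[lv - 1])
        for lv in range(1, N_LEVELS + 1)
    ]
    for lv, (start, stop), rate in windows:
        duration = stop - start
        count = rng.poisson(rate * duration / 60.0)
        times = np.sort(rng.uniform(start, stop - 1.0, size=count))
        amps = rng.uniform(*config.scr_amp_range, size=count)
        for t0, amp in zip(times, amps):
            scr_sum += amp * scr_kernel(t - t0, config.scr_rise_tau, decay_tau)
            event_times.append(float(t0))
            event_amps.append(float(amp))
            event_levels.append(lv)

    noise = rng.normal(0.0, config.noise_sd_eda, size=n) if config.noise_sd_eda > 0 else np.zeros(n)
    eda = drive + scr_sum + noise

    tonic_level_means = {
        lv: float(np.mean(drive[(t >= events.level_windows[lv][0]) & (t < events.level_windows[lv][1])]))
        for lv in range(1, N_LEVELS + 1)
    }
    truth = {
        "tonic_drive": drive,
        "scr_sum": scr_sum,
        "eda_noise": noise,
        "scr_times": np.array(event_times),
        "scr_amps": np.array(event_amps),
        "scr_levels": np.array(event_levels, dtype=int),
        "scr_decay_tau": float(decay_tau),
        "tonic_level_means": tonic_level_means,
    }
    return eda, truth


def _generate_bvp(
    config: SessionConfig,
    events: SessionEvents,
    total: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict]:
    fs = config.bvp_fs

    # cardiac level response varies between subjects and levels — the
    # autonomic HR reaction to a stressor is far less uniform than the
    # electrodermal one
    level_offsets = {
        lv: config.hr_level_slope * lv
        + (config.hr_level_sd * rng.standard_normal() if config.hr_level_sd > 0 else 0.0)
        for lv in range(1, N_LEVELS + 1)
    }

    def heart_rate(at: float) -> float:
        for lv in range(1, N_LEVELS + 1):
            start, stop = events.level_windows[lv]
            if start <= at < stop:
                return config.hr_base + level_offsets[lv]
        return config.hr_base

    beat_times = [0.2]
    intervals: list[float] = []
    while beat_times[-1] < total:
        now = beat_times[-1]
        mean_ibi = 60.0 / heart_rate(now)
        ibi = (
            mean_ibi
            + (config.resp_mod_ms / 1000.0) * np.sin(2 * np.pi * config.resp_freq * now)
            + rng.normal(0.0, config.hrv_sd_ms / 1000.0)
        )
        ibi = float(np.clip(ibi, 0.3, 2.0))
        intervals.append(ibi)
        beat_times.append(now + ibi)
    beats = np.array(beat_times)

    n = int(round(total * fs))
    t = np.arange(n) / fs
    idx = np.clip(np.searchsorted(beats, t, side="right") - 1, 0, len(intervals) - 1)
    ibi_at = np.array(intervals)[idx]
    tau = np.clip(t - beats[idx], 0.0, ibi_at)
    if config.waveform_deformed:
        # beat-to-beat waviness of the near-equal P/D amplitudes, so the
        # dominant positive peak flips between landmarks across beats
        scale_p = 1.0 + 0.15 * rng.standard_normal(len(intervals))
        scale_d = 1.0 + 0.15 * rng.standard_normal(len(intervals))
        bvp = _pulse_template(
            tau, ibi_at, True, scale_p[idx], scale_d[idx]
        )
    else:
        bvp = _pulse_template(tau, ibi_at, False)
    noise = rng.normal(0.0, config.noise_sd_bvp, size=n) if config.noise_sd_bvp > 0 else np.zeros(n)
    bvp = bvp + noise

    truth = {
        "beat_times": beats[:-1],
        "beat_intervals_ms": 1000.0 * np.array(intervals),
        "resp_freq": config.resp_freq,
        "bvp_noise": noise,
    }
    return bvp, truth


def generate_session(config: SessionConfig, subject_id: str) -> SyntheticSession:
    """Generate one subject session, deterministic in (config.seed, subject_id)."""
    rng = _subject_rng(config.seed, subject_id)
    events, total = _session_timeline(config, rng)
    eda, eda_truth = _generate_eda(config, events, total, rng)
    bvp, bvp_truth = _generate_bvp(config, events, total, rng)
    start_unix = 1_600_000_000.0
    session = SyntheticSession(
        subject_id=subject_id,
        eda=Recording("EDA", start_unix, config.eda_fs, eda),
        bvp=Recording("BVP", start_unix, config.bvp_fs, bvp),
        events=events,
        ground_truth={**eda_truth, **bvp_truth},
    )
    beats = session.ground_truth["beat_times"]
    assert np.all(np.diff(beats) > 0), "ground-truth beat times must increase"
    return session


def generate_cohort(config: SessionConfig):
    """Generate one session per subject plus the cohort PSS table.

    Returns ``(sessions, pss_table)`` where ``pss_table`` is a list of
    ``(subject_id, pss)`` pairs in cohort order.
    """
    sessions = [
        generate_session(config, f"S{i + 1:02d}") for i in range(config.n_subjects)
    ]
    pss_table = [(s.subject_id, s.events.pss) for s in sessions]
    return sessions, pss_table


def write_session(session: SyntheticSession, out_dir: str | Path) -> Path:
    """Write a session to disk: channel CSVs, game-log JSON, truth sidecar."""
    out = Path(out_dir) / session.subject_id
    out.mkdir(parents=True, exist_ok=True)
    write_channel(out / "EDA.csv", session.eda)
    write_channel(out / "BVP.csv", session.bvp)
    write_game_log(out / "events.json", session.events, session.eda.start_time)
    truth = {
        k: (v.tolist() if isinstance(v, np.ndarray) else v)
        for k, v in session.ground_truth.items()
        if k in ("scr_times", "scr_amps", "scr_levels", "scr_decay_tau",
                 "tonic_level_means", "beat_times", "beat_intervals_ms", "resp_freq")
    }
    (out / "ground_truth.json").write_text(json.dumps(truth))
    return out
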