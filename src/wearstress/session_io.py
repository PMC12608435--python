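"""On-disk session formats.

Channels follow the Empatica-style CSV dialect: the first row carries the
unix start time, the second row the sampling frequency in Hz, and every
following row one sample.  Game logs are JSON documents with one entry per
game level (start/stop unix timestamps, points, errors), a rest window and
the subject's perceived-stress (PSS) score.  Feature tables are tidy CSV,
one row per (subject, level).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

N_LEVELS = 4


class SessionIOError(ValueError):
    """Raised on malformed channel files or game logs."""


@dataclass
class Recording:
    """One uniformly sampled channel.

    Parameters
    ----------
    channel:
        ``"EDA"`` (µS) or ``"BVP"`` (arbitrary units).
    start_time:
        Unix start time in seconds.
    fs:
        Sampling rate in Hz, strictly positive.
    samples:
        Sample values; must be non-empty and free of missing values.
    """

    channel: str
    start_time: float
    fs: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.channel not in ("EDA", "BVP"):
            raise SessionIOError(f"unknown channel {self.channel!r}")
        if self.fs <= 0:
            raise SessionIOError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.size == 0:
            raise SessionIOError("empty signal body")
        if not np.all(np.isfinite(self.samples)):
            raise SessionIOError("signal contains missing or non-finite values")

    @property
    def duration(self) -> float:
        """Recorded span in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to the recording start."""
        return np.arange(self.samples.size) / self.fs

    def slice_window(self, start: float, stop: float) -> np.ndarray:
        """Samples in the half-open window [start, stop) seconds (relative)."""
        i0 = int(round(start * self.fs))
        i1 = int(round(stop * self.fs))
        if i0 < 0 or i1 > self.samples.size or i1 <= i0:
            raise SessionIOError(
                f"window [{start}, {stop}) s outside recording span 0-{self.duration} s"
            )
        return self.samples[i0:i1]


@dataclass
class SessionEvents:
    """Protocol structure of one session, in recording-relative seconds.

    Windows are half-open ``[start, stop)``.  ``level_windows`` maps level
    index (1-4) to its window; points/errors are per-level counts and
    ``pss`` is the subject's 0-40 perceived-stress score.
    """

    rest_window: tuple[float, float]
    level_windows: dict[int, tuple[float, float]]
    points: dict[int, int] = field(default_factory=dict)
    errors: dict[int, int] = field(default_factory=dict)
    pss: int = 0

    def __post_init__(self) -> None:
        if sorted(self.level_windows) != list(range(1, N_LEVELS + 1)):
            raise SessionIOError(
                f"expected {N_LEVELS} levels, got {sorted(self.level_windows)}"
            )
        windows = [self.rest_window] + [self.level_windows[k] for k in range(1, N_LEVELS + 1)]
        for start, stop in windows:
            if stop <= start:
                raise SessionIOError(f"degenerate window [{start}, {stop})")
        for (_, s0), (s1, _) in zip(windows[:-1], windows[1:]):
            if s1 < s0:
                raise SessionIOError("windows overlap or are out of order")
        for level in range(1, N_LEVELS + 1):
            if self.points.get(level, 0) < 0 or self.errors.get(level, 0) < 0:
                raise SessionIOError(f"negative points/errors in level {level}")
        if not 0 <= self.pss <= 40:
            raise SessionIOError(f"PSS score {self.pss} outside 0-40")

    def level_duration(self, level: int) -> float:
        start, stop = self.level_windows[level]
        return stop - start

    @property
    def span(self) -> tuple[float, float]:
        """From rest start to level-4 stop (the analysis window)."""
        return self.rest_window[0], self.level_windows[N_LEVELS][1]


def read_channel(path: str | Path, channel: str) -> Recording:
    """Read one Empatica-dialect channel CSV.

    Row 1 is the unix start time, row 2 the sampling rate, rows 3+ the
    samples.  Raises :class:`SessionIOError` identifying the offending
    line on malformed input.
    """
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if len(lines) < 2:
        raise SessionIOError(f"{path}: missing header rows")
    try:
        start_time = float(lines[0])
        fs = float(lines[1])
    except ValueError as exc:
        raise SessionIOError(f"{path}: non-numeric header: {exc}") from exc
    if fs <= 0:
        raise SessionIOError(f"{path}: sampling rate must be positive, got {fs}")
    if len(lines) == 2:
        raise SessionIOError(f"{path}: empty signal body")
    try:
        samples = np.array([float(v) for v in lines[2:]], dtype=float)
    except ValueError:
        for i, v in enumerate(lines[2:], start=3):
            try:
                float(v)
            except ValueError:
                raise SessionIOError(f"{path}: non-numeric sample at line {i}: {v!r}") from None
        raise
    return Recording(channel=channel, start_time=start_time, fs=fs, samples=samples)


def write_channel(path: str | Path, recording: Recording, decimals: int = 6) -> None:
    """Write a channel in the Empatica-style dialect (inverse of read_channel)."""
    path = Path(path)
    body = "\n".join(f"{v:.{decimals}f}" for v in recording.samples)
    path.write_text(f"{recording.start_time:.6f}\n{recording.fs:g}\n{body}\n")


def read_game_log(path: str | Path, recording_start: float | None = None) -> SessionEvents:
    """Read a game-log JSON into recording-relative :class:`SessionEvents`.

    The log stores unix timestamps; when ``recording_start`` is given it is
    subtracted, otherwise the log's own ``recording_start`` field is used.
    """
    path = Path(path)
    doc = json.loads(path.read_text())
    if recording_start is None:
        recording_start = float(doc["recording_start"])
    levels = doc.get("levels", [])
    if len(levels) != N_LEVELS:
        raise SessionIOError(f"{path}: expected {N_LEVELS} levels, got {len(levels)}")
    level_windows: dict[int, tuple[float, float]] = {}
    points: dict[int, int] = {}
    errors: dict[int, int] = {}
    for entry in levels:
        lv = int(entry["level"])
        level_windows[lv] = (
            float(entry["start_unix"]) - recording_start,
            float(entry["stop_unix"]) - recording_start,
        )
        points[lv] = int(entry["points"])
        errors[lv] = int(entry["errors"])
    rest = doc["rest"]
    rest_window = (
        float(rest["start_unix"]) - recording_start,
        float(rest["stop_unix"]) - recording_start,
    )
    return SessionEvents(
        rest_window=rest_window,
        level_windows=level_windows,
        points=points,
        errors=errors,
        pss=int(doc.get("pss", 0)),
    )


def write_game_log(path: str | Path, events: SessionEvents, recording_start: float) -> None:
    """Write a game log JSON (inverse of :func:`read_game_log`)."""
    doc = {
        "recording_start": recording_start,
        "pss": int(events.pss),
        "rest": {
            "start_unix": recording_start + events.rest_window[0],
            "stop_unix": recording_start + events.rest_window[1],
        },
        "levels": [
            {
                "level": lv,
                "start_unix": recording_start + events.level_windows[lv][0],
                "stop_unix": recording_start + events.level_windows[lv][1],
                "points": int(events.points.get(lv, 0)),
                "errors": int(events.errors.get(lv, 0)),
            }
            for lv in range(1, N_LEVELS + 1)
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def write_feature_table(path: str | Path, table: pd.DataFrame) -> None:
    """Write the tidy per-(subject, level) feature table as CSV."""
    table.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature table CSV; validates key columns."""
    table = pd.read_csv(path)
    for col in ("subject_id", "level"):
        if col not in table.columns:
            raise SessionIOError(f"{path}: missing required column {col!r}")
    return table


def level_labels(n_levels: int = N_LEVELS) -> Sequence[int]:
    return list(range(1, n_levels + 1))
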