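"""Assembly of the per-(subject, level) feature table.

One row per subject and game level; 95 feature columns (39 EDA-side, 28
per beat landmark for the systolic-peak ``pp`` and onset ``oo`` series)
plus metadata (PSS score, per-level points/errors/duration and a
``spectral_valid`` flag marking level windows long enough for the
spectral estimates).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from wearstress import eda as eda_mod
from wearstress.eda_features import SPECTRAL_MIN_DURATION_S, eda_level_features
from wearstress.hrv import landmark_features
from wearstress.session_io import (
    N_LEVELS,
    Recording,
    SessionEvents,
    read_channel,
    read_game_log,
)
from wearstress.synth import SyntheticSession

_EDA_STATS = ["Mean", "Std", "Median", "Kurt", "Skew", "Range", "Max"]
_SPECTRAL = ["PB5", "P90", "Pmax", "Pstd"]
_HRV_RAW = [
    "bpm", "ibi", "sdnn", "sdsd", "rmssd", "pnn20", "pnn50",
    "mad", "sd1", "sd2", "s", "sd1/sd2", "breathingrate",
]
_HRV_PRUNED = [
    "meanPP", "medianPP", "sdPP", "madPP", "iqr", "rangePP", "cvPP",
    "rmssdPP", "sdsdPP", "pnn20PP", "pnn50PP", "sd1PP", "sd2PP",
    "sd1/sd2PP", "sPP",
]

#: the documented 95-column feature inventory
FEATURE_INVENTORY: list[str] = (
    [f"{p}{s}" for p in ("EDA", "cvxT", "cvxP") for s in _EDA_STATS]
    + ["DerMean", "Dermax", "NegDerMean"]
    + ["EDAActivity", "EDAMobility"]
    + ["EDAEn", "EDAapEn", "EDAsaEn", "EDAlyapExp"]
    + [f"{p}{s}" for p in ("EDA", "cvxP") for s in _SPECTRAL]
    + ["SCRRate"]
    + [f"{lm}{s}" for lm in ("pp", "oo") for s in _HRV_RAW + _HRV_PRUNED]
)

METADATA_COLUMNS = [
    "subject_id", "level", "pss", "points", "errors", "duration", "spectral_valid",
]


def feature_columns(table: pd.DataFrame) -> list[str]:
    """The feature columns of a table (everything not metadata)."""
    return [c for c in table.columns if c not in METADATA_COLUMNS]


def session_feature_rows(
    eda: Recording,
    bvp: Recording,
    events: SessionEvents,
    subject_id: str,
    decomposition: eda_mod.EDADecomposition | None = None,
) -> list[dict]:
    """Feature rows (one per level) for a single session."""
    if decomposition is None:
        decomposition = eda_mod.decompose_session(eda, events)
    span_start, _ = events.span
    fs = eda.fs
    rows = []
    for level in range(1, N_LEVELS + 1):
        start, stop = events.level_windows[level]
        i0 = int(round((start - span_start) * fs))
        i1 = int(round((stop - span_start) * fs))
        row: dict = {
            "subject_id": subject_id,
            "level": level,
            "pss": events.pss,
            "points": events.points.get(level, 0),
            "errors": events.errors.get(level, 0),
            "duration": stop - start,
            "spectral_valid": (stop - start) >= SPECTRAL_MIN_DURATION_S,
        }
        row.update(
            eda_level_features(
                decomposition.z[i0:i1],
                decomposition.tonic[i0:i1],
                decomposition.phasic[i0:i1],
                decomposition.driver[i0:i1],
                fs,
            )
        )
        for landmark, prefix in (("P", "pp"), ("O", "oo")):
            feats = landmark_features(bvp, (start, stop), landmark)
            row.update({f"{prefix}{k}": v for k, v in feats.items()})
        rows.append(row)
    return rows


def build_feature_table(sessions: list[SyntheticSession]) -> pd.DataFrame:
    """Feature table for a cohort of in-memory sessions."""
    rows: list[dict] = []
    for session in sessions:
        rows.extend(
            session_feature_rows(
                session.eda, session.bvp, session.events, session.subject_id
            )
        )
    table = pd.DataFrame(rows)
    return table[METADATA_COLUMNS + [c for c in FEATURE_INVENTORY if c in table.columns]]


def build_feature_table_from_dir(root: str | Path) -> pd.DataFrame:
    """Feature table for sessions written to disk (one directory per subject)."""
    rows: list[dict] = []
    for subject_dir in sorted(Path(root).iterdir()):
        if not (subject_dir / "EDA.csv").exists():
            continue
        eda = read_channel(subject_dir / "EDA.csv", "EDA")
        bvp = read_channel(subject_dir / "BVP.csv", "BVP")
        events = read_game_log(subject_dir / "events.json", eda.start_time)
        rows.extend(session_feature_rows(eda, bvp, events, subject_dir.name))
    table = pd.DataFrame(rows)
    return table[METADATA_COLUMNS + [c for c in FEATURE_INVENTORY if c in table.columns]]
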