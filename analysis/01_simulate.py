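"""Step 1 — simulate the study cohort.

Generates one synthetic session per subject (23 by default): a 3-minute
rest, then four ~30 s game levels with level-graded tonic drive, SCR
rate, and heart-rate response, recorded as wrist-device EDA (4 Hz) and
BVP (64 Hz) channels plus a game-log JSON and the subject's PSS score.
Sessions are written under ``data/sessions/<subject>/`` in the same
layout the extraction step reads back.
"""

from __future__ import annotations

import argparse
from pathlib import Path

import pandas as pd

from wearstress.synth import SessionConfig, generate_cohort, write_session


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--subjects", type=int, default=23)
    parser.add_argument("--out", type=Path, default=Path("data/sessions"))
    args = parser.parse_args()

    config = SessionConfig(n_subjects=args.subjects, seed=args.seed)
    sessions, pss_table = generate_cohort(config)
    for session in sessions:
        write_session(session, args.out)
    args.out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(pss_table, columns=["subject_id", "pss"]).to_csv(
        args.out / "pss.csv", index=False
    )
    print(f"wrote {len(sessions)} sessions to {args.out} (seed {args.seed})")


if __name__ == "__main__":
    main()
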