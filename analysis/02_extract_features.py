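"""Step 2 — quality-gate the recordings and extract the feature table.

Each session's EDA channel is checked against the signal-quality gate
(low/high band SNR >= 20 dB, variance >= 0.001 µS²), filtered, windowed
over rest through level 4, z-scored and split into tonic/phasic/driver
components by the convex decomposition.  Per (subject, level) the 95
documented features are computed: 39 EDA-side and 28 HRV features per
beat landmark (systolic peak ``pp`` and onset ``oo``).

Writes ``results/quality_report.csv`` and ``results/features.csv``.
"""

from __future__ import annotations

import argparse
from pathlib import Path

import pandas as pd

from wearstress.eda import quality_gate
from wearstress.features import build_feature_table_from_dir
from wearstress.session_io import read_channel, write_feature_table


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--sessions", type=Path, default=Path("data/sessions"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    qc_rows = []
    for subject_dir in sorted(args.sessions.iterdir()):
        if not (subject_dir / "EDA.csv").exists():
            continue
        report = quality_gate(read_channel(subject_dir / "EDA.csv", "EDA"))
        qc_rows.append(
            {
                "subject_id": subject_dir.name,
                "snr_db": report.snr_db,
                "variance_us2": report.variance,
                "passed": report.passed,
                "reasons": ";".join(report.reasons),
            }
        )
    qc = pd.DataFrame(qc_rows)
    qc.to_csv(args.out / "quality_report.csv", index=False)
    print(f"quality gate: {int(qc['passed'].sum())}/{len(qc)} sessions pass")

    table = build_feature_table_from_dir(args.sessions)
    write_feature_table(args.out / "features.csv", table)
    print(
        f"feature table: {len(table)} rows x {table.shape[1]} columns "
        f"-> {args.out / 'features.csv'}"
    )


if __name__ == "__main__":
    main()
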