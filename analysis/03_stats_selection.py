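"""Step 3 — level statistics, correlation clustering and feature ranking.

Collinear features (|Spearman rho| > 0.8, p < 0.05, single linkage) are
clustered and one representative per cluster is kept.  Each
representative is tested for a game-level effect with a normality-gated
within-subject test (RM-ANOVA with generalized eta-squared, or Friedman
with Kendall's W) plus Bonferroni-corrected post hocs over the six level
pairs.  Significant features are ranked by the number of significant
pairs, then by |Spearman| correlation with the level label, into the
top-3/5/7 candidate sets.

Writes ``results/clusters.csv``, ``results/statistics.csv`` and
``results/feature_sets.json``.
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from wearstress.features import feature_columns
from wearstress.session_io import read_feature_table
from wearstress.stats import (
    cluster_select,
    level_effect_test,
    rank_features,
    statistics_report,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--features", type=Path, default=Path("results/features.csv"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    table = read_feature_table(args.features)
    feats = [f for f in feature_columns(table) if np.isfinite(table[f]).all()]
    dropped = sorted(set(feature_columns(table)) - set(feats))
    if dropped:
        print(f"dropped {len(dropped)} features with missing values: {dropped}")

    selection = cluster_select(table, feats, target="level")
    pd.DataFrame(
        {
            "cluster": np.arange(len(selection.clusters)),
            "representative": selection.representatives,
            "members": [";".join(c) for c in selection.clusters],
        }
    ).to_csv(args.out / "clusters.csv", index=False)
    print(
        f"{len(feats)} features -> {len(selection.clusters)} clusters "
        f"({len(selection.representatives)} representatives)"
    )

    results = [
        level_effect_test(table[f], table["subject_id"], table["level"])
        for f in selection.representatives
    ]
    report = statistics_report(results).sort_values(
        ["PHC", "W/ng2"], ascending=False
    )
    report.to_csv(args.out / "statistics.csv", index=False)
    print(report.head(10).to_string(index=False))

    sets = rank_features(results, table)
    (args.out / "feature_sets.json").write_text(
        json.dumps({str(k): v for k, v in sets.items()}, indent=2)
    )
    print(f"top-3 set: {sets[3]}")


if __name__ == "__main__":
    main()
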