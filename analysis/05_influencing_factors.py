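"""Step 5 — in-game performance and baseline stress as influencing factors.

Performance ((points − errors) / level duration) enters a per-feature
linear mixed model ``feature ~ C(level) + performance`` with a random
intercept per subject; performance-slope p-values get Bonferroni and
Benjamini–Hochberg corrections.  Subject-level (level-averaged) features
are correlated with mean performance and with the PSS score, and the
EDA recovery speed (NegDerMean) is tabulated per level for the low vs
moderate PSS groups.

Writes ``results/lmm_performance.csv``,
``results/correlations_performance.csv``,
``results/correlations_pss.csv`` and ``results/pss_group_contrast.csv``.
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import pandas as pd

from wearstress.factors import (
    add_performance,
    fit_performance_lmm,
    pss_group_contrast,
    subject_level_correlations,
    subject_summaries,
)
from wearstress.session_io import read_feature_table


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--features", type=Path, default=Path("results/features.csv"))
    parser.add_argument(
        "--feature-sets", type=Path, default=Path("results/feature_sets.json")
    )
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    table = add_performance(read_feature_table(args.features))
    candidates = json.loads(args.feature_sets.read_text())["7"]

    lmm = fit_performance_lmm(table, candidates)
    pd.DataFrame(
        [
            {
                "feature": r.feature,
                "performance_slope": r.performance_coef,
                "p": r.p_unc,
                "p_bonferroni": r.p_bonf,
                "p_fdr_bh": r.p_fdr,
                "converged": r.converged,
            }
            for r in lmm
        ]
    ).to_csv(args.out / "lmm_performance.csv", index=False)
    n_sig = sum(r.converged and r.p_fdr < 0.05 for r in lmm)
    print(f"LMM: {n_sig}/{len(lmm)} candidate features keep a performance effect (FDR)")

    summaries = subject_summaries(table)
    feats = candidates + (["NegDerMean"] if "NegDerMean" not in candidates else [])
    subject_level_correlations(summaries, feats, "performance").to_csv(
        args.out / "correlations_performance.csv", index=False
    )
    pss_corr = subject_level_correlations(summaries, feats, "pss")
    pss_corr.to_csv(args.out / "correlations_pss.csv", index=False)
    print(pss_corr.to_string(index=False))

    pss_group_contrast(table).to_csv(args.out / "pss_group_contrast.csv", index=False)
    print(f"wrote influencing-factor tables to {args.out}")


if __name__ == "__main__":
    main()
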