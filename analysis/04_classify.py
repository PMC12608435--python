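"""Step 4 — leave-one-subject-out stress-level classification.

For the selected feature set, each model family (SVM, random forest,
kNN, gradient-boosted trees) is evaluated with nested LOSO
cross-validation: the outer loop holds out every row of one subject,
the inner loop tunes hyperparameters by Gaussian-process search on
stratified 3-fold accuracy.  Runs are repeated over seeds and averaged.
Feature attribution uses exact Shapley values against the training-fold
median.

Writes per-model ``results/metrics_<model>.csv``,
``results/confusion_<model>.csv`` and ``results/attribution_<model>.csv``.
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import pandas as pd

from wearstress.classify import MODELS, aggregate_runs, loso_nested_cv
from wearstress.session_io import read_feature_table


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--features", type=Path, default=Path("results/features.csv"))
    parser.add_argument(
        "--feature-sets", type=Path, default=Path("results/feature_sets.json")
    )
    parser.add_argument("--set-size", type=int, default=3, choices=(3, 5, 7))
    parser.add_argument("--models", default="knn", help="comma list or 'all'")
    parser.add_argument("--seeds", type=int, default=5)
    parser.add_argument("--iterations", type=int, default=15)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    table = read_feature_table(args.features)
    feature_set = json.loads(args.feature_sets.read_text())[str(args.set_size)]
    models = list(MODELS) if args.models == "all" else args.models.split(",")

    for model in models:
        runs = [
            loso_nested_cv(
                table, feature_set, model=model, seed=s, n_iter=args.iterations
            )
            for s in range(args.seeds)
        ]
        pd.DataFrame(
            [r.metrics | {"seed": r.seed} for r in runs]
        ).to_csv(args.out / f"metrics_{model}.csv", index=False)
        if len(runs) > 1:
            summary = aggregate_runs(runs)
            confusion = summary.mean_confusion
            attribution = summary.attribution_ranking
            acc = summary.metric_means["accuracy"]
            sd = summary.metric_sds["accuracy"]
        else:
            confusion = runs[0].confusion
            attribution = sorted(runs[0].attribution.items(), key=lambda kv: -kv[1])
            acc, sd = runs[0].metrics["accuracy"], 0.0
        pd.DataFrame(
            confusion,
            index=[f"true_{lv}" for lv in range(1, 5)],
            columns=[f"pred_{lv}" for lv in range(1, 5)],
        ).to_csv(args.out / f"confusion_{model}.csv")
        pd.DataFrame(attribution, columns=["feature", "mean_abs_shapley"]).to_csv(
            args.out / f"attribution_{model}.csv", index=False
        )
        print(f"{model}: accuracy {acc:.3f} ± {sd:.3f} on {feature_set}")


if __name__ == "__main__":
    main()
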