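"""LOSO cross-validation, hyperparameter search and attribution."""

from __future__ import annotations

import numpy as np
import pytest

from tests.conftest import separable_table
from wearstress.classify import (
    MODELS,
    _decode_labels,
    _encode_labels,
    aggregate_runs,
    exact_shapley,
    gp_minimize_unit,
    loso_nested_cv,
)


class TestValidation:
    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown model"):
            loso_nested_cv(separable_table(4), ["f1"], model="mlp")

    def test_requires_one_row_per_level(self):
        table = separable_table(4).drop(index=0)
        with pytest.raises(ValueError, match="one row per level"):
            loso_nested_cv(table, ["f1"], model="knn")

    def test_missing_feature_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            loso_nested_cv(separable_table(4), ["f1", "zz"], model="knn")

    def test_needs_two_subjects(self):
        with pytest.raises(ValueError, match="2 subjects"):
            loso_nested_cv(separable_table(1), ["f1"], model="knn")


class TestLOSO:
    @pytest.mark.parametrize("model", MODELS)
    def test_every_model_separates_easy_cohort(self, model):
        table = separable_table(8)
        run = loso_nested_cv(
            table, ["f1", "f2", "f3"], model=model, seed=0, n_iter=5,
            compute_attribution=False,
        )
        assert run.metrics["accuracy"] >= 0.9
        assert run.confusion.shape == (4, 4)
        assert run.confusion.sum() == len(table)

    def test_predictions_cover_every_row_once(self):
        table = separable_table(6)
        run = loso_nested_cv(
            table, ["f1", "f2"], model="knn", seed=0, n_iter=5,
            compute_attribution=False,
        )
        assert len(run.predictions) == len(table)
        assert set(run.predictions["subject_id"]) == set(table["subject_id"])

    def test_metrics_include_ovr_auc_and_f1(self):
        run = loso_nested_cv(
            separable_table(6), ["f1"], model="knn", seed=0, n_iter=5,
            compute_attribution=False,
        )
        assert {"accuracy", "precision", "recall", "f1", "auc_ovr"} <= set(run.metrics)
        assert 0.0 <= run.metrics["auc_ovr"] <= 1.0

    def test_attribution_ranks_informative_feature_first(self):
        table = separable_table(8)
        rng = np.random.default_rng(0)
        table["junk"] = rng.normal(size=len(table))
        run = loso_nested_cv(
            table, ["f1", "junk"], model="rf", seed=0, n_iter=5,
            compute_attribution=True,
        )
        assert run.attribution["f1"] > run.attribution["junk"]


class TestLabels:
    def test_encode_decode_round_trip(self):
        y = np.array([1, 4, 2, 3, 1])
        enc = _encode_labels(y)
        assert enc.min() == 0 and enc.max() == 3
        assert np.array_equal(_decode_labels(enc), y)


class TestShapley:
    def test_values_satisfy_efficiency(self):
        from sklearn.ensemble import RandomForestClassifier

        table = separable_table(8)
        X = table[["f1", "f2", "f3"]].to_numpy()
        y = table["level"].to_numpy()
        model = RandomForestClassifier(n_estimators=20, random_state=0).fit(X, y)
        x = X[:3]
        background = np.median(X, axis=0)
        phis = exact_shapley(model, x, background)
        assert phis.shape == (3, 3)
        # efficiency: attributions sum to f(x) - f(background) for the
        # predicted class of each row
        for row in range(3):
            cls = int(np.argmax(model.predict_proba(x[row : row + 1])[0]))
            full = model.predict_proba(x[row : row + 1])[0, cls]
            base = model.predict_proba(background[None, :])[0, cls]
            assert phis[row].sum() == pytest.approx(full - base, abs=1e-8)


class TestSearch:
    def test_gp_search_locates_quadratic_optimum(self):
        target = np.array([0.3, 0.7])

        def objective(u: np.ndarray) -> float:
            return -float(np.sum((u - target) ** 2))

        rng = np.random.default_rng(0)
        best_u = gp_minimize_unit(objective, n_dims=2, n_iter=25, rng=rng)
        assert np.all((best_u >= 0) & (best_u <= 1))
        assert objective(best_u) >= -0.02


class TestAggregation:
    def test_seed_average_and_config_mismatch(self):
        table = separable_table(6)
        runs = [
            loso_nested_cv(table, ["f1", "f2"], model="knn", seed=s, n_iter=5,
                           compute_attribution=False)
            for s in range(2)
        ]
        summary = aggregate_runs(runs)
        assert summary.metric_means["accuracy"] == pytest.approx(
            np.mean([r.metrics["accuracy"] for r in runs])
        )
        assert summary.mean_confusion.shape == (4, 4)
        other = loso_nested_cv(table, ["f1"], model="knn", seed=0, n_iter=5,
                               compute_attribution=False)
        with pytest.raises(ValueError, match="mismatched"):
            aggregate_runs([runs[0], other])
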