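"""Level-effect statistics, correlation clustering and feature ranking."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from statsmodels.stats.anova import AnovaRM

from wearstress.stats import (
    cluster_select,
    friedman_statistic,
    level_effect_test,
    rank_features,
    statistics_report,
)


def _long(data: np.ndarray, name: str = "feat"):
    n, k = data.shape
    values = pd.Series(data.ravel(), name=name)
    subjects = pd.Series(np.repeat(np.arange(n), k))
    levels = pd.Series(np.tile(np.arange(1, k + 1), n))
    return values, subjects, levels


class TestFriedman:
    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(7)
        data = np.round(rng.normal(size=(8, 4)), 1)
        q, _ = friedman_statistic(data)
        q_ref, _ = sps.friedmanchisquare(*[data[:, j] for j in range(4)])
        assert q == pytest.approx(q_ref, abs=1e-12)

    def test_identical_conditions_give_zero(self):
        data = np.tile(np.arange(5.0)[:, None], (1, 4))
        q, w = friedman_statistic(data)
        assert q == 0.0
        assert w == 0.0


class TestLevelEffect:
    def test_rm_anova_branch_matches_statsmodels(self):
        rng = np.random.default_rng(0)
        n = 15
        data = rng.normal(size=(n, 4)) + np.array([0.0, 0.3, 0.6, 0.9])
        result = level_effect_test(*_long(data))
        if result.test == "RM-ANOVA":
            long = pd.DataFrame(
                {
                    "y": data.ravel(),
                    "subject": np.repeat(np.arange(n), 4),
                    "level": np.tile(np.arange(4), n),
                }
            )
            table = AnovaRM(long, "y", "subject", within=["level"]).fit().anova_table
            assert result.statistic == pytest.approx(
                float(table["F Value"].iloc[0]), rel=1e-9
            )
            assert result.p == pytest.approx(
                float(table["Pr > F"].iloc[0]), rel=1e-9
            )
        else:  # normality gate rejected this draw; the statistic is Friedman's
            q_ref, _ = sps.friedmanchisquare(*[data[:, j] for j in range(4)])
            assert result.statistic == pytest.approx(q_ref, abs=1e-9)

    def test_skewed_data_takes_friedman_branch(self):
        rng = np.random.default_rng(1)
        data = rng.lognormal(sigma=1.5, size=(12, 4))
        result = level_effect_test(*_long(data))
        assert result.test == "Friedman"

    def test_strong_graded_effect_flags_many_pairs(self):
        rng = np.random.default_rng(2)
        n = 20
        data = np.arange(1, 5) * 2.0 + rng.normal(0, 0.2, size=(n, 4))
        result = level_effect_test(*_long(data))
        assert result.p < 1e-4
        assert result.n_significant_pairs == 6

    def test_requires_three_complete_subjects(self):
        data = np.random.default_rng(3).normal(size=(2, 4))
        with pytest.raises(ValueError, match="3 complete"):
            level_effect_test(*_long(data))


class TestClusterSelect:
    def _table(self):
        rng = np.random.default_rng(4)
        n = 20
        rows = []
        for i in range(n):
            for level in range(1, 5):
                base = level + rng.normal(0, 0.1)
                rows.append(
                    {
                        "subject_id": f"S{i}",
                        "level": level,
                        "a": base,
                        "a_copy": 2.0 * base + 1.0,  # perfectly correlated with a
                        "b": rng.normal(),
                    }
                )
        return pd.DataFrame(rows)

    def test_collinear_features_share_a_cluster(self):
        table = self._table()
        selection = cluster_select(table, ["a", "a_copy", "b"], target="level")
        collinear = next(c for c in selection.clusters if "a" in c)
        assert set(collinear) == {"a", "a_copy"}
        assert ["b"] in selection.clusters
        assert len(selection.representatives) == 2

    def test_representative_is_most_label_correlated(self):
        table = self._table()
        selection = cluster_select(table, ["a", "a_copy", "b"], target="level")
        rep = next(
            r for r in selection.representatives if r in ("a", "a_copy")
        )
        # both carry identical label information; ties break by name
        assert rep in ("a", "a_copy")


class TestRanking:
    def test_orders_by_pairs_then_label_correlation(self):
        rng = np.random.default_rng(5)
        n = 20
        rows = []
        for i in range(n):
            for level in range(1, 5):
                rows.append(
                    {
                        "subject_id": f"S{i}",
                        "level": level,
                        "strong": level + rng.normal(0, 0.1),
                        "weak": level + rng.normal(0, 2.0),
                        "noise": rng.normal(),
                    }
                )
        table = pd.DataFrame(rows)
        results = [
            level_effect_test(table[f], table["subject_id"], table["level"])
            for f in ("strong", "weak", "noise")
        ]
        ranked = rank_features(results, table)
        assert ranked[3][0] == "strong"
        assert "noise" not in ranked[3]
        assert ranked[5] == ranked[7]  # only two significant features exist

    def test_report_has_one_row_per_feature(self):
        rng = np.random.default_rng(6)
        data = rng.normal(size=(10, 4))
        results = [level_effect_test(*_long(data, name=f"f{i}")) for i in range(3)]
        report = statistics_report(results)
        assert list(report["Feature"]) == ["f0", "f1", "f2"]
        assert set(report.columns) >= {"Test", "W/ng2", "Q/F", "p", "PHC"}
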