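"""Feature selection and within-subject level statistics.

Redundant features are grouped by single-linkage correlation clustering
(two features join a cluster when their Spearman |rho| exceeds 0.8 with
p < 0.05 against any member), and each cluster is represented by the
member best correlated with the target (the level label, or the
performance score for the confound analysis).

Each surviving feature is tested for a game-level effect within subjects:
a Shapiro-Wilk gate per level routes normally distributed features to
repeated-measures ANOVA (F, generalized eta-squared) with paired t post
hocs, and the rest to the Friedman test (tie-corrected Q, Kendall's W)
with pairwise Wilcoxon signed-rank post hocs; post hoc p-values are
Bonferroni-corrected over the six level pairs.  Features are finally
ranked by (number of significant post hoc pairs, |label correlation|)
into top-3/5/7 sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from wearstress.session_io import N_LEVELS

LEVEL_PAIRS = list(combinations(range(1, N_LEVELS + 1), 2))


@dataclass
class StatTestResult:
    """Level-effect test outcome for one feature."""

    feature: str
    test: str  # "RM-ANOVA" or "Friedman"
    statistic: float  # F or Q
    effect_size: float  # generalized eta-squared or Kendall's W
    p: float
    posthoc_pairs: list[tuple[int, int]] = field(default_factory=list)
    posthoc_p: dict[tuple[int, int], float] = field(default_factory=dict)

    @property
    def n_significant_pairs(self) -> int:
        return len(self.posthoc_pairs)


@dataclass
class SelectionResult:
    """Correlation clusters, their representatives and the ranked sets."""

    clusters: list[list[str]]
    representatives: list[str]
    ranked_sets: dict[int, list[str]] = field(default_factory=dict)


def friedman_statistic(data: np.ndarray) -> tuple[float, float]:
    """Friedman Q (tie-corrected) and Kendall's W for an (n, k) block design.

    Ranks are assigned within each subject (mid-ranks for ties);
    Q = 12/(n k (k+1)) * sum R_j^2 - 3 n (k+1), divided by the tie
    correction 1 - sum(t^3 - t) / (n k (k^2 - 1)); W = Q / (n (k - 1)).
    """
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, data)
    col_sums = ranks.sum(axis=0)
    q = 12.0 / (n * k * (k + 1)) * np.sum(col_sums**2) - 3.0 * n * (k + 1)
    tie_term = 0.0
    for row in data:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts**3 - counts))
    correction = 1.0 - tie_term / (n * k * (k**2 - 1))
    if correction <= 0:
        return 0.0, 0.0  # every row fully tied
    q /= correction
    w = q / (n * (k - 1))
    return float(q), float(w)


def _block_matrix(
    values: pd.Series, subjects: pd.Series, levels: pd.Series
) -> tuple[np.ndarray, list]:
    frame = pd.DataFrame({"v": values, "s": subjects, "l": levels})
    pivot = frame.pivot_table(index="s", columns="l", values="v")
    missing = pivot.index[pivot.isna().any(axis=1)].tolist()
    if missing:
        raise ValueError(f"incomplete 4-level blocks for subjects: {missing}")
    pivot = pivot[sorted(pivot.columns)]
    return pivot.to_numpy(), pivot.index.tolist()


def _rm_anova(data: np.ndarray) -> tuple[float, float, float]:
    """Repeated-measures one-way ANOVA: F, generalized eta-squared, p."""
    n, k = data.shape
    grand = data.mean()
    ss_subject = k * np.sum((data.mean(axis=1) - grand) ** 2)
    ss_level = n * np.sum((data.mean(axis=0) - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_error = ss_total - ss_subject - ss_level
    df_level = k - 1
    df_error = (n - 1) * (k - 1)
    ms_level = ss_level / df_level
    ms_error = ss_error / df_error
    f = ms_level / ms_error if ms_error > 0 else np.inf
    p = float(sps.f.sf(f, df_level, df_error))
    ng2 = ss_level / (ss_level + ss_subject + ss_error)
    return float(f), float(ng2), p


def level_effect_test(
    values: pd.Series,
    subjects: pd.Series,
    levels: pd.Series,
    alpha: float = 0.05,
) -> StatTestResult:
    """Normality-gated within-subject test of the game-level effect.

    Friedman is used when any level's Shapiro-Wilk p-value is below 0.05,
    RM-ANOVA otherwise.  Post hoc p-values (Wilcoxon signed-rank or
    paired t) are Bonferroni-corrected over the 6 level pairs.
    """
    data, _ = _block_matrix(values, subjects, levels)
    n, k = data.shape
    if n < 3:
        raise ValueError(f"need at least 3 complete subjects, got {n}")

    normal = True
    for j in range(k):
        col = data[:, j]
        if np.ptp(col) == 0:
            normal = False
            break
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if sps.shapiro(col).pvalue < 0.05:
                normal = False
                break

    if normal:
        f, ng2, p = _rm_anova(data)
        result = StatTestResult(
            feature=str(values.name), test="RM-ANOVA", statistic=f, effect_size=ng2, p=p
        )
    else:
        q, w = friedman_statistic(data)
        p = float(sps.chi2.sf(q, k - 1)) if q > 0 else 1.0
        result = StatTestResult(
            feature=str(values.name), test="Friedman", statistic=q, effect_size=w, p=p
        )

    for a, b in LEVEL_PAIRS:
        x, y = data[:, a - 1], data[:, b - 1]
        if np.all(x == y):
            p_raw = 1.0
        elif normal:
            p_raw = float(sps.ttest_rel(x, y).pvalue)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p_raw = float(sps.wilcoxon(x, y, zero_method="wilcox").pvalue)
        p_corr = min(1.0, 6.0 * p_raw)
        result.posthoc_p[(a, b)] = p_corr
        if p_corr < alpha:
            result.posthoc_pairs.append((a, b))
    return result


def cluster_select(
    table: pd.DataFrame,
    features: list[str],
    target: str = "level",
    rho_threshold: float = 0.8,
    p_threshold: float = 0.05,
) -> SelectionResult:
    """Correlation-cluster the features and keep one representative each.

    Single-linkage agglomeration under |Spearman rho| > threshold with
    significant p; the representative maximizes |Spearman rho| with the
    target column.  Constant columns are excluded with a warning.
    """
    usable = []
    for feat in features:
        col = table[feat].to_numpy(dtype=float)
        if not np.all(np.isfinite(col)):
            warnings.warn(f"feature {feat} has missing values; excluded")
            continue
        if np.ptp(col) == 0:
            warnings.warn(f"feature {feat} is constant; excluded")
            continue
        usable.append(feat)
    if len(table) < 8 or len(usable) < 2:
        raise ValueError("need at least 8 rows and 2 usable features")

    # union-find over the significant-correlation graph = single linkage
    parent = {f: f for f in usable}

    def find(f: str) -> str:
        while parent[f] != f:
            parent[f] = parent[parent[f]]
            f = parent[f]
        return f

    for fa, fb in combinations(usable, 2):
        rho, p = sps.spearmanr(table[fa], table[fb])
        if abs(rho) > rho_threshold and p < p_threshold:
            parent[find(fa)] = find(fb)

    groups: dict[str, list[str]] = {}
    for f in usable:
        groups.setdefault(find(f), []).append(f)

    clusters, representatives = [], []
    target_values = table[target].to_numpy(dtype=float)
    for members in groups.values():
        members = sorted(members)
        clusters.append(members)
        scores = {}
        for f in members:
            rho, _ = sps.spearmanr(table[f], target_values)
            scores[f] = abs(rho) if np.isfinite(rho) else 0.0
        representatives.append(max(members, key=lambda f: (scores[f], f)))
    order = [min(c) for c in clusters]
    idx = np.argsort(order)
    clusters = [clusters[i] for i in idx]
    representatives = [representatives[i] for i in idx]
    return SelectionResult(clusters=clusters, representatives=representatives)


def rank_features(
    results: list[StatTestResult],
    table: pd.DataFrame,
    target: str = "level",
    set_sizes: tuple[int, ...] = (3, 5, 7),
    significance: float = 0.05,
) -> dict[int, list[str]]:
    """Rank significant features into top-k sets.

    Sort key: number of significant post hoc pairs (descending), then
    |Spearman correlation with the target| (descending), ties broken by
    feature name.  Sets truncate if fewer significant features exist.
    """
    significant = [r for r in results if r.p < significance]

    def label_corr(feature: str) -> float:
        rho, _ = sps.spearmanr(table[feature], table[target])
        return abs(rho) if np.isfinite(rho) else 0.0

    ordered = sorted(
        significant,
        key=lambda r: (-r.n_significant_pairs, -label_corr(r.feature), r.feature),
    )
    names = [r.feature for r in ordered]
    return {k: names[:k] for k in set_sizes}


def statistics_report(results: list[StatTestResult]) -> pd.DataFrame:
    """Tabular report: one row per feature with test, statistic, effect size."""
    rows = []
    for r in results:
        rows.append(
            {
                "Feature": r.feature,
                "Test": r.test,
                "W/ng2": r.effect_size,
                "Q/F": r.statistic,
                "p": r.p,
                "PHC": r.n_significant_pairs,
                "PostHoc_Pairs": ", ".join(f"{a}-{b}" for a, b in r.posthoc_pairs),
            }
        )
    return pd.DataFrame(rows)
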