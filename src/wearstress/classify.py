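"""Leave-one-subject-out stress-level classification.

The outer loop holds out every row of one subject (LOSO); inside each
outer fold a nested stratified 3-fold search tunes the model
hyperparameters with a Gaussian-process expected-improvement optimizer
over documented spaces.  Standardization is fit on the training folds
only and applied to the distance-based models (SVM, kNN); the tree
ensembles run on raw features.  Four model families are supported (SVM,
random forest, kNN, gradient-boosted trees); all randomness is keyed to a
single seed and runs are typically repeated over several seeds and
averaged.

Feature attribution uses exact Shapley values: with the small feature
sets used here (<= 7 features) all 2^k coalitions are enumerated against
a training-median background, so no sampling approximation is involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern
from sklearn.metrics import (
    confusion_matrix,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from scipy import stats as sps
from xgboost import XGBClassifier

from wearstress.session_io import N_LEVELS

MODELS = ("svm", "rf", "knn", "xgboost")
SCALED_MODELS = ("svm", "knn")

# hyperparameter spaces: ("log", lo, hi) log-uniform float, ("int", lo, hi)
# inclusive integer, ("cat", options) categorical
SEARCH_SPACES: dict[str, dict[str, tuple]] = {
    "svm": {"C": ("log", 1e-2, 1e3), "gamma": ("log", 1e-4, 1e1)},
    "knn": {"n_neighbors": ("int", 1, 15), "weights": ("cat", ("uniform", "distance"))},
    "rf": {"n_estimators": ("int", 50, 500), "max_depth": ("int", 2, 10)},
    "xgboost": {
        "n_estimators": ("int", 50, 500),
        "max_depth": ("int", 2, 8),
        "learning_rate": ("log", 1e-3, 0.3),
    },
}


@dataclass
class CVRunResult:
    """One LOSO run: pooled predictions, metrics, confusion, attribution."""

    model: str
    feature_set: list[str]
    seed: int
    predictions: pd.DataFrame  # columns: subject_id, level, predicted
    metrics: dict[str, float]
    confusion: np.ndarray  # 4x4, rows = true level, cols = predicted
    attribution: dict[str, float]  # mean |Shapley value| per feature


def _decode(space: dict[str, tuple], unit: np.ndarray) -> dict:
    params = {}
    for u, (name, dim) in zip(unit, space.items()):
        kind = dim[0]
        if kind == "log":
            lo, hi = np.log(dim[1]), np.log(dim[2])
            params[name] = float(np.exp(lo + u * (hi - lo)))
        elif kind == "int":
            params[name] = int(round(dim[1] + u * (dim[2] - dim[1])))
        else:
            options = dim[1]
            params[name] = options[min(int(u * len(options)), len(options) - 1)]
    return params


def _make_model(name: str, params: dict, seed: int, n_train: int | None = None):
    if name == "svm":
        return SVC(kernel="rbf", probability=True, random_state=seed, **params)
    if name == "knn":
        if n_train is not None:
            # the searched neighbor count must not exceed the fitted fold
            params = params | {"n_neighbors": min(params["n_neighbors"], n_train)}
        return KNeighborsClassifier(**params)
    if name == "rf":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if name == "xgboost":
        return XGBClassifier(
            random_state=seed,
            n_jobs=1,
            verbosity=0,
            eval_metric="mlogloss",
            **params,
        )
    raise ValueError(f"unknown model {name!r}; choose from {MODELS}")


def gp_minimize_unit(
    objective,
    n_dims: int,
    n_iter: int,
    rng: np.random.Generator,
    n_init: int | None = None,
) -> np.ndarray:
    """Maximize a noisy objective over the unit hypercube with GP + EI.

    Random exploration for the first ``n_init`` evaluations, then a
    Matern-5/2 Gaussian process proposes the candidate with the highest
    expected improvement among 256 random points.  Returns the best point.
    """
    n_init = n_init if n_init is not None else max(3, min(5, n_iter // 2))
    X, y = [], []
    for _ in range(min(n_init, n_iter)):
        x = rng.uniform(size=n_dims)
        X.append(x)
        y.append(objective(x))
    while len(X) < n_iter:
        gp = GaussianProcessRegressor(
            kernel=Matern(nu=2.5, length_scale=0.3, length_scale_bounds=(1e-2, 1e2)),
            alpha=1e-4,
            normalize_y=True,
            random_state=int(rng.integers(2**31)),
        )
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            gp.fit(np.array(X), np.array(y))
        candidates = rng.uniform(size=(256, n_dims))
        mu, sigma = gp.predict(candidates, return_std=True)
        best_y = max(y)
        sigma = np.maximum(sigma, 1e-9)
        imp = mu - best_y - 0.01
        zscore = imp / sigma
        ei = imp * sps.norm.cdf(zscore) + sigma * sps.norm.pdf(zscore)
        x = candidates[int(np.argmax(ei))]
        X.append(x)
        y.append(objective(x))
    return np.array(X)[int(np.argmax(y))]


def _tune(
    model_name: str,
    X: np.ndarray,
    y: np.ndarray,
    seed: int,
    n_iter: int,
) -> dict:
    """Nested stratified 3-fold accuracy maximization over the model space."""
    space = SEARCH_SPACES[model_name]
    rng = np.random.default_rng(seed)
    splitter = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
    splits = list(splitter.split(X, y))

    def objective(unit: np.ndarray) -> float:
        params = _decode(space, unit)
        scores = []
        for train_idx, val_idx in splits:
            model = _make_model(model_name, params, seed, n_train=len(train_idx))
            model.fit(X[train_idx], _encode_labels(y[train_idx]))
            pred = _decode_labels(model.predict(X[val_idx]))
            scores.append(float(np.mean(pred == y[val_idx])))
        return float(np.mean(scores))

    best_unit = gp_minimize_unit(objective, len(space), n_iter, rng)
    return _decode(space, best_unit)


def _encode_labels(y: np.ndarray) -> np.ndarray:
    return np.asarray(y, dtype=int) - 1


def _decode_labels(y: np.ndarray) -> np.ndarray:
    return np.asarray(y, dtype=int) + 1


def exact_shapley(model, X_test: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Exact Shapley values of ``predict_proba`` for the predicted class.

    ``background`` is one row (training-fold medians).  For every test
    sample all 2^k coalitions are evaluated; returns an (n_test, k) array
    of attributions.
    """
    n, k = X_test.shape
    subsets = []
    for size in range(k + 1):
        subsets.extend(combinations(range(k), size))
    masks = np.zeros((len(subsets), k), dtype=bool)
    for i, s in enumerate(subsets):
        masks[i, list(s)] = True
    subset_index = {s: i for i, s in enumerate(subsets)}

    from math import factorial

    weights = {}
    for size in range(k):
        weights[size] = factorial(size) * factorial(k - size - 1) / factorial(k)

    phis = np.zeros((n, k))
    for row in range(n):
        grid = np.where(masks, X_test[row], background)
        proba = model.predict_proba(grid)
        cls = int(np.argmax(proba[-1]))  # full coalition = actual prediction
        values = proba[:, cls]
        for i in range(k):
            for s in subsets:
                if i in s:
                    continue
                with_i = tuple(sorted(s + (i,)))
                delta = values[subset_index[with_i]] - values[subset_index[s]]
                phis[row, i] += weights[len(s)] * delta
    return phis


def loso_nested_cv(
    table: pd.DataFrame,
    feature_set: list[str],
    model: str = "knn",
    seed: int = 0,
    n_iter: int = 30,
    compute_attribution: bool = True,
) -> CVRunResult:
    """Run one leave-one-subject-out nested cross-validation.

    Requires every subject to contribute exactly one row per level.
    Returns pooled predictions, one-vs-rest metrics, the 4x4 confusion
    matrix and (optionally) the exact-Shapley attribution averaged over
    held-out samples.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    subjects = table["subject_id"].unique()
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    counts = table.groupby("subject_id")["level"].nunique()
    if (counts != N_LEVELS).any() or (table.groupby("subject_id").size() != N_LEVELS).any():
        bad = counts.index[counts != N_LEVELS].tolist()
        raise ValueError(f"subjects without one row per level: {bad or 'duplicates'}")
    missing = [f for f in feature_set if f not in table.columns]
    if missing:
        raise ValueError(f"features absent from table: {missing}")

    X_all = table[feature_set].to_numpy(dtype=float)
    y_all = table["level"].to_numpy(dtype=int)
    sid = table["subject_id"].to_numpy()

    preds = np.zeros_like(y_all)
    proba_all = np.zeros((len(y_all), N_LEVELS))
    shap_rows = []
    for subject in subjects:
        test_mask = sid == subject
        X_train, y_train = X_all[~test_mask], y_all[~test_mask]
        X_test = X_all[test_mask]
        if len(np.unique(y_train)) < 2:
            raise ValueError("degenerate single-class training fold")
        if model in SCALED_MODELS:
            scaler = StandardScaler().fit(X_train)
            X_train, X_test = scaler.transform(X_train), scaler.transform(X_test)
        params = _tune(model, X_train, y_train, seed, n_iter)
        clf = _make_model(model, params, seed, n_train=len(X_train))
        clf.fit(X_train, _encode_labels(y_train))
        preds[test_mask] = _decode_labels(clf.predict(X_test))
        proba_all[test_mask] = clf.predict_proba(X_test)
        if compute_attribution:
            background = np.median(X_train, axis=0)
            shap_rows.append(np.abs(exact_shapley(clf, X_test, background)))

    metrics = {
        "accuracy": float(np.mean(preds == y_all)),
        "precision": float(precision_score(y_all, preds, average="macro", zero_division=0)),
        "recall": float(recall_score(y_all, preds, average="macro", zero_division=0)),
        "f1": float(f1_score(y_all, preds, average="macro", zero_division=0)),
        "auc_ovr": float(
            roc_auc_score(y_all, proba_all, multi_class="ovr", average="macro")
        ),
    }
    confusion = confusion_matrix(y_all, preds, labels=list(range(1, N_LEVELS + 1)))
    attribution = {}
    if compute_attribution:
        mean_abs = np.vstack(shap_rows).mean(axis=0)
        attribution = dict(zip(feature_set, mean_abs.astype(float)))
    predictions = pd.DataFrame(
        {"subject_id": sid, "level": y_all, "predicted": preds}
    )
    return CVRunResult(
        model=model,
        feature_set=list(feature_set),
        seed=seed,
        predictions=predictions,
        metrics=metrics,
        confusion=confusion,
        attribution=attribution,
    )


@dataclass
class RunSummary:
    """Seed-averaged summary of repeated LOSO runs."""

    model: str
    feature_set: list[str]
    metric_means: dict[str, float]
    metric_sds: dict[str, float]
    mean_confusion: np.ndarray
    attribution_ranking: list[tuple[str, float]] = field(default_factory=list)


def aggregate_runs(results: list[CVRunResult]) -> RunSummary:
    """Average metrics, confusion and attribution over same-config runs."""
    if len(results) < 2:
        raise ValueError("need at least 2 runs to aggregate")
    first = results[0]
    for r in results[1:]:
        if r.model != first.model or r.feature_set != first.feature_set:
            raise ValueError("runs have mismatched configurations")
    metric_names = first.metrics.keys()
    means = {
        m: float(np.mean([r.metrics[m] for r in results])) for m in metric_names
    }
    sds = {m: float(np.std([r.metrics[m] for r in results])) for m in metric_names}
    mean_conf = np.mean([r.confusion for r in results], axis=0)
    ranking: list[tuple[str, float]] = []
    if all(r.attribution for r in results):
        mean_attr = {
            f: float(np.mean([r.attribution[f] for r in results]))
            for f in first.feature_set
        }
        ranking = sorted(mean_attr.items(), key=lambda kv: -kv[1])
    return RunSummary(
        model=first.model,
        feature_set=first.feature_set,
        metric_means=means,
        metric_sds=sds,
        mean_confusion=mean_conf,
        attribution_ranking=ranking,
    )
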