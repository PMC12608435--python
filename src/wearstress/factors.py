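"""In-game performance and baseline-stress (PSS) confound analyses.

Performance is scored as (points - errors) / level duration, in points
per second.  Its linear influence on each physiological feature is
estimated with a linear mixed model ``feature ~ C(level) + performance``
with a random intercept per subject (REML fit, Wald test on the
performance slope) and the slope p-values are corrected for multiplicity
with both Bonferroni and Benjamini-Hochberg.  Subject-level analyses
average features over the four levels and correlate them (Pearson and
Spearman) with mean performance or the PSS score; for the EDA recovery
speed (NegDerMean) a descriptive per-level contrast between the low
(PSS <= 13) and moderate (14-26) baseline-stress groups is produced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

PSS_GROUPS = {"low": (0, 13), "moderate": (14, 26), "high": (27, 40)}


@dataclass
class LMMResult:
    """Mixed-model outcome for the performance slope of one feature."""

    feature: str
    performance_coef: float
    p_unc: float
    p_bonf: float = np.nan
    p_fdr: float = np.nan
    converged: bool = True


def performance_score(points: int, errors: int, duration_s: float) -> float:
    """(points - errors) / duration, in points per second; may be negative."""
    if duration_s <= 0:
        raise ValueError(f"level duration must be positive, got {duration_s}")
    if points < 0 or errors < 0:
        raise ValueError("points and errors must be nonnegative")
    return (points - errors) / duration_s


def add_performance(table: pd.DataFrame) -> pd.DataFrame:
    """Append a ``performance`` column computed from points/errors/duration."""
    out = table.copy()
    out["performance"] = [
        performance_score(p, e, d)
        for p, e, d in zip(out["points"], out["errors"], out["duration"])
    ]
    return out


def fit_performance_lmm(
    table: pd.DataFrame, features: list[str]
) -> list[LMMResult]:
    """Per-feature mixed models of the performance effect.

    ``table`` must carry subject_id, level, performance and the feature
    columns.  Non-converged models are flagged and excluded from the
    multiplicity corrections.
    """
    if table["subject_id"].nunique() < 10:
        raise ValueError("need at least 10 subjects for the mixed models")
    results: list[LMMResult] = []
    for feat in features:
        data = table[["subject_id", "level", "performance", feat]].dropna()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                warnings.simplefilter("ignore", UserWarning)
                model = MixedLM.from_formula(
                    f"Q('{feat}') ~ C(level) + performance",
                    groups="subject_id",
                    data=data,
                )
                fit = model.fit(reml=True)
            coef = float(fit.params["performance"])
            p_unc = float(fit.pvalues["performance"])
            converged = bool(fit.converged) and np.isfinite(p_unc)
        except Exception:
            coef, p_unc, converged = np.nan, np.nan, False
        if not converged:
            warnings.warn(f"LMM for {feat} did not converge; excluded from corrections")
        results.append(
            LMMResult(feature=feat, performance_coef=coef, p_unc=p_unc, converged=converged)
        )
    ok = [r for r in results if r.converged]
    if ok:
        raw = [r.p_unc for r in ok]
        p_bonf = multipletests(raw, method="bonferroni")[1]
        p_fdr = multipletests(raw, method="fdr_bh")[1]
        for r, pb, pf in zip(ok, p_bonf, p_fdr):
            r.p_bonf = float(pb)
            r.p_fdr = float(pf)
    return results


def subject_summaries(table: pd.DataFrame) -> pd.DataFrame:
    """One row per subject: level-averaged features, performance, PSS, group."""
    feature_cols = [
        c
        for c in table.columns
        if c not in ("subject_id", "level", "points", "errors", "duration",
                     "spectral_valid")
        and pd.api.types.is_numeric_dtype(table[c])
    ]
    summary = table.groupby("subject_id", as_index=False)[feature_cols].mean()

    def group(pss: float) -> str:
        for name, (lo, hi) in PSS_GROUPS.items():
            if lo <= pss <= hi:
                return name
        raise ValueError(f"PSS score {pss} outside 0-40")

    summary["pss_group"] = summary["pss"].map(group)
    return summary


def subject_level_correlations(
    summaries: pd.DataFrame, features: list[str], target: str
) -> pd.DataFrame:
    """Pearson r and Spearman rho of level-averaged features vs a target.

    Raises when the target has no variance (e.g. a fixed PSS).  Features
    are flagged at p < 0.05 and p < 0.01 on either test.
    """
    if len(summaries) < 5:
        raise ValueError("need at least 5 subjects")
    y = summaries[target].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError(f"{target} variance zero; correlations undefined")
    rows = []
    for feat in features:
        x = summaries[feat].to_numpy(dtype=float)
        valid = np.isfinite(x)
        if valid.sum() < 5 or np.ptp(x[valid]) == 0:
            rows.append(
                {"feature": feat, "pearson_r": np.nan, "pearson_p": np.nan,
                 "spearman_rho": np.nan, "spearman_p": np.nan, "sig_05": False,
                 "sig_01": False}
            )
            continue
        pr, pp = sps.pearsonr(x[valid], y[valid])
        sr, sp = sps.spearmanr(x[valid], y[valid])
        rows.append(
            {
                "feature": feat,
                "pearson_r": float(pr),
                "pearson_p": float(pp),
                "spearman_rho": float(sr),
                "spearman_p": float(sp),
                "sig_05": bool(min(pp, sp) < 0.05),
                "sig_01": bool(min(pp, sp) < 0.01),
            }
        )
    return pd.DataFrame(rows)


def pss_group_contrast(
    table: pd.DataFrame, feature: str = "NegDerMean"
) -> pd.DataFrame:
    """Per level x PSS-group descriptive table (median and quartiles).

    Compares the low and moderate baseline-stress groups; purely
    descriptive, no inferential claim.  Raises when either group is empty.
    """
    data = table.copy()
    data["pss_group"] = data["pss"].map(
        lambda p: next(
            name for name, (lo, hi) in PSS_GROUPS.items() if lo <= p <= hi
        )
    )
    for name in ("low", "moderate"):
        if not (data["pss_group"] == name).any():
            raise ValueError(f"empty group: {name}")
    rows = []
    for (level, group), sub in data[data["pss_group"].isin(["low", "moderate"])].groupby(
        ["level", "pss_group"]
    ):
        q25, q50, q75 = np.percentile(sub[feature].dropna(), [25, 50, 75])
        rows.append(
            {"level": level, "pss_group": group, "median": q50, "q25": q25,
             "q75": q75, "n": len(sub)}
        )
    return pd.DataFrame(rows)
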