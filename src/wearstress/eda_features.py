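"""Per-level EDA feature battery.

Features are computed on the filtered, windowed, z-scored signal (EDA)
and on its tonic (cvxT) and phasic (cvxP) components: statistical
descriptors, first-derivative summaries, Hjorth parameters, complexity
measures (Shannon/approximate/sample entropy and the largest Lyapunov
exponent) and spectral descriptors.  Spectral features are reliable only
on segments of at least a minute, so on the short game levels they are
flagged; the whole-session values are the ones used for cross-level
comparisons.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal, spatial, stats

SHANNON_BINS = 16
SPECTRAL_MIN_DURATION_S = 60.0


def segment_stats(segment: np.ndarray) -> dict[str, float]:
    """Mean, std, median, kurtosis, skewness, range and maximum.

    Population moments; kurtosis is Fisher (excess).  Zero-variance
    segments have undefined skewness/kurtosis, reported as 0 with a
    warning.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.size < 4:
        raise ValueError(f"segment too short for statistics ({segment.size} < 4)")
    sd = float(np.std(segment))
    if sd == 0:
        warnings.warn("zero-variance segment: skewness/kurtosis reported as 0")
        skew = kurt = 0.0
    else:
        skew = float(stats.skew(segment))
        kurt = float(stats.kurtosis(segment))
    return {
        "Mean": float(np.mean(segment)),
        "Std": sd,
        "Median": float(np.median(segment)),
        "Kurt": kurt,
        "Skew": skew,
        "Range": float(np.ptp(segment)),
        "Max": float(np.max(segment)),
    }


def derivative_features(segment: np.ndarray, fs: float) -> dict[str, float]:
    """Mean/max absolute derivative and mean negative derivative (1/s units).

    The mean negative derivative averages only the strictly negative
    derivative samples — the average recovery speed; a segment with no
    decreasing samples yields 0.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.size < 2:
        raise ValueError("need at least 2 samples for a derivative")
    d = np.diff(segment) * fs
    neg = d[d < 0]
    return {
        "DerMean": float(np.mean(np.abs(d))),
        "Dermax": float(np.max(np.abs(d))),
        "NegDerMean": float(np.mean(neg)) if neg.size else 0.0,
    }


def hjorth(segment: np.ndarray) -> dict[str, float]:
    """Hjorth activity (variance) and mobility sqrt(var(diff)/var).

    The first difference is taken sample-to-sample (no rate scaling),
    matching the usual EEG-style definition.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.size < 3:
        raise ValueError("need at least 3 samples for Hjorth parameters")
    activity = float(np.var(segment))
    if activity == 0:
        raise ValueError("zero-variance segment: Hjorth mobility undefined")
    mobility = float(np.sqrt(np.var(np.diff(segment)) / activity))
    return {"Activity": activity, "Mobility": mobility}


def shannon_entropy(segment: np.ndarray, bins: int = SHANNON_BINS) -> float:
    """Shannon entropy in bits over a uniform histogram of the segment."""
    segment = np.asarray(segment, dtype=float)
    if np.ptp(segment) == 0:
        return 0.0
    counts, _ = np.histogram(segment, bins=bins)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _embed(x: np.ndarray, m: int, delay: int = 1) -> np.ndarray:
    n = x.size - (m - 1) * delay
    return np.column_stack([x[i * delay : i * delay + n] for i in range(m)])


def _phi_counts(x: np.ndarray, m: int, r: float, self_match: bool) -> np.ndarray:
    emb = _embed(x, m)
    dist = spatial.distance.cdist(emb, emb, metric="chebyshev")
    counts = (dist <= r).sum(axis=1).astype(float)
    if not self_match:
        counts -= 1.0
    return counts


def approximate_entropy(segment: np.ndarray, m: int = 2, r_factor: float = 0.2) -> float:
    """Approximate entropy with embedding m and tolerance r = r_factor * SD."""
    x = np.asarray(segment, dtype=float)
    sd = np.std(x)
    if sd == 0:
        return 0.0
    r = r_factor * sd

    def phi(mm: int) -> float:
        counts = _phi_counts(x, mm, r, self_match=True)
        n = counts.size
        return float(np.mean(np.log(counts / n)))

    return phi(m) - phi(m + 1)


def sample_entropy(segment: np.ndarray, m: int = 2, r_factor: float = 0.2) -> float:
    """Sample entropy (self-matches excluded) with r = r_factor * SD."""
    x = np.asarray(segment, dtype=float)
    sd = np.std(x)
    if sd == 0:
        return 0.0
    r = r_factor * sd
    b = _phi_counts(x, m, r, self_match=False)[: x.size - m].sum()
    a = _phi_counts(x, m + 1, r, self_match=False).sum()
    if a == 0 or b == 0:
        return 0.0
    return float(-np.log(a / b))


def lyapunov_exponent(segment: np.ndarray, m: int = 3, delay: int = 1) -> float:
    """Largest Lyapunov exponent, Rosenstein's method (per-sample units).

    Mean log divergence of nearest neighbours is regressed over the first
    expansion steps.  Constant or too-regular segments return 0.
    """
    x = np.asarray(segment, dtype=float)
    if np.std(x) == 0:
        return 0.0
    emb = _embed(x, m, delay)
    n = emb.shape[0]
    if n < 20:
        return 0.0
    dist = spatial.distance.cdist(emb, emb)
    # exclude temporally close neighbours (Theiler window)
    theiler = 4
    for i in range(n):
        lo, hi = max(0, i - theiler), min(n, i + theiler + 1)
        dist[i, lo:hi] = np.inf
    nn = np.argmin(dist, axis=1)
    max_steps = min(12, n // 4)
    mean_log = []
    for k in range(1, max_steps):
        valid = (np.arange(n) + k < n) & (nn + k < n)
        if valid.sum() < 5:
            break
        d = np.linalg.norm(emb[np.arange(n)[valid] + k] - emb[nn[valid] + k], axis=1)
        d = d[d > 0]
        if d.size < 5:
            break
        mean_log.append(np.mean(np.log(d)))
    if len(mean_log) < 3:
        return 0.0
    steps = np.arange(1, len(mean_log) + 1)
    slope = np.polyfit(steps, mean_log, 1)[0]
    return float(slope)


def complexity_features(segment: np.ndarray) -> dict[str, float]:
    """Shannon/approximate/sample entropy and largest Lyapunov exponent."""
    segment = np.asarray(segment, dtype=float)
    if segment.size < 50:
        raise ValueError(f"segment too short for complexity features ({segment.size} < 50)")
    return {
        "En": shannon_entropy(segment),
        "apEn": approximate_entropy(segment),
        "saEn": sample_entropy(segment),
        "lyapExp": lyapunov_exponent(segment),
    }


def spectral_features(segment: np.ndarray, fs: float) -> dict[str, float]:
    """Band-power and spectral-shape descriptors of an EDA segment.

    ``PB5`` is the percentage of power in 0.05-0.5 Hz relative to the
    total non-DC power up to 2 Hz (the filtered band), ``P90`` the
    frequency below which 90 % of the non-DC power lies, ``Pmax`` the
    frequency of the PSD maximum and ``Pstd`` the SD of the PSD values.
    """
    segment = np.asarray(segment, dtype=float)
    freqs, psd = signal.periodogram(segment, fs=fs, detrend="constant")
    freqs, psd = freqs[1:], psd[1:]  # drop DC
    total = np.trapezoid(psd, freqs)
    if total == 0:
        return {"PB5": 0.0, "P90": 0.0, "Pmax": 0.0, "Pstd": 0.0}
    band = (freqs >= 0.05) & (freqs <= 0.5)
    denom_mask = freqs <= 2.0
    denom = np.trapezoid(psd[denom_mask], freqs[denom_mask])
    pb5 = 100.0 * np.trapezoid(psd[band], freqs[band]) / denom if denom > 0 else 0.0
    cum = np.cumsum(psd) / np.sum(psd)
    p90 = float(freqs[np.searchsorted(cum, 0.9)])
    return {
        "PB5": float(pb5),
        "P90": p90,
        "Pmax": float(freqs[np.argmax(psd)]),
        "Pstd": float(np.std(psd)),
    }


def scr_burst_rate(driver: np.ndarray, fs: float, threshold: float = 0.05) -> float:
    """Rate of distinct driver bursts (per minute) above a small threshold.

    Contiguous runs of the sudomotor driver above ``threshold`` count as
    one burst each.
    """
    driver = np.asarray(driver, dtype=float)
    above = driver > threshold
    starts = np.sum(above[1:] & ~above[:-1]) + int(above[0])
    return float(starts) / (driver.size / fs) * 60.0


def eda_level_features(
    z: np.ndarray, tonic: np.ndarray, phasic: np.ndarray, driver: np.ndarray, fs: float
) -> dict[str, float]:
    """The full EDA-side battery for one level segment (39 features)."""
    feats: dict[str, float] = {}
    for prefix, sig in (("EDA", z), ("cvxT", tonic), ("cvxP", phasic)):
        for name, value in segment_stats(sig).items():
            feats[f"{prefix}{name}"] = value
    feats.update(derivative_features(z, fs))
    hj = hjorth(z)
    feats["EDAActivity"] = hj["Activity"]
    feats["EDAMobility"] = hj["Mobility"]
    for name, value in complexity_features(z).items():
        feats[f"EDA{name}"] = value
    for prefix, sig in (("EDA", z), ("cvxP", phasic)):
        for name, value in spectral_features(sig, fs).items():
            feats[f"{prefix}{name}"] = value
    feats["SCRRate"] = scr_burst_rate(driver, fs)
    return feats
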