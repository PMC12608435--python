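"""EDA quality gating, preprocessing and convex tonic/phasic decomposition.

The decomposition follows the cvxEDA model: the z-scored skin-conductance
signal is explained as

    z  =  phasic + tonic + residual,      phasic = h * p,   p >= 0,

where ``p`` is a sparse nonnegative sudomotor-nerve-activity (SMNA)
driver, ``h`` a bi-exponential (Bateman) impulse response with slow/fast
time constants (tau0, tau1), and the tonic term a coarse cubic-spline
grid plus an affine drift.  The components are obtained by minimizing

    1/2 ||z - h*p - B l - C d||^2  +  alpha ||p||_1  +  gamma/2 ||l||^2

subject to ``p >= 0``.  Because the driver is constrained nonnegative the
L1 penalty is the linear form ``alpha * sum(p)``, so the problem is a
smooth bound-constrained quadratic program, solved here with L-BFGS-B.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, optimize, signal

from wearstress.session_io import Recording, SessionEvents

SNR_THRESHOLD_DB = 20.0
VARIANCE_THRESHOLD_US2 = 1e-3
LOW_BAND = (0.0, 0.5)
HIGH_BAND = (0.5, 2.0)


class QualityError(ValueError):
    """Raised when a signal cannot be quality-evaluated."""


class DecompositionError(RuntimeError):
    """Raised when the convex decomposition fails to converge."""


@dataclass
class QualityReport:
    """Outcome of the EDA signal-quality gate.

    ``snr_db`` is the band-power ratio 10*log10(P[0-0.5 Hz] / P[0.5-2 Hz])
    — low frequencies carry sympathetic regulation, the high band mostly
    noise — and ``variance`` is the raw-signal variance in µS².  A signal
    passes iff snr >= 20 dB and variance >= 0.001 µS² (both inclusive).
    """

    snr_db: float
    variance: float
    passed: bool
    reasons: list[str] = field(default_factory=list)


@dataclass
class EDADecomposition:
    """Tonic/phasic split of a z-scored EDA window."""

    z: np.ndarray
    tonic: np.ndarray
    phasic: np.ndarray
    driver: np.ndarray
    fs: float
    objective: float = np.nan

    @property
    def residual(self) -> np.ndarray:
        return self.z - self.tonic - self.phasic


def quality_gate(raw: Recording) -> QualityReport:
    """Evaluate the SNR and variance gates on a raw EDA recording."""
    if raw.fs < 4.0:
        raise QualityError(f"fs {raw.fs} Hz too low to evaluate the 2 Hz band edge")
    if raw.duration < 60.0:
        raise QualityError("need at least 60 s of signal for the spectral estimate")
    variance = float(np.var(raw.samples))
    nperseg = int(60.0 * raw.fs)
    freqs, psd = signal.welch(
        raw.samples,
        fs=raw.fs,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend="constant",
    )

    def band_power(lo: float, hi: float) -> float:
        mask = (freqs >= lo) & (freqs <= hi)
        return float(np.trapezoid(psd[mask], freqs[mask]))

    p_low = band_power(*LOW_BAND)
    p_high = band_power(*HIGH_BAND)
    snr_db = 10.0 * np.log10(p_low / p_high) if p_high > 0 else np.inf
    reasons = []
    if snr_db < SNR_THRESHOLD_DB:
        reasons.append("snr")
    if variance < VARIANCE_THRESHOLD_US2:
        reasons.append("variance")
    return QualityReport(
        snr_db=float(snr_db), variance=variance, passed=not reasons, reasons=reasons
    )


def lowpass_filter(samples: np.ndarray, fs: float, cutoff: float = 1.5) -> np.ndarray:
    """First-order Butterworth low-pass, applied zero-phase."""
    if cutoff >= fs / 2:
        return np.asarray(samples, dtype=float)
    b, a = signal.butter(1, cutoff, fs=fs)
    return signal.filtfilt(b, a, samples)


def preprocess(raw: Recording, events: SessionEvents) -> np.ndarray:
    """Filter, window over the protocol span (rest through level 4), z-score."""
    filtered = lowpass_filter(raw.samples, raw.fs)
    start, stop = events.span
    i0 = int(round(start * raw.fs))
    i1 = int(round(stop * raw.fs))
    window = filtered[i0:i1]
    sd = np.std(window)
    # filtering a constant leaves O(eps) jitter, so test against a tolerance
    if sd <= 1e-12 * max(1.0, float(np.abs(window).max(initial=0.0))):
        raise QualityError("zero variance in the analysis window; cannot z-score")
    return (window - np.mean(window)) / sd


def _bateman_kernel(fs: float, tau0: float, tau1: float) -> np.ndarray:
    """Sampled bi-exponential IRF, peak-normalized, truncated at 1e-4 of peak."""
    t_peak = (np.log(tau0) - np.log(tau1)) / (1 / tau1 - 1 / tau0)
    t_end = t_peak + tau0 * np.log(1e4)
    t = np.arange(0.0, t_end, 1.0 / fs)
    h = np.exp(-t / tau0) - np.exp(-t / tau1)
    return h / h.max()


def cvxeda_decompose(
    z: np.ndarray,
    fs: float,
    alpha: float = 8e-4,
    gamma: float = 1e-2,
    tau0: float = 2.0,
    tau1: float = 0.7,
    knot_spacing: float = 10.0,
    maxiter: int = 2000,
) -> EDADecomposition:
    """Solve the sparse-driver convex decomposition of a z-scored signal.

    Parameters follow the reference convex-EDA formulation: ``alpha``
    weights driver sparsity, ``gamma`` the tonic-spline smoothness, and
    (tau0, tau1) are the slow/fast kernel time constants in seconds with
    ``tau1 < tau0``.  Raises :class:`DecompositionError` carrying the
    solver status on non-convergence; never returns partial components.
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("signal must be finite")
    if fs <= 0 or tau0 <= 0 or tau1 <= 0:
        raise ValueError("fs and time constants must be positive")
    if tau1 >= tau0:
        raise ValueError("tau1 must be smaller than tau0")
    n = z.size
    t = np.arange(n) / fs

    h = _bateman_kernel(fs, tau0, tau1)

    def conv(p: np.ndarray) -> np.ndarray:
        return signal.fftconvolve(p, h)[:n]

    def conv_t(r: np.ndarray) -> np.ndarray:
        return signal.fftconvolve(r[::-1], h)[:n][::-1]

    # cubic B-spline basis on a coarse knot grid for the tonic level
    inner = np.arange(0.0, t[-1] + knot_spacing, knot_spacing)
    knots = np.concatenate(([inner[0]] * 3, inner, [inner[-1]] * 3))
    B = interpolate.BSpline.design_matrix(t, knots, k=3).toarray()
    m = B.shape[1]
    C = np.column_stack([np.ones(n), t / max(t[-1], 1.0)])

    def objective(x: np.ndarray):
        p, ell, d = x[:n], x[n : n + m], x[n + m :]
        r = conv(p) + B @ ell + C @ d - z
        f = 0.5 * r @ r + alpha * p.sum() + 0.5 * gamma * ell @ ell
        g = np.concatenate([conv_t(r) + alpha, B.T @ r + gamma * ell, C.T @ r])
        return f, g

    x0 = np.zeros(n + m + 2)
    x0[n + m :] = np.linalg.lstsq(C, z, rcond=None)[0]
    bounds = [(0.0, None)] * n + [(None, None)] * (m + 2)
    res = optimize.minimize(
        objective,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": maxiter, "maxfun": 10 * maxiter, "ftol": 1e-12, "gtol": 1e-9},
    )
    if not res.success and "ABNORMAL" in str(res.message):
        raise DecompositionError(f"solver failed: {res.message}")
    p = np.maximum(res.x[:n], 0.0)
    ell, d = res.x[n : n + m], res.x[n + m :]
    tonic = B @ ell + C @ d
    phasic = conv(p)
    # optimality certificate: never worse than the trivial feasible point
    f_triv = 0.5 * float(np.sum((C @ x0[n + m :] - z) ** 2))
    if res.fun > f_triv + 1e-6:
        raise DecompositionError(
            f"solver returned suboptimal point (f={res.fun:.4g} > trivial {f_triv:.4g})"
        )
    return EDADecomposition(
        z=z, tonic=tonic, phasic=phasic, driver=p, fs=fs, objective=float(res.fun)
    )


def decompose_session(raw: Recording, events: SessionEvents, **kwargs) -> EDADecomposition:
    """Preprocess and decompose one session's EDA channel."""
    z = preprocess(raw, events)
    return cvxeda_decompose(z, raw.fs, **kwargs)
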