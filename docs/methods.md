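# Methods

This document records the modeling assumptions, parameter defaults, and
numerical choices behind `wearstress`. The package analyzes short-term
stress responses during a four-level exergame from two wrist-device
channels — electrodermal activity (EDA, 4 Hz) and blood volume pulse
(BVP, 64 Hz) — and ships a synthetic-session generator so the entire
chain is testable without access to recordings.

## 1. Synthetic session generator (`wearstress.synth`)

### Protocol model

A session is a 3-minute rest with eyes closed, a 15 s gap, then four
game levels of nominally 30 s each. Level durations are jittered ±20 %
per subject so window arithmetic is exercised on non-round spans.
Per-level points and errors are drawn from a per-subject skill level
(Beta(8, 2)) so that the derived PerformanceScore varies both between
and within subjects. Each subject receives an integer PSS
(Perceived Stress Scale, 0–40) score drawn uniformly from `pss_range`.

### EDA model

The EDA signal is the sum of three parts:

1. **Tonic drive** — a baseline (`tonic_baseline`, 1.0 µS) plus a
   per-level increment (`tonic_level_increment`, 0.5 µS per level),
   smoothed so the staircase has no discontinuities.
2. **Phasic activity** — SCR events drawn as a Poisson stream whose
   rate is 1/min at rest and (4, 6, 8, 10)/min in levels 1–4, each
   contributing a peak-normalized Bateman kernel
   `exp(-t/tau_d) - exp(-t/tau_r)` with rise `tau_r = 0.7 s` and decay
   `tau_d = 3.0 s`, and an amplitude uniform in (0.1, 0.6) µS. The
   configured amplitude floor must exceed 0.05 µS, the usual
   significance threshold for wrist EDA responses.
3. **Gaussian noise** (`noise_sd_eda`, 0.01 µS).

The subject's PSS couples into physiology in exactly one place: the
SCR decay constant is inflated to `tau_d × (1 + 0.04 × PSS)`, i.e.
higher baseline stress produces slower electrodermal recovery. This is
the hook that lets the influencing-factor analyses find a
PSS–recovery-speed association without hard-coding any feature value.

Config validation rejects level durations shorter than two SCR kernel
supports (support taken as `tau_r + 3 tau_d`), since such levels cannot
contain a resolvable response.

### BVP model

Beats are laid down sequentially: the instantaneous mean inter-beat
interval follows `60 / (hr_base + offset(level))`, where
`hr_base = 70 bpm` and `offset(level) = 1.5 bpm × level + N(0, 2.0 bpm)`
drawn once per (subject, level). The deterministic slope is kept small
and the per-subject scatter comparatively large on purpose: the cardiac
response to a stressor is far less uniform across subjects than the
electrodermal one, and a steeper deterministic slope would make HRV
features implausibly dominant in the level statistics. Each interval
additionally gets white HRV noise (`hrv_sd_ms = 15 ms`) and a sinusoidal
respiratory modulation (`resp_mod_ms = 20 ms` at `resp_freq = 0.25 Hz`),
then is clipped to [0.3, 2.0] s.

The pulse waveform is expressed in **seconds since beat onset**, not in
phase fractions: the systolic peak (P) sits 0.22 s and the diastolic
peak (D) 0.45 s after the onset, followed by an exponential runoff and a
smooth Gaussian foot dip 0.08 s before the next onset. Two choices here
matter for correctness of the evaluation:

- With phase-fraction landmarks, the PP interval between fixed-phase
  peaks is `ibi_i + 0.22 (ibi_{i+1} − ibi_i)` — a warped version of the
  OO series — and independently detected P- and O-tachograms disagree
  even on noiseless signals. Fixed post-onset delays mimic real pulse
  physiology (systolic upstroke timing does not stretch with the cycle)
  and make both landmark series measure the same rhythm.
- The foot is a smooth dip rather than a cusp because the beat detector
  refines landmark times by parabolic interpolation, which is biased on
  non-smooth extrema.

In the *deformed* mode (`waveform_deformed`), P and D amplitudes become
near-equal (0.52 vs 0.62) with ±15 % per-beat amplitude jitter, so a
positive-peak detector locks onto inconsistent landmarks while the onset
trough remains well defined — reproducing the known failure mode of
systolic-peak tachograms on poorly formed wrist PPG pulses.

### What the generator does *not* emulate

Motion artifacts and electrode detachment, temperature/hydration drift
of the skin conductance level, non-stationary breathing, pulse-wave
reflection changes with vascular tone, any PSS influence beyond the
SCR-decay coupling, and learning/fatigue effects across levels. Signals
are stationary within a window by construction; quality-gate failures
must be constructed explicitly in tests rather than sampled.

Determinism: every session is generated from
`default_rng([seed mod 2^31, crc32(subject_id)])`, so cohorts are
reproducible per subject and independent of generation order.

## 2. EDA processing (`wearstress.eda`)

- **Quality gate**: Welch PSD (60 s Hann segments, 50 % overlap);
  SNR = `10 log10(P[0–0.5 Hz] / P[0.5–2 Hz])` must be ≥ 20 dB and raw
  variance ≥ 0.001 µS² (both inclusive). Band powers use trapezoidal
  integration of the PSD.
- **Preprocessing**: first-order Butterworth low-pass at 1.5 Hz applied
  zero-phase, windowed from rest start to level-4 end, z-scored over
  that window. (Z-scoring makes the decomposition scale-free; features
  on absolute µS levels are deliberately not part of the inventory.)
- **Convex decomposition**: the sparse-driver model
  `min ½‖z − h*p − Bℓ − Cd‖² + α·1ᵀp + ½γ‖ℓ‖²  s.t. p ≥ 0`,
  where `h` is the Bateman kernel (slow/fast constants
  `tau0 = 2.0 s`, `tau1 = 0.7 s`), `B` a cubic B-spline basis with 10 s
  knot spacing for the tonic level and `C` an affine drift term.
  Because `p ≥ 0`, the L1 penalty is the linear term `α·1ᵀp` and the
  problem is a smooth bound-constrained QP, solved with L-BFGS-B
  (analytic gradient via FFT convolution and its adjoint,
  `ftol = 1e-12`). Defaults `α = 8e-4`, `γ = 1e-2` follow the reference
  convex formulation of EDA decomposition. Two safeguards: solver
  failure raises (`DecompositionError`, never partial output), and an
  optimality certificate rejects any solution worse than the trivial
  affine fit. One 360 s session at 4 Hz solves in ~0.5 s.

## 3. Feature inventory (95 features; `wearstress.eda_features`, `wearstress.hrv`, `wearstress.features`)

EDA-side (39):

- 7 distribution statistics (mean, SD, median, excess kurtosis,
  skewness, range, max) × 3 signals: z-scored EDA, tonic (`cvxT`),
  phasic (`cvxP`) = 21;
- 3 derivative features: mean |d/dt|, max |d/dt|, and `NegDerMean`
  (mean over strictly negative derivative samples — the average
  recovery speed; 0 when no sample decreases);
- 2 Hjorth parameters (activity = variance, mobility) of the EDA;
- 4 complexity features of the EDA: Shannon entropy (16-bin histogram,
  bits), approximate and sample entropy (m = 2, r = 0.2·SD), and the
  largest Lyapunov exponent (Rosenstein method, m = 3);
- 4 spectral descriptors × 2 signals (EDA, `cvxP`) = 8: `PB5` (% of
  power in 0.05–0.5 Hz relative to the non-DC power up to 2 Hz — the
  pass band of the filter, so the denominator excludes attenuated
  content), `P90` (frequency below which 90 % of non-DC power lies),
  `Pmax` (PSD argmax) and `Pstd` (SD of PSD values);
- 1 `SCRRate`: distinct driver bursts above 0.05 per minute.

Spectral estimates on ~30 s windows are marked by the table's
`spectral_valid` flag (false below 60 s) rather than dropped.

HRV-side (28 × 2 landmarks = 56), computed once on the systolic-peak
(`pp*`) and once on the onset (`oo*`) tachogram:

- 13 raw-series features: bpm, mean IBI, sdnn, sdsd, rmssd,
  pnn20/pnn50, MAD, Poincaré sd1/sd2/area/ratio, breathing rate
  (dominant 0.1–0.4 Hz frequency of the cubic-interpolated 4 Hz
  tachogram periodogram);
- 15 pruned-series descriptors after retaining intervals strictly
  inside the 5th–95th percentiles (pruning is skipped with a warning
  for series under 20 intervals or when it would empty the series).

Beat detection standardizes the window, smooths by 0.1 s moving
average, scans `find_peaks` prominence thresholds
(0.3 … 3.0, with a 300 ms refractory), gates candidates by a
rolling-mean envelope, keeps the scan whose interval SD is smallest
subject to a plausible rate (40–180 bpm), and refines peak times by
parabolic interpolation. Intervals outside 300–2000 ms or further than
`max(0.25 × median, 150 ms)` from a moving median are rejected before
any feature computation. On clean signals the continuous features of
the P- and O-tachograms agree to within a few percent; the discrete
threshold counts (pnn20/pnn50) are intrinsically noisier and are not
held to that agreement.

## 4. Level statistics and feature selection (`wearstress.stats`)

- Per feature, a within-subject level-effect test gated by normality:
  if any level fails Shapiro-Wilk (p < 0.05) or is constant, the
  tie-corrected Friedman test with Kendall's `W = Q / (n(k−1))` is
  used; otherwise a repeated-measures ANOVA with generalized
  eta-squared. Post hoc comparisons (Wilcoxon signed-rank or paired t,
  matching the omnibus branch) are Bonferroni-corrected over the 6
  level pairs.
- Collinearity pruning: single-linkage clusters over
  |Spearman ρ| > 0.8 with p < 0.05 (union-find); the cluster member
  with the highest label correlation represents the cluster.
- Ranking of significant representatives: by number of significant
  post hoc pairs, then |Spearman| correlation with the level label,
  ties broken alphabetically; truncated to top-3/5/7 sets.

## 5. Classification (`wearstress.classify`)

Nested leave-one-subject-out cross-validation: the outer loop holds out
all four rows of one subject; the inner loop tunes hyperparameters on
the training subjects only, by maximizing stratified 3-fold accuracy
with a Gaussian-process search (Matern-5/2, expected improvement over
256 random candidates per iteration) over per-model spaces (SVM: C,
gamma; kNN: neighbors, weights; random forest: trees, depth; gradient
boosting: trees, depth, learning rate). Standardization is fit on the
training fold only and applied to SVM and kNN. The kNN neighbor count
is clamped to the fitted-fold size. Metrics are pooled over held-out
rows: accuracy, macro precision/recall/F1, and one-vs-rest macro AUC,
plus the 4×4 confusion matrix. Feature attribution uses *exact* Shapley
values of the predicted-class probability by full coalition enumeration
(2^k evaluations against the training-fold median; feasible because the
sets have ≤ 7 features). Repeated runs over seeds are averaged.

## 6. Influencing factors (`wearstress.factors`)

`PerformanceScore = (points − errors) / duration` per level. Its effect
on each candidate feature is the Wald test of the `performance` slope in
the mixed model `feature ~ C(level) + performance` with a random
intercept per subject (REML). Slope p-values are corrected by both
Bonferroni and Benjamini–Hochberg over the converged models; models
that fail to converge are flagged and excluded from correction.
Subject-level analyses average features over the four levels and
correlate them (Pearson and Spearman) with mean performance or the PSS
score. PSS groups follow the standard bins: low ≤ 13, moderate 14–26,
high 27–40; the `NegDerMean` contrast between low and moderate groups
is reported descriptively (median and quartiles per level).

## 7. Numerical and scale notes

- All random draws use `numpy.random.default_rng`; seeds stay below
  2^31.
- Problem sizes: a session is ~315 s (1 260 EDA samples in the analysis
  window); the decomposition QP has ~1 300 variables; a 23-subject
  cohort yields a 92 × 102 table; full feature extraction for a cohort
  takes ~30 s on one CPU and a tuned kNN LOSO run a few seconds.
- The generator's defaults are the study conditions assumed throughout;
  analyses never re-tune them.

## 8. Limitations

All quantitative statements in the README and the test suite are
computed on synthetic data; they validate the machinery (recovery of
known ground truth, oracle agreement, chance-level behavior under label
permutation), not the field performance of any device. The feature
inventory fixes one concrete realization of commonly used EDA/HRV
batteries; alternative definitions (e.g. sample vs population SD,
different entropy radii) shift absolute values and are deliberately
pinned by the tests.
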