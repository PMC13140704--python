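# Methods

This note documents the models, conventions and design choices behind
`spo2delta`, and what the synthetic-data subsystem does and does not
emulate.

## Signals and quality control

The analysis unit is a contiguous, gap-free 1 Hz SpO2 segment in percent.
Raw exports (two-column `t_s,spo2` CSV or single-column value-per-line
text, optionally gzipped) may contain gaps and out-of-range samples; both
terminate a "valid run" identically, because the method is defined on
noise-free series and performs no imputation. Timestamps must be whole
seconds and strictly increasing — duplicated or sub-second stamps are
rejected rather than silently merged. Default required durations are
1200 s for ICU patients, 600 s for short recordings (the acute-liver-failure
convention), and 480 s for healthy hypoxia exposures; segment extraction
takes the *earliest* qualifying run for patients (first available data of
the ICU stay) and the *final* samples of the last run for exposures
(approximating a stable hypoxic state). Values are never rescaled; integer
percent, the bedside-monitor dialect, is the expected patient input.

## Sample entropy and multiscale entropy

SampEn(m, t) = −ln(A/B), where B counts template pairs of length m within
Chebyshev distance t and A the pairs still within t at length m + 1.
Conventions that matter:

* Both counts run over the N − m templates that possess an (m+1)-point
  extension, each unordered pair once, self-matches excluded.
* The tolerance is **inclusive** (≤ t). Consequently a constant series,
  whose SD and hence tolerance are zero, yields SampEn 0 — the correct
  "perfectly regular" limit — instead of an error.
* Defaults m = 2, r = 0.2. `tolerance_mode="relative_sd"` (default) sets
  t = r × SD(segment) with sample SD (N−1); `"absolute"` uses r directly
  in percentage points. Both are exposed because the distinction is
  material for integer-quantised SpO2: the source analyses specify only
  r = 0.2, and relative-to-SD is the canonical reading, so it is the
  default.
* Zero-match degeneracies (B = 0 or A = 0) return "undefined" with a
  reason code; no plug-in correction is applied, and such subjects are
  excluded from δ with the exclusion flagged downstream.

MSE coarse-grains the series into non-overlapping windows of length τ
(window means, remainder discarded, output length ⌊N/τ⌋) for τ = 1…5 and
recomputes SampEn at each scale using **one absolute tolerance frozen from
the scale-1 series** — the standard multiscale convention; re-deriving the
tolerance per scale would mask the variance reduction that coarse-graining
induces on random signals. The per-scale values are averaged into an
overall complexity index; undefined scales are dropped from the average.
White noise shows a flat-to-decreasing per-scale profile, structured
physiological signals an increasing one, which is what makes MSE a noise
filter for the δ interpretation. The patient-table "SpO2 entropy" used for
δ is the scale-1 value.

The implementation counts matches with row-blocked boolean comparisons
(O(N²) time, bounded memory); it is validated against an independent
full-distance-matrix enumeration oracle to < 1e−12 in the test suite.

## Reference line and δ

The healthy reference is an OLS regression of SampEn on mean SpO2.
Default `fit_mode="group_mean"`: per-subject points are first averaged
within each FiO2 level and the line is fitted through the (typically four)
level means, equally weighted — the graded-exposure design yields its
near-unity R² only at level-mean resolution. `per_subject` is available
for sensitivity analysis. The line is serialisable to JSON so patient
analysis can run without the raw reference signals.

δ = (m·x − y + b)/√(m² + 1) is applied to raw (percent, entropy)
coordinates without axis standardisation, exactly as the formula is
defined; δ therefore carries the mixed units of that plane. The sign is
preserved: positive below the line (entropy deficit), negative above.
δ is linear in y with coefficient −1/√(m²+1) and in x with m/√(m²+1),
and for the fitted points of a line the δ values sum to zero (they are a
fixed multiple of the vertical OLS residuals).

## Cohort statistics

* Survivor comparisons use the pooled-variance Student's t (two-sided) by
  default, Welch by switch; α = 0.05 throughout with no multiplicity
  correction.
* Continuous predictors are z-scored (sample SD) before Cox regression so
  hazard ratios are per SD; the transform parameters are returned so
  per-unit effects can be reported alongside.
* Cox fits delegate to lifelines (Efron tie handling by default — ICU
  day-resolution times tie often — Breslow via an explicit exact-likelihood
  refit), with tightened Newton convergence so estimates agree with a
  brute-force partial-likelihood maximiser to < 1e−4. Identifiability is
  checked up front (no constant or collinear covariates, ≥ 1 event);
  Wald 95% CIs are exp(β ± 1.96·se).
* The proportional-hazards diagnostic correlates scaled Schoenfeld
  residuals with event-time *rank* (lifelines' rank transform), flags at
  α = 0.05, requires ≥ 3 events, and never blocks a fit.
* ROC AUC uses the rank (Mann–Whitney) estimator with tie correction and
  a Hanley–McNeil normal-approximation CI.
* Bland–Altman: differences a − b, bias ± 1.96 SD limits (sample SD),
  strict-inequality outside counts.
* Event coding (1 = died *or transplanted* within the 30-day horizon,
  0 = censored at 30 days) is a cohort-assembly convention, applied before
  the fit, not inside it.

## Synthetic data

The generator exists so the pipeline is testable without restricted ICU
waveforms. What it emulates, and how:

* **Signals** are a MIX-style process: a slow sinusoid (default amplitude
  0.8%, period 180 s) around a target mean, each sample independently
  replaced by uniform noise (half-width 6%) with probability p, then
  mean-corrected (SampEn is translation-invariant), clipped to [0, 100]
  and optionally quantised to integers (on by default for patient-like
  signals, off for the continuous reference). The 180 s period keeps the
  deterministic limit genuinely regular at m = 2 (per-step divergence of
  mirrored-phase templates below the tolerance), giving a wide,
  near-monotone p → SampEn map — the property the calibration relies on.
  The p → SampEn map is inverted by bisection against Monte-Carlo means
  (`calibrate_irregularity`); signal-level cohort generation adds a local
  grid-plus-interpolation search on realised values so each subject's
  actual segment hits its planted (x, y) closely.
* **Reference study**: FiO2 levels 21/17/14.5/12% with 12/12/12/11
  subjects and 480 s final segments. Level target means follow a
  plausible dose-response (97.7, 94.5, 90.5, 85.0%); level target
  entropies follow a linear law anchored at the healthy normoxic point
  (97.7%, SampEn 0.115) with slope −0.03 entropy units per percent — a
  value chosen once to match the geometry of the healthy inverse
  relationship, since no numeric slope is published. Between-subject
  jitter: SD 0.6% on means, lognormal σ 0.12 on p.
* **Cohorts** default to the printed sepsis-cohort conditions: n = 164
  with 34 non-survivors, survivor δ ~ N(0.0391, 0.0827²), non-survivor
  δ ~ N(0.113, 0.126²), mean SpO2 ~ N(97.1, 3.5²) clipped to [80, 99.9],
  SOFA ~ rounded N(4.7, 3²), ventilation Bernoulli(0.5). Feature-level
  mode inverts the δ formula exactly (y = ŷ − δ√(m²+1)), so the round
  trip through `batch_delta` is exact; planted δ is capped so the implied
  SampEn stays positive, which shrinks extreme positive deviations at
  near-ceiling saturations (a real entropy-floor effect, but note it pulls
  the realised stratum means below the nominal ones). Survival is either
  stratum-driven (non-survivors die at truncated-exponential times inside
  the horizon; survivors censored at 30 days) or hazard-driven through an
  exponential model rate·exp(Σβ_k z_k) on z-scored covariates for
  parameter-recovery studies.

What it does **not** emulate: oximeter noise and motion artefacts,
autocorrelated desaturation episodes, the physiological coupling between
saturation level and variability within a subject, SOFA/MELD computation
from labs, or non-proportional hazards (a Weibull switch would be needed;
PH-violation tests instead plant a piecewise effect directly). Passing
tests therefore demonstrate the *correctness of the computations and the
internal consistency of the framework*, not the clinical effect sizes,
which come from restricted data.

## Problem sizes and numerics

The test suite validates the entropy estimator on 100 random series up to
N = 300 against exact enumeration; multiscale behaviour on 50 seeds of
N = 3000 white noise; δ geometry on 1000 random point/line triples; Cox
estimation on 200 replicates of n = 500 hazard-driven cohorts (mean β̂
within ±0.05 of the true 0.6, CI coverage 92–97%); survivor-comparison
power on 200 replicates at the sepsis cohort size n = 164; and the
signal-level planted-δ round trip on 12 subjects of 1200 s (mean |Δδ| ≤
0.15 × SD of planted δ). The acceptance script uses 50 Cox replicates and
a 40-subject signal-level cohort. Tolerances: SampEn oracle equality at
1e−12; OLS agreement at 1e−10 relative; Cox oracle agreement at 1e−4
(lifelines convergence tightened to a 1e−9 step norm for this reason);
round-trip δ at 1e−9 in feature mode. Degenerate inputs (constant series,
zero-SD covariates, single-class outcomes, < 3 events) raise typed errors
or return undefined-with-reason rather than NaNs.
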