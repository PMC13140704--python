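# spo2delta

Tools for interpreting **oxygen-saturation variability** (OSV) in critical
illness. Continuous 1 Hz pulse-oximetry (SpO2) signals fluctuate in a
structured way: in healthy people the irregularity of those fluctuations —
measured by **sample entropy** (SampEn) — *rises* as hypoxia deepens and mean
SpO2 falls, reflecting active engagement of cardiorespiratory control. Entropy
alone is therefore ambiguous in patients: a low value can mean either "stable
and unchallenged" or "challenged but unable to respond". This package
implements the normalisation that resolves the ambiguity: the **directional
parenclitic deviation** δ of a subject's (mean SpO2, SampEn) point from a
healthy hypoxia-response reference line, and the survival analysis used to
evaluate δ as a prognostic marker in ICU cohorts.

## The model

For a reference line `y = m·x + b` fitted by ordinary least squares to healthy
(mean SpO2 `x`, SampEn `y`) points under graded hypoxia, a subject's deviation
is the signed perpendicular distance

```
δ = (m·x − y + b) / √(m² + 1)
```

No absolute value is taken: δ > 0 means *less* entropy than a healthy subject
would show at that saturation (blunted regulatory engagement, the pattern seen
in sepsis and COPD), δ < 0 means *more* (over-engagement, the pattern seen in
cirrhosis). SampEn uses template length m = 2 and tolerance r = 0.2 (default:
0.2 × SD of the segment, Chebyshev distance, self-matches excluded); a 5-scale
multiscale-entropy (MSE) profile with a single scale-1 tolerance distinguishes
genuine complexity from noise. Prognostic value is assessed with Cox
proportional-hazards regression of 30-day ICU mortality on z-scored
predictors (hazard ratios per SD), proportional-hazards diagnostics via
scaled Schoenfeld residuals, ROC discrimination, and Bland–Altman agreement
between recording durations.

Because the ICU waveform data this methodology targets sit behind
credentialled access, the package includes a first-class synthetic subsystem:
MIX-style signal generation with calibratable entropy, a simulated
graded-hypoxia reference study, and cohorts with planted δ structure and
exponential survival — enough to exercise and validate every stage of the
pipeline end to end.

## Worked example

```python
from spo2delta import (ReferencePoint, fit_reference, gen_reference_population)

table = gen_reference_population(seed=3)          # simulated hypoxia study
points = [ReferencePoint(fio2=r.fio2, mean_spo2=r.mean_spo2, sampen=r.sampen)
          for r in table.itertuples()]
line = fit_reference(points, fit_mode="group_mean")
print(f"SampEn = {line.slope:.4f} * meanSpO2 + {line.intercept:.3f} "
      f"(R^2 = {line.r_squared:.4f})")
```

prints

```
SampEn = -0.0367 * meanSpO2 + 3.681 (R^2 = 0.9990)
```

— the healthy inverse mean–entropy relationship: per percentage point of
desaturation, entropy rises by ≈ 0.037, and the four FiO2 level means are
almost exactly collinear. Scoring a patient against that line
(`examples/02_entropy_and_delta.py`) prints

```
mean SpO2 = 95.52%  SampEn = 0.1122
expected SampEn at this saturation: 0.2069
parenclitic deviation delta = +0.0946 (below the healthy line)
```

i.e. this subject shows roughly half the entropy a healthy person would at
95.5% saturation — a positive δ of the size seen in septic non-survivors.
`examples/03_survival_analysis.py` completes the picture on a synthetic
164-patient cohort (univariate hazard ratio ≈ 1.5 per SD of δ, PH assumption
satisfied, risk-score AUC ≈ 0.65 for δ+SOFA+ventilation with this seed).

The `spo2delta` console command exposes the same pipeline for shell use
(`spo2delta reference-fit`, `entropy`, `delta`, `survival`, `agreement`,
`simulate`).

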