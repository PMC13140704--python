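"""Synthetic SpO2 signals, reference populations, cohorts and survival times.

Real ICU oximetry for this kind of study sits behind credentialled access,
so the package ships a generator subsystem that emulates the statistical
features the analysis pipeline depends on:

* **Signals** — a MIX-style process: a small slow sinusoid around a target
  mean, each sample independently replaced by uniform noise with
  probability ``p``. The single parameter ``p`` maps monotonically (in
  expectation) onto SampEn over a wide range, which makes entropy
  calibration a one-dimensional search. Signals are mean-corrected (SampEn
  is translation-invariant, so this costs nothing), clipped to [0, 100] and
  optionally quantised to integer percent — the dialect of bedside-monitor
  exports.
* **Reference population** — graded normobaric hypoxia exposures at FiO2
  21 / 17 / 14.5 / 12 % with 12 / 12 / 12 / 11 subjects and 480 s (8 min)
  final segments. Level target means follow a physiologically plausible
  dose-response; level target entropies follow a linear law anchored at the
  healthy normoxic point (97.7 %, SampEn 0.115) with slope -0.03 entropy
  units per percent SpO2, so the fitted group-mean reference line is
  negative-sloped and tightly linear by construction.
* **Patient cohorts** — either *feature-level* (draw mean SpO2 and a
  planted delta per outcome stratum, invert the delta formula exactly to
  get SampEn — an algebraic round trip) or *signal-level* (additionally
  synthesise a signal whose realised mean and entropy hit the planted
  coordinates, then recompute everything from the signal).
* **Survival** — exponential times: either hazard-driven
  (rate_i = baseline_rate * exp(sum beta_k z_k) on z-scored covariates,
  censored at the 30-day horizon) or stratum-driven (non-survivors die at a
  truncated-exponential time inside the horizon, survivors are censored).

Defaults mirror the printed sepsis-cohort conditions: n = 164 with 34
non-survivors, survivor delta 0.0391 +- 0.0827, non-survivor delta
0.113 +- 0.126, mean SpO2 97.1 +- 3.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .complexity import EntropyParams, sample_entropy
from .exceptions import CalibrationRangeError, DegenerateInputError
from .reference import ReferenceLine, batch_delta
from .signal_io import OximetrySegment

# level -> target mean SpO2 (%) for the default hypoxia dose-response
_DEFAULT_DOSE_RESPONSE = {21.0: 97.7, 17.0: 94.5, 14.5: 90.5, 12.0: 85.0}
# linear entropy target: anchored at the healthy normoxic point
_ENTROPY_ANCHOR_X = 97.7
_ENTROPY_ANCHOR_Y = 0.115
_ENTROPY_SLOPE = -0.03  # entropy units per percent SpO2


@dataclass(frozen=True)
class HypoxiaProtocol:
    """Graded hypoxic-exposure protocol for the reference population."""

    fio2_levels: tuple[float, ...] = (21.0, 17.0, 14.5, 12.0)
    n_subjects: tuple[int, ...] = (12, 12, 12, 11)
    exposure_duration_s: int = 480
    mean_jitter_sd: float = 0.6      # between-subject spread of mean SpO2 (%)
    irregularity_jitter_sd: float = 0.12  # lognormal sigma on per-subject p

    def __post_init__(self):
        if len(self.fio2_levels) != len(self.n_subjects):
            raise ValueError("fio2_levels and n_subjects length mismatch")
        if any(b >= a for a, b in zip(self.fio2_levels, self.fio2_levels[1:])):
            raise ValueError("fio2_levels must be strictly decreasing")
        if self.exposure_duration_s < 40:
            raise ValueError("exposure too short for entropy computation")


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Conditions for a synthetic patient cohort.

    If ``beta`` is None, outcomes are stratum-driven: a fixed non-survivor
    fraction with per-stratum planted delta distributions (mean, sd). If
    ``beta`` maps covariate names (subset of delta/sofa/mech_vent) to true
    per-SD log hazards, survival is hazard-driven through an exponential
    model and delta is drawn from the pooled (survivor-stratum) distribution.
    """

    n: int = 164
    mode: str = "feature_level"  # or "signal_level"
    delta_survivor: tuple[float, float] = (0.0391, 0.0827)
    delta_nonsurvivor: tuple[float, float] = (0.113, 0.126)
    nonsurvivor_frac: float = 34 / 164
    beta: Mapping[str, float] | None = None
    baseline_rate: float = 0.012      # events per day (hazard-driven mode)
    death_rate: float = 0.08          # per day within horizon (stratum mode)
    horizon: float = 30.0             # days
    x_mean: float = 97.1
    x_sd: float = 3.5
    sofa_mean: float = 4.7
    sofa_sd: float = 3.0
    mech_vent_frac: float = 0.5
    signal_duration_s: int = 1200
    quantize: bool = True

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.baseline_rate <= 0 or self.horizon <= 0:
            raise ValueError("baseline_rate and horizon must be positive")
        if self.mode not in ("feature_level", "signal_level"):
            raise ValueError(f"unknown mode {self.mode!r}")


# ------------------------------------------------------------------ signals

def gen_spo2_signal(
    target_mean: float,
    irregularity: float,
    duration_s: int,
    seed: int | np.random.Generator,
    quantize: bool = False,
    noise_amplitude: float = 6.0,
    sine_amplitude: float = 0.8,
    sine_period_s: float = 180.0,
    subject_id: str = "synthetic",
) -> OximetrySegment:
    """MIX-style synthetic SpO2 segment at 1 Hz.

    ``irregularity`` in [0, 1] is the per-sample probability of replacing
    the deterministic sinusoid with uniform noise of half-width
    ``noise_amplitude``. The realised mean is corrected to ``target_mean``
    (translation leaves SampEn unchanged) before clipping to [0, 100] and
    optional integer quantisation.
    """
    if not 0.0 <= irregularity <= 1.0:
        raise ValueError("irregularity must lie in [0, 1]")
    if not 50.0 < target_mean <= 100.0:
        raise ValueError("target_mean must lie in (50, 100]")
    if duration_s < 20:
        raise DegenerateInputError("duration too short for a meaningful segment")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.arange(duration_s, dtype=float)
    phase = rng.uniform(0, 2 * np.pi)
    x = target_mean + sine_amplitude * np.sin(2 * np.pi * t / sine_period_s + phase)
    if irregularity > 0:
        replace = rng.random(duration_s) < irregularity
        noise = rng.uniform(target_mean - noise_amplitude,
                            target_mean + noise_amplitude, duration_s)
        x = np.where(replace, noise, x)
    x += target_mean - x.mean()
    x = np.clip(x, 0.0, 100.0)
    if quantize:
        x = np.round(x)
    return OximetrySegment(subject_id=subject_id, values=x, group_label="synthetic")


def _mean_sampen(
    p: float, target_mean: float, duration_s: int, params: EntropyParams,
    quantize: bool, reps: int, seeds: np.random.SeedSequence,
) -> float:
    vals = []
    for child in seeds.spawn(reps):
        seg = gen_spo2_signal(target_mean, p, duration_s,
                              np.random.default_rng(child), quantize=quantize)
        res = sample_entropy(seg.values, params)
        if res.defined:
            vals.append(res.value)
    return float(np.mean(vals)) if vals else 0.0


def calibrate_irregularity(
    target_sampen: float,
    params: EntropyParams = EntropyParams(),
    duration_s: int = 1200,
    seed: int = 0,
    target_mean: float = 96.0,
    quantize: bool = False,
    reps: int = 20,
    rel_tol: float = 0.10,
) -> float:
    """Find the irregularity p whose expected SampEn matches a target.

    Bisection over p in [0, 1] against the Monte-Carlo mean SampEn
    (``reps`` realisations per probe), stopping when the probe mean is
    within ``rel_tol`` (relative) of the target. Raises
    :class:`CalibrationRangeError` when the target lies outside the
    achievable [p=0, p=1] entropy interval.
    """
    ss = np.random.SeedSequence(seed)
    ss_lo, ss_hi, ss_probe = ss.spawn(3)
    lo_val = _mean_sampen(0.0, target_mean, duration_s, params, quantize, reps, ss_lo)
    hi_val = _mean_sampen(1.0, target_mean, duration_s, params, quantize, reps, ss_hi)
    low, high = min(lo_val, hi_val), max(lo_val, hi_val)
    if not (low - 1e-9) <= target_sampen <= (high + 1e-9):
        raise CalibrationRangeError(
            f"target SampEn {target_sampen:.4f} outside achievable "
            f"[{low:.4f}, {high:.4f}]", low, high)
    p_lo, p_hi = 0.0, 1.0
    probe_seeds = ss_probe.spawn(24)
    p_mid = 0.5
    for k in range(24):
        p_mid = 0.5 * (p_lo + p_hi)
        val = _mean_sampen(p_mid, target_mean, duration_s, params, quantize,
                           reps, probe_seeds[k])
        if abs(val - target_sampen) <= rel_tol * max(target_sampen, 1e-6):
            return p_mid
        if val < target_sampen:
            p_lo = p_mid
        else:
            p_hi = p_mid
        if p_hi - p_lo < 1e-4:
            break
    return p_mid


# ------------------------------------------------- reference population

def gen_reference_population(
    protocol: HypoxiaProtocol = HypoxiaProtocol(),
    params: EntropyParams = EntropyParams(),
    seed: int = 0,
    dose_response: Mapping[float, float] | None = None,
    return_signals: bool = False,
):
    """Simulate the graded-hypoxia reference study.

    Per subject per level: generate a final-exposure segment whose target
    mean follows the dose-response and whose irregularity is calibrated so
    expected SampEn follows the linear entropy law; then compute the
    realised (mean SpO2, SampEn) through the complexity module. Returns a
    DataFrame with columns fio2 / subject_id / mean_spo2 / sampen (and the
    signal dict when requested).
    """
    dose = dict(_DEFAULT_DOSE_RESPONSE if dose_response is None else dose_response)
    ss = np.random.SeedSequence(seed)
    level_seeds = ss.spawn(len(protocol.fio2_levels))
    rows = []
    signals: dict[str, OximetrySegment] = {}
    for (fio2, n_subj), lvl_ss in zip(
        zip(protocol.fio2_levels, protocol.n_subjects), level_seeds
    ):
        x_level = dose.get(fio2)
        if x_level is None:  # linear interpolation over FiO2 for custom levels
            ks, vs = zip(*sorted(dose.items()))
            x_level = float(np.interp(fio2, ks, vs))
        y_level = _ENTROPY_ANCHOR_Y + _ENTROPY_SLOPE * (x_level - _ENTROPY_ANCHOR_X)
        cal_ss, subj_ss = lvl_ss.spawn(2)
        p_level = calibrate_irregularity(
            y_level, params, protocol.exposure_duration_s,
            seed=cal_ss.generate_state(1)[0] % (2**31),
            target_mean=x_level, reps=10)
        rng = np.random.default_rng(subj_ss)
        for i in range(n_subj):
            mean_i = float(np.clip(x_level + rng.normal(0, protocol.mean_jitter_sd),
                                   55.0, 100.0))
            p_i = float(np.clip(
                p_level * rng.lognormal(0, protocol.irregularity_jitter_sd), 0, 1))
            seg = gen_spo2_signal(
                mean_i, p_i, protocol.exposure_duration_s, rng,
                quantize=False, subject_id=f"ref{fio2:g}_{i:02d}")
            res = sample_entropy(seg.values, params)
            rows.append({
                "fio2": fio2,
                "subject_id": seg.subject_id,
                "mean_spo2": seg.mean_spo2,
                "sampen": res.value if res.defined else np.nan,
            })
            if return_signals:
                signals[seg.subject_id] = seg
    table = pd.DataFrame(rows)
    return (table, signals) if return_signals else table


# ------------------------------------------------------- patient cohorts

def _draw_survival(rng: np.random.Generator, rate: np.ndarray,
                   horizon: float) -> tuple[np.ndarray, np.ndarray]:
    t = rng.exponential(1.0 / rate)
    event = (t <= horizon).astype(int)
    return np.minimum(t, horizon), event


def _target_signal(
    target_mean: float, target_y: float, duration_s: int, params: EntropyParams,
    quantize: bool, ss: np.random.SeedSequence,
) -> tuple[OximetrySegment, float]:
    """Synthesise a signal whose realised SampEn is close to target_y.

    One cheap bisection calibration seeds a local grid search over p around
    the calibrated value; a second stage interpolates p against the realised
    grid entropies and draws further realisations there. The realisation
    minimising |SampEn - target| overall is returned together with its
    realised entropy.
    """
    cal_ss, grid_ss, fine_ss = ss.spawn(3)
    try:
        p0 = calibrate_irregularity(
            target_y, params, duration_s,
            seed=cal_ss.generate_state(1)[0] % (2**31),
            target_mean=target_mean, quantize=quantize, reps=5, rel_tol=0.08)
    except CalibrationRangeError as exc:
        p0 = 0.0 if target_y <= exc.achievable_low else 1.0
    factors = np.array([0.55, 0.7, 0.85, 1.0, 1.15, 1.35, 1.6, 1.9])
    candidates = np.clip(p0 * factors, 0.0, 1.0)
    if p0 == 0.0:
        candidates = np.linspace(0.0, 0.05, len(factors))
    best_seg, best_y, best_err = None, np.nan, np.inf
    probed: list[tuple[float, float]] = []

    def _try(p: float, child: np.random.SeedSequence):
        nonlocal best_seg, best_y, best_err
        seg = gen_spo2_signal(target_mean, float(p), duration_s,
                              np.random.default_rng(child), quantize=quantize)
        res = sample_entropy(seg.values, params)
        if not res.defined:
            return
        probed.append((float(p), res.value))
        err = abs(res.value - target_y)
        if err < best_err:
            best_seg, best_y, best_err = seg, res.value, err

    for p, child in zip(candidates, grid_ss.spawn(len(candidates))):
        _try(p, child)
    # stage 2: interpolate p for the target on the realised (p, y) map and
    # take repeated draws there, keeping the best realisation overall
    if probed and best_err > 1e-4:
        ps, ys = zip(*sorted(probed, key=lambda q: q[1]))
        p_star = float(np.clip(np.interp(target_y, ys, ps), 0.0, 1.0))
        for child in fine_ss.spawn(10):
            _try(p_star, child)
    if best_seg is None:  # pathological; fall back to the deterministic limit
        best_seg = gen_spo2_signal(target_mean, 0.0, duration_s,
                                   np.random.default_rng(grid_ss), quantize=quantize)
        best_y = sample_entropy(best_seg.values, params).value or 0.0
    return best_seg, float(best_y)


def gen_patient_cohort(
    spec: SyntheticCohortSpec,
    line: ReferenceLine,
    params: EntropyParams = EntropyParams(),
    seed: int = 0,
    return_signals: bool = False,
):
    """Generate a synthetic patient cohort with planted delta structure.

    Feature-level mode inverts the delta formula exactly
    (y = slope*x + intercept - delta*sqrt(slope^2+1)), so recomputing delta
    from (x, y) recovers the planted values to floating-point precision.
    Signal-level mode synthesises an actual segment per subject targeting
    the planted (x, y) and recomputes features from it; ``delta_planted``
    records the intended value in both modes.

    Returns a DataFrame with the cohort CSV schema (subject_id, group,
    time_days, event, mean_spo2, sampen, delta, delta_planted, sofa, meld,
    mech_vent) and optionally the signal dict.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    sig_ss = np.random.SeedSequence(seed).spawn(2)[1]
    n = spec.n
    denom = float(np.sqrt(line.slope**2 + 1.0))

    x = np.clip(rng.normal(spec.x_mean, spec.x_sd, n), 80.0, 99.9)
    sofa = np.clip(np.round(rng.normal(spec.sofa_mean, spec.sofa_sd, n)), 0, 24)
    meld = np.clip(np.round(rng.normal(14.0, 8.0, n)), 6, 40)
    mech_vent = (rng.random(n) < spec.mech_vent_frac).astype(int)

    y_hat = line.predict(x)
    # delta is capped so the implied SampEn stays positive
    delta_cap = (y_hat - 0.005) / denom

    if spec.beta is None:
        n_nonsurv = int(round(n * spec.nonsurvivor_frac))
        stratum = np.zeros(n, dtype=int)
        stratum[rng.choice(n, size=n_nonsurv, replace=False)] = 1
        mu = np.where(stratum == 1, spec.delta_nonsurvivor[0], spec.delta_survivor[0])
        sd = np.where(stratum == 1, spec.delta_nonsurvivor[1], spec.delta_survivor[1])
        delta = np.minimum(rng.normal(mu, sd), delta_cap)
        event = stratum.copy()
        # truncated-exponential death times inside the horizon
        u = rng.random(n)
        t_death = -np.log(1 - u * (1 - np.exp(-spec.death_rate * spec.horizon))) \
            / spec.death_rate
        time = np.where(event == 1, t_death, spec.horizon)
    else:
        delta = np.minimum(
            rng.normal(spec.delta_survivor[0], spec.delta_survivor[1], n), delta_cap)
        cov_values = {"delta": delta, "sofa": sofa.astype(float),
                      "mech_vent": mech_vent.astype(float)}
        eta = np.zeros(n)
        for name, b in spec.beta.items():
            v = cov_values[name]
            sdv = v.std(ddof=1)
            z = (v - v.mean()) / sdv if sdv > 0 else np.zeros(n)
            eta += b * z
        rate = spec.baseline_rate * np.exp(eta)
        time, event = _draw_survival(rng, rate, spec.horizon)

    y = y_hat - delta * denom

    signals: dict[str, OximetrySegment] = {}
    if spec.mode == "signal_level":
        subj_seeds = sig_ss.spawn(n)
        xr = np.empty(n)
        yr = np.empty(n)
        for i in range(n):
            seg, y_real = _target_signal(
                float(x[i]), float(max(y[i], 0.0)), spec.signal_duration_s,
                params, spec.quantize, subj_seeds[i])
            seg = OximetrySegment(subject_id=f"pt{i:04d}", values=seg.values,
                                  group_label="synthetic")
            signals[seg.subject_id] = seg
            xr[i] = seg.mean_spo2
            yr[i] = y_real
        x_out, y_out = xr, yr
    else:
        x_out, y_out = x, y

    cohort = pd.DataFrame({
        "subject_id": [f"pt{i:04d}" for i in range(n)],
        "group": "synthetic",
        "time_days": time,
        "event": event,
        "mean_spo2": x_out,
        "sampen": y_out,
        "sofa": sofa.astype(int),
        "meld": meld.astype(int),
        "mech_vent": mech_vent,
    })
    cohort = batch_delta(cohort, line)
    cohort["delta_planted"] = delta
    if return_signals:
        return cohort, signals
    return cohort
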