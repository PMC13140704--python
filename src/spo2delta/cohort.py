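"""Cohort-level statistical evaluation of delta and companion features.

Covers the survivor/non-survivor comparisons (Student's t), z-scoring of
continuous predictors so hazard ratios are per standard deviation, Cox
proportional-hazards regression for 30-day ICU mortality with a
proportional-hazards diagnostic, ROC-based discrimination, and Bland-Altman
agreement between delta computed from recordings of different durations.

The Cox partial-likelihood machinery is delegated to lifelines
(Efron tie handling by default, Breslow as a switch); this module owns the
cohort conventions around it: event coding (1 = died or transplanted within
the horizon), censoring at the 30-day horizon, per-SD covariate scaling,
and identifiability checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import proportional_hazard_test

from .exceptions import DegenerateInputError, NonIdentifiableError, SchemaError

DEFAULT_HORIZON_DAYS = 30.0
ALPHA = 0.05  # two-sided significance threshold used in reports


# ---------------------------------------------------------------- z-scoring

def zscore(values: Sequence[float] | np.ndarray) -> tuple[np.ndarray, float, float]:
    """Standardise to mean 0, sample SD 1 (denominator n-1).

    Returns (z, mean, sd) so per-SD hazard ratios can be mapped back to the
    original units.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise DegenerateInputError("z-scoring needs at least 2 values")
    mu, sd = float(np.mean(x)), float(np.std(x, ddof=1))
    if sd == 0:
        raise NonIdentifiableError("constant covariate cannot be z-scored")
    return (x - mu) / sd, mu, sd


# ------------------------------------------------------------------ t-test

@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    welch: bool = False


def two_group_t(
    values_a: Sequence[float],
    values_b: Sequence[float],
    welch: bool = False,
) -> TTestResult:
    """Independent-samples Student's t-test (pooled variance by default,
    Welch by switch), two-sided p."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DegenerateInputError("each group needs at least 2 observations")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    if welch:
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    else:
        df = len(a) + len(b) - 2
    return TTestResult(
        t=float(res.statistic), df=float(df), p=float(res.pvalue),
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)), n_a=len(a),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)), n_b=len(b),
        welch=welch,
    )


# ----------------------------------------------------------------- Cox fit

@dataclass(frozen=True)
class CovariateEffect:
    name: str
    beta: float
    hazard_ratio: float
    se: float
    ci95_low: float
    ci95_high: float
    p_value: float


@dataclass(frozen=True)
class CoxModelFit:
    effects: tuple[CovariateEffect, ...]
    log_partial_likelihood: float
    n: int
    n_events: int
    converged: bool
    ties: str
    warnings: tuple[str, ...] = ()

    def effect(self, name: str) -> CovariateEffect:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)

    def linear_predictor(self, covariates: pd.DataFrame) -> np.ndarray:
        betas = np.array([e.beta for e in self.effects])
        X = covariates[[e.name for e in self.effects]].to_numpy(dtype=float)
        return X @ betas

    def to_dict(self) -> dict:
        return {
            "effects": [e.__dict__ for e in self.effects],
            "log_partial_likelihood": self.log_partial_likelihood,
            "n": self.n,
            "n_events": self.n_events,
            "converged": self.converged,
            "ties": self.ties,
            "warnings": list(self.warnings),
        }


def cox_fit(
    covariates: pd.DataFrame,
    time: Sequence[float],
    event: Sequence[int],
    ties: Literal["efron", "breslow"] = "efron",
) -> CoxModelFit:
    """Cox proportional-hazards fit of the given covariates on survival.

    ``covariates`` is an (n x p) frame of finite predictors (z-score
    continuous ones beforehand for per-SD hazard ratios); ``time`` in days,
    ``event`` coded 1 for death (or transplant) and 0 for censoring. Efron
    tie handling is the default (ICU day-resolution times tie often);
    Breslow is available as a switch. 95% CIs are Wald: exp(beta +- 1.96 se).
    """
    X = covariates.astype(float)
    if X.isna().any().any() or not np.isfinite(X.to_numpy()).all():
        raise SchemaError("covariates contain missing or non-finite values")
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=int)
    if len(X) != len(t) or len(t) != len(d):
        raise SchemaError("covariates, time and event must have equal lengths")
    if d.sum() < 1:
        raise DegenerateInputError("need at least one event")
    sds = X.std(ddof=1)
    if (sds == 0).any():
        bad = list(sds.index[sds == 0])
        raise NonIdentifiableError(f"constant covariate(s): {bad}")
    if np.linalg.matrix_rank(X.to_numpy() - X.to_numpy().mean(0)) < X.shape[1]:
        raise NonIdentifiableError("collinear covariates: design matrix rank-deficient")

    if ties == "breslow":
        return _breslow_fit(X.to_numpy(), t, d, list(X.columns))
    if ties != "efron":
        raise ValueError(f"unknown ties method {ties!r}")

    df = X.copy()
    df["_time"] = t
    df["_event"] = d
    cph = CoxPHFitter()
    caught: list[str] = []
    converged = True
    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")
        try:
            cph.fit(df, duration_col="_time", event_col="_event", robust=False,
                    fit_options={"precision": 1e-9, "r_precision": 1e-14})
        except ConvergenceError as exc:
            raise NonIdentifiableError(f"Cox fit failed to converge: {exc}") from exc
        for w in wrec:
            msg = str(w.message)
            caught.append(msg)
            if "convergence" in msg.lower() or "monotone" in msg.lower():
                converged = False

    effects = []
    summ = cph.summary
    for name in X.columns:
        beta = float(summ.loc[name, "coef"])
        se = float(summ.loc[name, "se(coef)"])
        effects.append(CovariateEffect(
            name=name, beta=beta, hazard_ratio=float(np.exp(beta)), se=se,
            ci95_low=float(np.exp(beta - 1.96 * se)),
            ci95_high=float(np.exp(beta + 1.96 * se)),
            p_value=float(summ.loc[name, "p"]),
        ))
    return CoxModelFit(
        effects=tuple(effects),
        log_partial_likelihood=float(cph.log_likelihood_),
        n=len(t),
        n_events=int(d.sum()),
        converged=converged,
        ties="efron",
        warnings=tuple(caught),
    )


def _breslow_neg_loglik(beta: np.ndarray, X: np.ndarray, t: np.ndarray,
                        d: np.ndarray) -> float:
    eta = X @ beta
    order = np.argsort(-t)  # decreasing time: cumulative sums give risk sets
    eta_o, t_o, d_o = eta[order], t[order], d[order]
    log_cum = np.logaddexp.accumulate(eta_o)
    # ties share the risk set of their common time: use the last index of each tie run
    ll = 0.0
    i = 0
    n = len(t_o)
    while i < n:
        j = i
        while j + 1 < n and t_o[j + 1] == t_o[i]:
            j += 1
        risk_log = log_cum[j]
        for k in range(i, j + 1):
            if d_o[k]:
                ll += eta_o[k] - risk_log
        i = j + 1
    return -ll


def _breslow_fit(X: np.ndarray, t: np.ndarray, d: np.ndarray,
                 names: list[str]) -> CoxModelFit:
    """Newton-type Breslow fit via BFGS on the exact Breslow partial
    likelihood, with numerical-Hessian Wald SEs."""
    from scipy.optimize import minimize

    res = minimize(_breslow_neg_loglik, np.zeros(X.shape[1]),
                   args=(X, t, d), method="BFGS",
                   options={"gtol": 1e-9, "maxiter": 500})
    beta = res.x
    # central-difference Hessian for the observed information
    p = len(beta)
    h = 1e-5
    H = np.zeros((p, p))
    for i in range(p):
        for j in range(p):
            bpp = beta.copy(); bpp[i] += h; bpp[j] += h
            bpm = beta.copy(); bpm[i] += h; bpm[j] -= h
            bmp = beta.copy(); bmp[i] -= h; bmp[j] += h
            bmm = beta.copy(); bmm[i] -= h; bmm[j] -= h
            H[i, j] = (
                _breslow_neg_loglik(bpp, X, t, d) - _breslow_neg_loglik(bpm, X, t, d)
                - _breslow_neg_loglik(bmp, X, t, d) + _breslow_neg_loglik(bmm, X, t, d)
            ) / (4 * h * h)
    cov = np.linalg.inv(H)
    ses = np.sqrt(np.clip(np.diag(cov), 0, None))
    effects = []
    for k, name in enumerate(names):
        b, se = float(beta[k]), float(ses[k])
        z = b / se if se > 0 else np.inf
        effects.append(CovariateEffect(
            name=name, beta=b, hazard_ratio=float(np.exp(b)), se=se,
            ci95_low=float(np.exp(b - 1.96 * se)),
            ci95_high=float(np.exp(b + 1.96 * se)),
            p_value=float(2 * stats.norm.sf(abs(z))),
        ))
    return CoxModelFit(
        effects=tuple(effects),
        log_partial_likelihood=float(-res.fun),
        n=len(t),
        n_events=int(d.sum()),
        converged=bool(res.success),
        ties="breslow",
    )


# ------------------------------------------------------- PH assumption test

@dataclass(frozen=True)
class PHCheckRow:
    name: str
    corr: float
    p: float
    flagged: bool


def ph_check(
    covariates: pd.DataFrame,
    time: Sequence[float],
    event: Sequence[int],
    fit: CoxModelFit | None = None,
) -> list[PHCheckRow]:
    """Proportional-hazards diagnostic per covariate.

    Correlates the scaled Schoenfeld residuals with the rank of event time
    (lifelines' rank-transform test); a small p flags a time-varying effect
    at alpha = 0.05. Diagnostic only — never blocks the fit. Requires at
    least 3 events, else raises a degenerate-input error.
    """
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=int)
    if d.sum() < 3:
        raise DegenerateInputError(
            f"PH diagnostic undefined with {int(d.sum())} events (need >= 3)"
        )
    df = covariates.astype(float).copy()
    df["_time"] = t
    df["_event"] = d
    cph = CoxPHFitter()
    cph.fit(df, duration_col="_time", event_col="_event")
    res = proportional_hazard_test(cph, df, time_transform="rank")
    rows = []
    for name in covariates.columns:
        stat = float(res.summary.loc[name, "test_statistic"])
        p = float(res.summary.loc[name, "p"])
        # test statistic is chi2(1) on the residual-time correlation; report
        # the signed correlation magnitude implied by it for orientation
        n_ev = int(d.sum())
        corr = float(np.sqrt(stat / max(n_ev - 1, 1)))
        rows.append(PHCheckRow(name=name, corr=corr, p=p, flagged=p < ALPHA))
    return rows


# ------------------------------------------------------------------ ROC AUC

@dataclass(frozen=True)
class AUCResult:
    auc: float
    ci95_low: float
    ci95_high: float
    n_pos: int
    n_neg: int


def roc_auc(risk_scores: Sequence[float], outcome: Sequence[int]) -> AUCResult:
    """AUC of risk scores against a binary outcome at the horizon.

    The rank (Mann-Whitney) estimator with tie correction; CI by the
    Hanley-McNeil normal approximation, clipped to [0, 1].
    """
    y = np.asarray(outcome, dtype=int)
    s = np.asarray(risk_scores, dtype=float)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateInputError("both outcome classes must be present")
    auc = float(roc_auc_score(y, s))
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (auc * (1 - auc) + (n_pos - 1) * (q1 - auc**2)
           + (n_neg - 1) * (q2 - auc**2)) / (n_pos * n_neg)
    se = float(np.sqrt(max(var, 0.0)))
    return AUCResult(
        auc=auc,
        ci95_low=max(0.0, auc - 1.96 * se),
        ci95_high=min(1.0, auc + 1.96 * se),
        n_pos=n_pos,
        n_neg=n_neg,
    )


# -------------------------------------------------------------- Bland-Altman

@dataclass(frozen=True)
class AgreementReport:
    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    n_outside: int
    n_total: int


def bland_altman(measure_a: Sequence[float], measure_b: Sequence[float]) -> AgreementReport:
    """Bland-Altman agreement between paired measurements.

    Differences d = a - b; bias = mean(d); limits of agreement
    bias +- 1.96 SD(d) (sample SD); pairs strictly outside the limits are
    counted. With constant differences the limits collapse to the bias.
    """
    a = np.asarray(measure_a, dtype=float)
    b = np.asarray(measure_b, dtype=float)
    if len(a) != len(b):
        raise SchemaError("paired measurements must have equal lengths")
    if len(a) < 3:
        raise DegenerateInputError("Bland-Altman needs at least 3 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    lo, hi = bias - 1.96 * sd, bias + 1.96 * sd
    outside = int(np.count_nonzero((d < lo) | (d > hi)))
    return AgreementReport(bias=bias, loa_low=lo, loa_high=hi, sd_diff=sd,
                           n_outside=outside, n_total=len(d))


# ------------------------------------------------------------ survivor table

SURVIVOR_FEATURES = ("mean_spo2", "sampen", "delta", "sofa", "meld")


def survivor_table(
    cohort: pd.DataFrame,
    features: Sequence[str] = SURVIVOR_FEATURES,
    group_col: str = "group",
    event_col: str = "event",
) -> pd.DataFrame:
    """Per-group survivor vs non-survivor comparison of signal features and
    severity scores (mean +- SD and Student's t p-value per feature).

    Cells whose stratum has fewer than 2 members are reported as NaN.
    """
    for col in (group_col, event_col):
        if col not in cohort.columns:
            raise SchemaError(f"cohort table missing column {col!r}")
    rows = []
    for grp, sub in cohort.groupby(group_col, sort=False):
        surv = sub[sub[event_col] == 0]
        nons = sub[sub[event_col] == 1]
        for feat in features:
            if feat not in sub.columns or sub[feat].dropna().empty:
                continue
            va = surv[feat].dropna().to_numpy(dtype=float)
            vb = nons[feat].dropna().to_numpy(dtype=float)
            row = {
                "group": grp, "feature": feat,
                "n_survivors": len(va), "n_nonsurvivors": len(vb),
                "survivor_mean": va.mean() if len(va) else np.nan,
                "survivor_sd": va.std(ddof=1) if len(va) > 1 else np.nan,
                "nonsurvivor_mean": vb.mean() if len(vb) else np.nan,
                "nonsurvivor_sd": vb.std(ddof=1) if len(vb) > 1 else np.nan,
            }
            try:
                row["p_value"] = two_group_t(va, vb).p
            except DegenerateInputError:
                row["p_value"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)
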