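"""Healthy hypoxia-reference regression and directional parenclitic deviation.

In healthy individuals SpO2 entropy rises as graded hypoxia lowers mean
SpO2, producing a strong inverse linear relationship between mean SpO2 (x)
and SampEn (y). A patient's deviation from that reference line,

    delta = (slope * x - y + intercept) / sqrt(slope**2 + 1),

is the signed perpendicular distance of the point (x, y) from the line in
the raw (percent, entropy) coordinate plane. No absolute value is taken:
points below the line (lower-than-expected entropy, blunted regulatory
engagement) get positive delta, points above it (higher-than-expected
entropy) negative delta, and that direction is the interpretive content of
the framework.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateInputError, NonIdentifiableError, SchemaError


@dataclass(frozen=True)
class ReferencePoint:
    """One (FiO2 level, mean SpO2, SampEn) reference observation."""

    fio2: float
    mean_spo2: float
    sampen: float
    subject_id: str | None = None

    def __post_init__(self):
        if not 0 <= self.mean_spo2 <= 100:
            raise ValueError("mean_spo2 must lie in [0, 100]")
        if self.sampen < 0:
            raise ValueError("sampen must be >= 0")


@dataclass(frozen=True)
class ReferenceLine:
    """OLS line of SampEn (y) on mean SpO2 (x) in a healthy reference
    population; the normalisation anchor for delta. For a hypoxia reference
    the slope is negative (entropy rises as saturation falls)."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    fit_mode: Literal["group_mean", "per_subject"] = "group_mean"

    def predict(self, x: float | np.ndarray) -> float | np.ndarray:
        return self.slope * x + self.intercept

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "ReferenceLine":
        """Load from a JSON file path or a JSON string."""
        if isinstance(source, Path) or not str(source).lstrip().startswith("{"):
            text = Path(source).read_text()
        else:
            text = str(source)
        d = json.loads(text)
        return cls(
            slope=float(d["slope"]),
            intercept=float(d["intercept"]),
            r_squared=float(d.get("r_squared", float("nan"))),
            n_points=int(d.get("n_points", 0)),
            fit_mode=d.get("fit_mode", "group_mean"),
        )


@dataclass(frozen=True)
class DeviationResult:
    """delta with the coordinates it was computed from."""

    delta: float
    x: float
    y: float
    y_hat: float


def fit_reference(
    points: Sequence[ReferencePoint],
    fit_mode: Literal["group_mean", "per_subject"] = "group_mean",
) -> ReferenceLine:
    """Ordinary least-squares fit of sampen on mean_spo2.

    ``group_mean`` (default) first averages per-subject points within each
    FiO2 level and fits the line through the level means, each level
    weighted equally — the graded-exposure design this reference emulates.
    ``per_subject`` fits through all individual points.
    """
    if len(points) < 2:
        raise DegenerateInputError("need at least 2 reference points")
    df = pd.DataFrame(
        {"fio2": [p.fio2 for p in points],
         "x": [p.mean_spo2 for p in points],
         "y": [p.sampen for p in points]}
    )
    if fit_mode == "group_mean":
        df = df.groupby("fio2", as_index=False)[["x", "y"]].mean()
        if len(df) < 2:
            raise DegenerateInputError("need at least 2 FiO2 levels in group_mean mode")
    elif fit_mode != "per_subject":
        raise ValueError(f"unknown fit_mode {fit_mode!r}")
    x, y = df["x"].to_numpy(), df["y"].to_numpy()
    if np.ptp(x) == 0:
        raise NonIdentifiableError("all mean_spo2 values identical; slope undefined")
    res = stats.linregress(x, y)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        r2 = 1.0  # all y identical and fit exact
    else:
        resid = y - (res.slope * x + res.intercept)
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return ReferenceLine(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        n_points=len(df),
        fit_mode=fit_mode,
    )


def parenclitic_delta(x: float, y: float, line: ReferenceLine) -> DeviationResult:
    """Signed perpendicular distance of (x, y) from the reference line.

    Positive below the line (y < y_hat), negative above; magnitude is the
    Euclidean point-to-line distance in the raw coordinate plane.
    """
    if not (math.isfinite(line.slope) and math.isfinite(line.intercept)):
        raise ValueError("reference line is not finite")
    if y is None or not math.isfinite(y):
        raise ValueError("y (SampEn) is undefined")
    delta = (line.slope * x - y + line.intercept) / math.sqrt(line.slope**2 + 1.0)
    return DeviationResult(delta=float(delta), x=float(x), y=float(y),
                           y_hat=float(line.predict(x)))


def batch_delta(
    table: pd.DataFrame,
    line: ReferenceLine,
    x_col: str = "mean_spo2",
    y_col: str = "sampen",
) -> pd.DataFrame:
    """Row-wise delta over a feature table.

    Rows with undefined y are flagged (``delta_defined = False``, delta NaN)
    and should be excluded from downstream statistics; the exclusion count
    is available from the flag column.
    """
    missing = {x_col, y_col} - set(table.columns)
    if missing:
        raise SchemaError(f"feature table missing columns: {sorted(missing)}")
    out = table.copy()
    y = pd.to_numeric(out[y_col], errors="coerce").to_numpy(dtype=float)
    x = pd.to_numeric(out[x_col], errors="coerce").to_numpy(dtype=float)
    defined = np.isfinite(x) & np.isfinite(y)
    delta = np.full(len(out), np.nan)
    denom = math.sqrt(line.slope**2 + 1.0)
    delta[defined] = (line.slope * x[defined] - y[defined] + line.intercept) / denom
    out["delta"] = delta
    out["delta_defined"] = defined
    return out
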