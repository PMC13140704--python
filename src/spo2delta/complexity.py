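"""Sample entropy and multiscale entropy of SpO2 segments.

Sample entropy (SampEn) quantifies the irregularity of a time series as the
negative natural logarithm of the conditional probability that two template
sequences that match for ``m`` consecutive points (within tolerance ``t``,
Chebyshev distance) still match at point ``m + 1``. Self-matches are
excluded and each unordered template pair is counted once, so SampEn is an
(almost) unbiased estimator of the underlying conditional probability and
carries no bias toward regularity from self-counting.

Conventions
-----------
* Templates of both lengths are drawn from the same index range
  ``i = 0 .. N - m - 1`` (the ``N - m`` templates that possess an
  ``(m+1)``-point extension), the convention of the original definition and
  of the PhysioNet reference implementation.
* Tolerance is inclusive (distance ``<= t`` counts as a match), so a
  constant series — whose sample standard deviation, and therefore
  tolerance, is zero — yields SampEn 0 rather than an error.
* Multiscale entropy (MSE) coarse-grains the series into non-overlapping
  windows of length ``tau`` (window means, remainder discarded) for
  ``tau = 1 .. max_scale`` and recomputes SampEn at each scale with ONE
  absolute tolerance fixed from the original scale-1 series, the standard
  multiscale convention; the per-scale values are averaged into an overall
  complexity index.

Zero-match degeneracies (no ``m``-matches, or no ``(m+1)``-matches) are
reported as undefined with a reason code rather than as ±inf; no plug-in
correction is applied and such segments are excluded downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError
from .signal_io import OximetrySegment

_BLOCK = 2048  # row-block size for the pairwise comparison loop


@dataclass(frozen=True)
class EntropyParams:
    """SampEn / MSE parameters.

    ``embed_dim`` is the template length m (default 2) and
    ``tolerance_factor`` is r (default 0.2). With
    ``tolerance_mode="relative_sd"`` the absolute tolerance is
    r x SD(scale-1 series) (sample SD, denominator N-1); with
    ``"absolute"``, r itself is the tolerance in percent-saturation units —
    a distinction that matters for integer-quantised SpO2 signals.
    ``max_scale`` is the number of coarse-graining scales (default 5).
    """

    embed_dim: int = 2
    tolerance_factor: float = 0.2
    tolerance_mode: Literal["relative_sd", "absolute"] = "relative_sd"
    max_scale: int = 5

    def __post_init__(self):
        if self.embed_dim < 1:
            raise ValueError("embed_dim must be >= 1")
        if not self.tolerance_factor > 0:
            raise ValueError("tolerance_factor must be > 0")
        if self.max_scale < 1:
            raise ValueError("max_scale must be >= 1")

    def absolute_tolerance(self, values: np.ndarray) -> float:
        if self.tolerance_mode == "absolute":
            return float(self.tolerance_factor)
        return float(self.tolerance_factor * np.std(values, ddof=1))


@dataclass(frozen=True)
class SampEnResult:
    """SampEn value with its template match counts.

    ``value`` is None when undefined; ``reason`` then carries one of
    ``"no_m_matches"`` / ``"no_m_plus_1_matches"``. ``b`` counts matching
    m-template pairs, ``a`` matching (m+1)-template pairs (i < j).
    """

    value: float | None
    a: int
    b: int
    tolerance_used: float
    reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.value is not None


@dataclass(frozen=True)
class ScaleEntropy:
    scale: int
    value: float | None
    n_points: int
    reason: str | None = None


@dataclass(frozen=True)
class EntropyProfile:
    """Scale-1 SampEn plus the per-scale MSE values for one segment."""

    sampen: float | None
    per_scale: tuple[ScaleEntropy, ...]
    mse_mean: float | None
    tolerance_used: float

    @property
    def defined_values(self) -> list[float]:
        return [s.value for s in self.per_scale if s.value is not None]


def coarse_grain(values: Sequence[float] | np.ndarray, scale: int) -> np.ndarray:
    """Non-overlapping window means at the given scale.

    Output length is floor(N / scale); trailing remainder samples are
    discarded. Scale 1 returns the series unchanged.
    """
    x = np.asarray(values, dtype=float)
    if scale < 1:
        raise ValueError("scale must be >= 1")
    n_windows = len(x) // scale
    if n_windows == 0:
        raise DegenerateInputError(
            f"series of length {len(x)} cannot be coarse-grained at scale {scale}"
        )
    return x[: n_windows * scale].reshape(n_windows, scale).mean(axis=1)


def _match_counts(x: np.ndarray, m: int, tol: float) -> tuple[int, int]:
    """Count template pairs (i < j) matching at lengths m and m+1.

    Chebyshev distance, inclusive tolerance. Both counts run over the
    N - m templates that have an (m+1)-point extension. Row-blocked so the
    boolean comparison matrices stay modest for long segments.
    """
    n = len(x) - m
    a = b = 0
    col = np.arange(n)
    for s in range(0, n, _BLOCK):
        e = min(s + _BLOCK, n)
        within = np.ones((e - s, n), dtype=bool)
        for k in range(m):
            within &= np.abs(x[s + k : e + k, None] - x[None, k : n + k]) <= tol
        upper = col[None, :] > np.arange(s, e)[:, None]  # j > i only
        within &= upper
        b += int(np.count_nonzero(within))
        within &= np.abs(x[s + m : e + m, None] - x[None, m : n + m]) <= tol
        a += int(np.count_nonzero(within))
    return a, b


def sample_entropy(
    values: Sequence[float] | np.ndarray,
    params: EntropyParams = EntropyParams(),
    tolerance: float | None = None,
) -> SampEnResult:
    """Sample entropy of a series.

    ``tolerance`` overrides the tolerance derived from ``params`` (used by
    :func:`multiscale_entropy` to hold the scale-1 tolerance fixed across
    scales). Returns an undefined result with a reason code when no template
    pair matches at length m (or none extends to m+1); raises
    :class:`DegenerateInputError` when the series is shorter than m + 2.
    """
    x = np.asarray(values, dtype=float)
    m = params.embed_dim
    if len(x) < m + 2:
        raise DegenerateInputError(
            f"series of length {len(x)} too short for SampEn with m={m}"
        )
    tol = params.absolute_tolerance(x) if tolerance is None else float(tolerance)
    a, b = _match_counts(x, m, tol)
    if b == 0:
        return SampEnResult(None, a, b, tol, reason="no_m_matches")
    if a == 0:
        return SampEnResult(None, a, b, tol, reason="no_m_plus_1_matches")
    return SampEnResult(float(np.log(b) - np.log(a)), a, b, tol)


def multiscale_entropy(
    values: Sequence[float] | np.ndarray,
    params: EntropyParams = EntropyParams(),
) -> EntropyProfile:
    """Multiscale entropy profile over scales 1 .. ``params.max_scale``.

    The absolute tolerance is fixed once from the original series and reused
    at every scale. Scale 1 must be computable (else the degenerate-input
    error propagates); higher scales that are too short or matchless appear
    as undefined entries, and ``mse_mean`` averages the defined values.
    """
    x = np.asarray(values, dtype=float)
    m = params.embed_dim
    if len(x) < (m + 2) * params.max_scale:
        raise DegenerateInputError(
            f"series of length {len(x)} too short for {params.max_scale}-scale "
            f"MSE with m={m}: need at least {(m + 2) * params.max_scale}"
        )
    tol = params.absolute_tolerance(x)
    per_scale: list[ScaleEntropy] = []
    for tau in range(1, params.max_scale + 1):
        cg = coarse_grain(x, tau)
        if len(cg) < m + 2:
            per_scale.append(ScaleEntropy(tau, None, len(cg), reason="too_short"))
            continue
        res = sample_entropy(cg, params, tolerance=tol)
        per_scale.append(ScaleEntropy(tau, res.value, len(cg), reason=res.reason))
    scale1 = per_scale[0].value
    if scale1 is None and per_scale[0].reason == "too_short":
        raise DegenerateInputError("scale-1 series too short for SampEn")
    defined = [s.value for s in per_scale if s.value is not None]
    return EntropyProfile(
        sampen=scale1,
        per_scale=tuple(per_scale),
        mse_mean=float(np.mean(defined)) if defined else None,
        tolerance_used=tol,
    )


def entropy_table(
    segments: Iterable[OximetrySegment],
    params: EntropyParams = EntropyParams(),
) -> pd.DataFrame:
    """Batch interface: one row per segment with mean SpO2, scale-1 SampEn,
    per-scale values and their average. CSV round-trippable."""
    rows = []
    for seg in segments:
        prof = multiscale_entropy(seg.values, params)
        row = {
            "subject_id": seg.subject_id,
            "group": seg.group_label,
            "mean_spo2": seg.mean_spo2,
            "sampen": prof.sampen,
            "mse_mean": prof.mse_mean,
            "tolerance_used": prof.tolerance_used,
        }
        for s in prof.per_scale:
            row[f"sampen_scale_{s.scale}"] = s.value
        rows.append(row)
    return pd.DataFrame(rows)
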