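"""Independent brute-force oracles used to cross-check the implementation.

Every function here deliberately takes a different computational path from
the package (explicit enumeration, closed-form normal equations, geometric
projection, grid search over an explicitly written partial likelihood) so
agreement is evidence of correctness rather than shared code.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial.distance import cdist


def sampen_bruteforce(x: np.ndarray, m: int, tol: float) -> tuple[float | None, int, int]:
    """SampEn by full pairwise Chebyshev distance matrices over all
    templates (O(N^2) memory and time)."""
    x = np.asarray(x, dtype=float)
    n = len(x) - m
    tm = np.stack([x[i : i + m] for i in range(n)])
    tm1 = np.stack([x[i : i + m + 1] for i in range(n)])
    dm = cdist(tm, tm, metric="chebyshev")
    dm1 = cdist(tm1, tm1, metric="chebyshev")
    iu = np.triu_indices(n, k=1)
    b = int(np.count_nonzero(dm[iu] <= tol))
    a = int(np.count_nonzero(dm1[iu] <= tol))
    if b == 0 or a == 0:
        return None, a, b
    return -math.log(a / b), a, b


def point_line_distance(x: float, y: float, slope: float, intercept: float) -> float:
    """Unsigned point-to-line distance via perpendicular projection: find
    the foot of the perpendicular and measure the Euclidean distance."""
    # line through (0, intercept) with direction (1, slope)
    dx, dy = 1.0, slope
    px, py = x - 0.0, y - intercept
    t = (px * dx + py * dy) / (dx * dx + dy * dy)
    fx, fy = t * dx, intercept + t * dy
    return math.hypot(x - fx, y - fy)


def ols_normal_equations(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Closed-form OLS slope/intercept from the normal equations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return float(slope), float(intercept)


def pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    """Hand-computed pooled-variance Student's t and df."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    return float(t), na + nb - 2


def cox_partial_loglik(beta: float, x: np.ndarray, time: np.ndarray,
                       event: np.ndarray) -> float:
    """Explicit Cox partial log-likelihood, single covariate, no ties
    (distinct event times)."""
    ll = 0.0
    for i in range(len(x)):
        if event[i]:
            risk = time >= time[i]
            ll += beta * x[i] - math.log(np.exp(beta * x[risk]).sum())
    return ll


def cox_grid_mle(x: np.ndarray, time: np.ndarray, event: np.ndarray,
                 lo: float = -6.0, hi: float = 6.0) -> float:
    """Grid-search maximiser of the explicit partial likelihood, refined to
    a resolution well below 1e-4."""
    grid = np.linspace(lo, hi, 4001)
    lls = np.array([cox_partial_loglik(b, x, time, event) for b in grid])
    best = grid[np.argmax(lls)]
    fine = np.linspace(best - 0.01, best + 0.01, 4001)  # 5e-6 spacing
    lls = np.array([cox_partial_loglik(b, x, time, event) for b in fine])
    return float(fine[np.argmax(lls)])


def auc_pairwise(scores: np.ndarray, outcome: np.ndarray) -> float:
    """Exhaustive pairwise AUC: concordant + 0.5 * tied over all
    positive-negative pairs."""
    s = np.asarray(scores, float)
    y = np.asarray(outcome, int)
    pos, neg = s[y == 1], s[y == 0]
    total = conc = ties = 0
    for p in pos:
        for q in neg:
            total += 1
            if p > q:
                conc += 1
            elif p == q:
                ties += 1
    return (conc + 0.5 * ties) / total
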