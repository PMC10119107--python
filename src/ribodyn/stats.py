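"""Statistical primitives: pooled t, BH step-up, Mann-Whitney U, Spearman.

Authored directly (scipy supplies only distribution CDFs) so that every
decision — tie handling, exact-vs-approximate switching, two-sided
conventions — is explicit and testable against brute-force oracles.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import norm, rankdata
from scipy.stats import t as t_dist


def pooled_t_test(x, y) -> tuple[float, int, float]:
    """Two-sided Student's t test with pooled variance.

    Returns (t, df, p). Degenerate cases: zero variance in both groups with
    equal means -> p = 1; zero variance with unequal means -> p = 0.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("each group needs at least two observations")
    df = nx + ny - 2
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / df
    diff = x.mean() - y.mean()
    if sp2 == 0:
        if diff == 0:
            return 0.0, df, 1.0
        return np.inf * np.sign(diff), df, 0.0
    t = diff / np.sqrt(sp2 * (1 / nx + 1 / ny))
    p = 2 * t_dist.sf(abs(t), df)
    return float(t), df, float(min(p, 1.0))


def benjamini_hochberg(p) -> np.ndarray:
    """BH step-up q-values: monotone in p-rank, clipped at 1."""
    p = np.asarray(p, float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return np.array([])
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _u_statistic(ranks_x: np.ndarray, nx: int) -> float:
    return ranks_x.sum() - nx * (nx + 1) / 2


def mann_whitney(x, y, exact_max: int = 12) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U test; returns (U of x, p).

    Exact p by enumeration of all rank assignments when nx + ny <=
    ``exact_max`` (ties handled via average ranks in the enumeration);
    otherwise the normal approximation with tie and continuity correction.
    Two-sided convention: 2 * min(P(U <= u), P(U >= u)), capped at 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u_x = _u_statistic(ranks[:nx], nx)
    n = nx + ny
    if n <= exact_max:
        us = np.array(
            [_u_statistic(ranks[list(idx)], nx) for idx in combinations(range(n), nx)]
        )
        p_le = np.mean(us <= u_x + 1e-12)
        p_ge = np.mean(us >= u_x - 1e-12)
        p = min(1.0, 2 * min(p_le, p_ge))
        return float(u_x), float(p)
    mu = nx * ny / 2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
    sigma2 = nx * ny / 12 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return float(u_x), 1.0
    z = (u_x - mu - 0.5 * np.sign(u_x - mu)) / np.sqrt(sigma2)
    return float(u_x), float(min(1.0, 2 * norm.sf(abs(z))))


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties.

    Two-sided p from the t approximation t = r sqrt((n-2)/(1-r^2)).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("samples must have equal length")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 pairs")
    rx = rankdata(x)
    ry = rankdata(y)
    sx = rx.std()
    sy = ry.std()
    if sx == 0 or sy == 0:
        return float("nan"), float("nan")
    r = float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return r, float(min(1.0, 2 * t_dist.sf(abs(t), n - 2)))


def mann_whitney_exact_null_size(nx: int, ny: int) -> int:
    """Number of arrangements the exact MWU enumeration averages over."""
    return comb(nx + ny, nx)
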