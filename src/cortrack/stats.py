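"""Shared statistical kernels.

Classical paired and pooled-variance independent t tests, Spearman rank
correlation with a t-approximation p value (exact permutation p for small
n behind a flag), min-max scaling, and Benjamini-Hochberg FDR control.
Implemented from the textbook formulas; the test suite cross-checks them
against scipy/statsmodels on random instances.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConstantVector, LengthMismatch, MissingColumn

__all__ = [
    "CorrelationResult",
    "paired_t",
    "independent_t",
    "minmax_scale",
    "spearman",
    "bh_fdr",
    "correlate_measures",
    "DEFAULT_CORRELATION_PAIRS",
]

DEFAULT_CORRELATION_PAIRS = [
    ("sentential_db", "listening_score"),
    ("sentential_db", "n400_500_700_uv"),
    ("sentential_db", "comprehension_rating"),
]


@dataclass
class CorrelationResult:
    x_label: str
    y_label: str
    rho: float
    n: int
    p_two_tailed: float


def _tail_p(t: float, df: int, alternative: str) -> float:
    if alternative == "two-sided":
        return float(2.0 * sps.t.sf(abs(t), df))
    if alternative == "greater":
        return float(sps.t.sf(t, df))
    if alternative == "less":
        return float(sps.t.cdf(t, df))
    raise ValueError(f"unknown alternative: {alternative}")


def paired_t(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> tuple[float, int, float]:
    """Classical paired t on x - y; returns (t, df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise LengthMismatch(f"{x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need n >= 2")
    d = x - y
    n = d.size
    df = n - 1
    sd = d.std(ddof=1)
    if sd == 0:
        m = d[0]
        if m == 0:
            t = 0.0
            p = {"two-sided": 1.0, "greater": 0.5, "less": 0.5}[alternative]
        else:
            t = np.inf if m > 0 else -np.inf
            if alternative == "two-sided":
                p = 0.0
            elif alternative == "greater":
                p = 0.0 if m > 0 else 1.0
            else:
                p = 0.0 if m < 0 else 1.0
        return float(t), df, float(p)
    t = d.mean() / (sd / np.sqrt(n))
    return float(t), df, _tail_p(t, df, alternative)


def independent_t(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> tuple[float, int, float]:
    """Pooled-variance Student t; df = n_x + n_y - 2, two-tailed by default."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("need n >= 2 per group")
    df = nx + ny - 2
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / df
    if sp2 == 0:
        diff = x.mean() - y.mean()
        if diff == 0:
            return 0.0, df, 1.0 if alternative == "two-sided" else 0.5
        t = np.inf if diff > 0 else -np.inf
        return float(t), df, 0.0 if alternative == "two-sided" else _tail_p(t, df, alternative)
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))
    return float(t), df, _tail_p(t, df, alternative)


def minmax_scale(x: Sequence[float]) -> np.ndarray:
    """Linear rescale to [0, 1]; raises on constant input."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need length >= 2")
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ConstantVector("max == min")
    return (x - lo) / (hi - lo)


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho: float) -> float:
    """Two-sided permutation p over all orderings (n <= 10)."""
    n = rx.size
    cx = rx - rx.mean()
    cy = ry - ry.mean()
    denom = np.sqrt((cx**2).sum() * (cy**2).sum())
    obs = abs(rho)
    count = total = 0
    for perm in permutations(range(n)):
        r = float(cx @ cy[list(perm)]) / denom
        total += 1
        if abs(r) >= obs - 1e-12:
            count += 1
    return count / total


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    labels: tuple[str, str] = ("x", "y"),
    method: str = "t-approx",
) -> CorrelationResult:
    """Spearman rank correlation (mean ranks for ties).

    p values use the t-approximation with df = n - 2; ``method='exact'``
    enumerates all permutations (only for n <= 10).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise LengthMismatch(f"{x.shape} vs {y.shape}")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ConstantVector("constant input to spearman")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if method == "exact":
        if n > 10:
            raise ValueError("exact permutation p only for n <= 10")
        p = _exact_spearman_p(rx, ry, rho)
    elif method == "t-approx":
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1 - rho**2))
            p = _tail_p(t, n - 2, "two-sided")
    else:
        raise ValueError(f"unknown method: {method}")
    return CorrelationResult(
        x_label=labels[0], y_label=labels[1], rho=rho, n=n, p_two_tailed=float(p)
    )


def bh_fdr(p_values: Sequence[float], q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance mask at level ``q``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    thresh = q * np.arange(1, m + 1) / m
    passing = np.nonzero(ranked <= thresh)[0]
    mask = np.zeros(m, dtype=bool)
    if passing.size:
        k = passing[-1]
        mask[order[: k + 1]] = True
    return mask


def correlate_measures(
    table: pd.DataFrame,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> list[CorrelationResult]:
    """Min-max scale each requested column, then Spearman per pair.

    The scaling is order-preserving and therefore leaves the rank
    correlation unchanged; it is kept so reported scaled tables and
    correlations come from the same numbers.
    """
    if pairs is None:
        pairs = DEFAULT_CORRELATION_PAIRS
    results = []
    for cx, cy in pairs:
        for c in (cx, cy):
            if c not in table.columns:
                raise MissingColumn(c)
        sub = table[[cx, cy]].dropna()
        if len(sub) < 3:
            raise ValueError(f"fewer than 3 complete cases for ({cx}, {cy})")
        x = minmax_scale(sub[cx].to_numpy())
        y = minmax_scale(sub[cy].to_numpy())
        results.append(spearman(x, y, labels=(cx, cy)))
    return results
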