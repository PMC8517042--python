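"""Shared statistical primitives with exact small-sample behavior."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

#: Product n_a * n_b below which the Mann-Whitney null is enumerated exactly
#: (tie-free data only); above it a tie- and continuity-corrected normal
#: approximation is used.
EXACT_MW_LIMIT = 400


@dataclass(frozen=True)
class TestResult:
    """Statistic, two-sided (or stated one-sided) p, and method metadata."""

    statistic: float
    p: float
    method: str
    exact: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p={self.p} outside [0, 1]")


def _has_ties(a: np.ndarray, b: np.ndarray) -> bool:
    pooled = np.concatenate([a, b])
    return len(np.unique(pooled)) < len(pooled)


def mann_whitney(a, b, mode: str = "auto") -> TestResult:
    """Two-sided Mann-Whitney U test; U is reported for the first sample.

    ``mode='exact'`` enumerates the null distribution (requires tie-free
    data), ``'normal-approx'`` uses the tie-corrected normal approximation
    with continuity correction, and ``'auto'`` picks exact when
    n_a*n_b <= 400 and the pooled data are tie-free.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    if mode not in ("exact", "normal-approx", "auto"):
        raise ValueError(f"unknown mode {mode!r}")
    ties = _has_ties(a, b)
    if mode == "auto":
        use_exact = (a.size * b.size <= EXACT_MW_LIMIT) and not ties
    elif mode == "exact":
        if ties:
            raise ValueError("exact Mann-Whitney requires tie-free data")
        use_exact = True
    else:
        use_exact = False
    method = "exact" if use_exact else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return TestResult(
        statistic=float(res.statistic),
        p=float(min(res.pvalue, 1.0)),
        method=f"mann-whitney-{method}",
        exact=use_exact,
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Sort ascending, q(i) = p(i) * m / i, enforce monotone non-increasing
    from the largest rank down, cap at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d vector of p-values")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adjusted
    return out


def binom_test_exact(k: int, n: int, p0: float, side: str = "two") -> TestResult:
    """Exact binomial test of k successes in n trials against p0.

    ``side='greater'`` sums the upper tail; ``side='two'`` uses the
    minimum-likelihood two-sided convention.
    """
    if not (0 <= k <= n):
        raise ValueError("require 0 <= k <= n")
    if not (0.0 < p0 < 1.0):
        raise ValueError("require 0 < p0 < 1")
    if side not in ("two", "greater"):
        raise ValueError(f"unknown side {side!r}")
    alternative = "two-sided" if side == "two" else "greater"
    res = stats.binomtest(k, n, p0, alternative=alternative)
    return TestResult(
        statistic=float(k),
        p=float(min(res.pvalue, 1.0)),
        method=f"binomial-exact-{side}",
        exact=True,
    )
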