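"""Statistical kernels shared by every caller in the package.

These are deliberately small, pure functions: the 2x2 Pearson chi-squared
test that drives the sliding-window DMR caller, the Benjamini-Hochberg
step-up used for every multiple-testing correction, the upper-tail
hypergeometric test used for cross-tissue set-overlap enrichment, and the
Pearson correlation reported for shared effect sizes.  Each has a clear
undefined-input regime that is signalled with a dedicated exception so
callers can skip (a window with an empty margin) or report a missing value
(a correlation over fewer than three points) instead of silently emitting 0.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import erfc, gammaln, logsumexp

__all__ = [
    "UndefinedTestError",
    "UndefinedCorrelationError",
    "chi2_2x2",
    "chi2_sf_df1",
    "bh_adjust",
    "hypergeom_tail",
    "pearson_r",
]


class UndefinedTestError(ValueError):
    """A contingency table has a zero marginal total: the test statistic is
    undefined and the unit (e.g. a genomic window) should be skipped."""


class UndefinedCorrelationError(ValueError):
    """Too few points or zero variance: correlation is undefined and must be
    reported as missing, never coerced to 0."""


def chi2_2x2(table) -> tuple[float, float]:
    """Pearson chi-squared test of a 2x2 table of read counts.

    Parameters
    ----------
    table
        ``[[a, b], [c, d]]`` of non-negative counts; by convention row 1 is
        the control group (methylated, unmethylated) and row 2 the exposed
        group.

    Returns
    -------
    (statistic, p)
        The uncorrected Pearson statistic ``n (ad - bc)^2 / (r1 r2 c1 c2)``
        and its upper-tail p-value on 1 degree of freedom.  No continuity
        correction is applied (see :mod:`crossomics.dmr` for the rationale
        and the config flag).

    Raises
    ------
    UndefinedTestError
        If any row or column total is zero.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise ValueError("table entries must be finite and non-negative")
    a, b = t[0]
    c, d = t[1]
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) <= 0:
        raise UndefinedTestError("zero marginal total: chi-squared undefined")
    n = r1 + r2
    stat = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return float(stat), chi2_sf_df1(stat)


def chi2_sf_df1(x) -> float:
    """Survival function of the chi-squared distribution with 1 df.

    Equals ``erfc(sqrt(x / 2))``; vectorised over array input.
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("chi-squared statistic must be non-negative")
    out = erfc(np.sqrt(arr / 2.0))
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def bh_adjust(pvalues):
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Accepts a sequence, ndarray, or keyed :class:`pandas.Series`; returns
    the same container type in the original order.  ``q_i = min_{j >= i}
    p_(j) * m / j`` (ranks over ascending p), capped at 1.

    Raises
    ------
    ValueError
        On an empty input, NaN, a duplicate key, or p outside [0, 1].
    """
    keys = None
    if isinstance(pvalues, pd.Series):
        if pvalues.index.has_duplicates:
            raise ValueError("duplicate feature keys in p-value vector")
        keys = pvalues.index
        p = pvalues.to_numpy(dtype=float)
    else:
        p = np.asarray(list(pvalues) if not isinstance(pvalues, np.ndarray) else pvalues,
                       dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    if keys is not None:
        return pd.Series(q, index=keys)
    return q


def hypergeom_tail(N: int, K: int, n: int, s: int) -> float:
    """Upper-tail hypergeometric probability ``P(X >= s)``.

    ``X`` counts successes in ``n`` draws without replacement from a
    universe of ``N`` objects of which ``K`` are successes.  The sum runs in
    log space (log-binomials via ``gammaln`` + ``logsumexp``) so that tiny
    tails at genome-scale universes do not underflow term by term.
    """
    for name, v in (("N", N), ("K", K), ("n", n), ("s", s)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    N, K, n, s = int(N), int(K), int(n), int(s)
    if K > N or n > N:
        raise ValueError(f"K={K} and n={n} must not exceed N={N}")
    if s > min(K, n):
        raise ValueError(f"s={s} exceeds min(K, n)={min(K, n)}")
    lo = max(s, n + K - N)  # smallest attainable count >= s
    hi = min(K, n)
    if lo <= max(0, n + K - N):
        return 1.0  # the whole support
    k = np.arange(lo, hi + 1)
    logpmf = (
        _logcomb(K, k)
        + _logcomb(N - K, n - k)
        - _logcomb(N, n)
    )
    return float(min(1.0, np.exp(logsumexp(logpmf))))


def _logcomb(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def pearson_r(x, y) -> float:
    """Sample Pearson correlation of two equal-length vectors.

    Raises
    ------
    UndefinedCorrelationError
        If fewer than 3 points or either vector has zero variance; callers
        report the value as missing rather than 0.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if xa.size < 3:
        raise UndefinedCorrelationError(f"need >= 3 points, got {xa.size}")
    xc = xa - xa.mean()
    yc = ya - ya.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        raise UndefinedCorrelationError("zero variance in one of the vectors")
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))
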