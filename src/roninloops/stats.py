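"""Shared statistical primitives: hypergeometric upper tail and BH correction.

The interaction caller and the gene-set enrichment both test "at least k
successes" under a hypergeometric model; they share the single log-space tail
routine below so the two modules can never disagree.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

__all__ = ["hypergeom_upper_tail", "bh_adjust"]

_EPS = 1e-17


def _log_pmf(x, N, nA, nB):
    """log P(X = x) for X ~ Hypergeometric(N, nA, nB), vectorized."""
    return (
        gammaln(nA + 1) - gammaln(x + 1) - gammaln(nA - x + 1)
        + gammaln(N - nA + 1) - gammaln(nB - x + 1) - gammaln(N - nA - nB + x + 1)
        - (gammaln(N + 1) - gammaln(nB + 1) - gammaln(N - nB + 1))
    )


def hypergeom_upper_tail(k, N, n_a, n_b):
    """Upper-tail probability P(X >= k), X ~ Hypergeometric(N, n_a, n_b).

    Population of ``N`` items of which ``n_a`` are marked; ``n_b`` are drawn
    without replacement; ``k`` is the observed number of marked draws.
    Symmetric in ``n_a``/``n_b``. Computed in log space with a term-ratio
    recursion so that both deep tails (tiny p) and near-1 values are stable.

    All arguments broadcast; returns a scalar for scalar input.

    Raises
    ------
    ValueError
        if counts are negative, ``n_a``/``n_b`` exceed ``N``, or
        ``k > min(n_a, n_b)``.
    """
    k, N, n_a, n_b = np.broadcast_arrays(
        np.asarray(k, dtype=np.int64),
        np.asarray(N, dtype=np.int64),
        np.asarray(n_a, dtype=np.int64),
        np.asarray(n_b, dtype=np.int64),
    )
    scalar = k.ndim == 0
    k = np.atleast_1d(k).astype(np.int64)
    N = np.atleast_1d(N).astype(np.int64)
    nA = np.atleast_1d(n_a).astype(np.int64)
    nB = np.atleast_1d(n_b).astype(np.int64)

    if np.any((k < 0) | (N < 0) | (nA < 0) | (nB < 0)):
        raise ValueError("hypergeometric counts must be nonnegative")
    if np.any((nA > N) | (nB > N)):
        raise ValueError("n_a and n_b must not exceed N")
    if np.any(k > np.minimum(nA, nB)):
        raise ValueError("k must not exceed min(n_a, n_b)")

    p = np.empty(k.shape, dtype=float)
    xmin = np.maximum(0, nA + nB - N)
    xmax = np.minimum(nA, nB)

    trivial = k <= xmin
    p[trivial] = 1.0

    todo = ~trivial
    if np.any(todo):
        mean = nA[todo] * nB[todo] / np.maximum(N[todo], 1)
        upper = k[todo].astype(float) > mean  # short decaying upper tail
        idx = np.flatnonzero(todo)
        up_idx = idx[upper]
        lo_idx = idx[~upper]
        if up_idx.size:
            p[up_idx] = np.exp(
                _tail_up(k[up_idx], N[up_idx], nA[up_idx], nB[up_idx], xmax[up_idx])
            )
        if lo_idx.size:
            # k at or below the mean: 1 - P(X <= k-1); the lower sum is
            # comfortably below 1 here so the subtraction is benign.
            lo = np.exp(
                _tail_down(k[lo_idx] - 1, N[lo_idx], nA[lo_idx], nB[lo_idx], xmin[lo_idx])
            )
            p[lo_idx] = np.clip(1.0 - lo, 0.0, 1.0)
    p = np.clip(p, 0.0, 1.0)
    return float(p[0]) if scalar else p


def _tail_up(k, N, nA, nB, xmax):
    """log sum_{x=k..xmax} pmf(x) via forward term ratios (terms decay)."""
    log_t0 = _log_pmf(k, N, nA, nB)
    s = np.ones_like(log_t0)          # accumulated sum / leading term
    term = np.ones_like(log_t0)
    x = k.astype(np.int64).copy()
    active = x < xmax
    while np.any(active):
        ratio = np.zeros_like(s)
        a = active
        ratio[a] = ((nA[a] - x[a]) * (nB[a] - x[a])).astype(float) / (
            (x[a] + 1) * (N[a] - nA[a] - nB[a] + x[a] + 1)
        )
        term = term * ratio
        s = s + term
        x = x + active
        active = (x < xmax) & (term > _EPS * s)
    return log_t0 + np.log(s)


def _tail_down(k, N, nA, nB, xmin):
    """log sum_{x=xmin..k} pmf(x) via backward term ratios (terms decay)."""
    log_t0 = _log_pmf(k, N, nA, nB)
    s = np.ones_like(log_t0)
    term = np.ones_like(log_t0)
    x = k.astype(np.int64).copy()
    active = x > xmin
    while np.any(active):
        ratio = np.zeros_like(s)
        a = active
        ratio[a] = (x[a] * (N[a] - nA[a] - nB[a] + x[a])).astype(float) / (
            (nA[a] - x[a] + 1) * (nB[a] - x[a] + 1)
        )
        term = term * ratio
        s = s + term
        x = x - active
        active = (x > xmin) & (term > _EPS * s)
    return log_t0 + np.log(s)


def bh_adjust(p_values):
    """Benjamini-Hochberg step-up q-values, input order preserved.

    q_(i) = min_{j >= i} m * p_(j) / j, clipped to 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return np.array([], dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q
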