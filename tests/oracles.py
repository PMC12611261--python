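"""Independent oracles used by the test suite.

Each function re-derives an expected result from first principles
(textbook formulas, exhaustive enumeration, direct Hermite evaluation) and
never calls the implementation it checks.
"""

import math

import numpy as np
from scipy import stats


def pooled_t_oracle(x, y):
    """Textbook equal-variance two-sample t-test (statistic and p)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / nx + 1 / ny))
    p = 2 * stats.t.sf(abs(t), nx + ny - 2)
    return t, p


def s0_t_oracle(x, y, s0):
    """Hand formula: mean difference over (sp * sqrt(1/nx + 1/ny) + s0)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    sp = math.sqrt(
        ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    )
    return (x.mean() - y.mean()) / (sp * math.sqrt(1 / nx + 1 / ny) + s0)


def hypergeom_upper_tail(k, N, K, n):
    """P(X >= k) for X ~ Hypergeom(N, K, n) by exhaustive summation."""
    total = math.comb(N, n)
    lo = max(0, n + K - N)
    hi = min(n, K)
    acc = 0
    for x in range(max(k, lo), hi + 1):
        acc += math.comb(K, x) * math.comb(N - K, n - x)
    return acc / total


def ease_oracle(k, n, K, N):
    """EASE score by enumeration on the overlap-decremented table."""
    if k <= 1:
        return 1.0
    return hypergeom_upper_tail(k - 1, N - 1, K - 1, n - 1)


def fisher_upper_tail(k, n, K, N):
    """Plain one-tailed Fisher (no decrement) by enumeration."""
    return hypergeom_upper_tail(k, N, K, n)


def bh_oracle(pvals):
    """Step-up BH by the p(i) * m / i + cumulative-minimum formula."""
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def pchip_oracle(x, y, xq):
    """Shape-preserving cubic Hermite interpolation from the published rules.

    Interior derivatives use the Fritsch-Butland weighted harmonic mean and
    are zero where secant slopes change sign; endpoint derivatives use the
    one-sided three-point formula with the standard monotonicity clamps.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    h = np.diff(x)
    delta = np.diff(y) / h
    n = len(x)
    d = np.zeros(n)
    for k in range(1, n - 1):
        if delta[k - 1] == 0 or delta[k] == 0 or np.sign(delta[k - 1]) != np.sign(delta[k]):
            d[k] = 0.0
        else:
            w1 = 2 * h[k] + h[k - 1]
            w2 = h[k] + 2 * h[k - 1]
            d[k] = (w1 + w2) / (w1 / delta[k - 1] + w2 / delta[k])

    def edge(h0, h1, d0, d1):
        val = ((2 * h0 + h1) * d0 - h0 * d1) / (h0 + h1)
        if np.sign(val) != np.sign(d0):
            return 0.0
        if np.sign(d0) != np.sign(d1) and abs(val) > 3 * abs(d0):
            return 3 * d0
        return val

    if n == 2:
        d[0] = d[1] = delta[0]
    else:
        d[0] = edge(h[0], h[1], delta[0], delta[1])
        d[-1] = edge(h[-1], h[-2], delta[-1], delta[-2])

    xq = np.asarray(xq, float)
    out = np.empty_like(xq)
    for i, xi in enumerate(xq):
        k = min(np.searchsorted(x, xi, side="right") - 1, n - 2)
        k = max(k, 0)
        t = (xi - x[k]) / h[k]
        h00 = 2 * t**3 - 3 * t**2 + 1
        h10 = t**3 - 2 * t**2 + t
        h01 = -2 * t**3 + 3 * t**2
        h11 = t**3 - t**2
        out[i] = (
            h00 * y[k] + h10 * h[k] * d[k] + h01 * y[k + 1] + h11 * h[k] * d[k + 1]
        )
    return out
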