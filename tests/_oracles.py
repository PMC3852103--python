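"""Independent naive scalar oracles for the test suite.

Pure-Python, loop-based reimplementations of every statistic and of the
consensus / enrichment primitives, written directly from their defining
formulas and kept deliberately separate from the vectorised package code.
"""

from __future__ import annotations

import math
from itertools import combinations

MADN = 1.4826


def median_naive(v):
    s = sorted(v)
    n = len(s)
    mid = n // 2
    return s[mid] if n % 2 else (s[mid - 1] + s[mid]) / 2.0


def quantile_naive(v, p):
    """Linear interpolation at 1-based position 1 + (n-1)p."""
    s = sorted(v)
    h = 1 + (len(s) - 1) * p
    lo = int(math.floor(h))
    hi = min(lo + 1, len(s))
    frac = h - lo
    return s[lo - 1] * (1 - frac) + s[hi - 1] * frac


def madn_naive(v, center=None):
    c = median_naive(v) if center is None else center
    scale = MADN * median_naive([abs(x - c) for x in v])
    if scale == 0.0:
        scale = MADN * sum(abs(x - c) for x in v) / len(v)
    return scale


def ttest_naive(x, y):
    n1, n2 = len(x), len(y)
    mx, my = sum(x) / n1, sum(y) / n2
    ss = sum((v - mx) ** 2 for v in x) + sum((v - my) ** 2 for v in y)
    sp2 = ss / (n1 + n2 - 2)
    if sp2 <= 0:
        return 0.0, True
    return (my - mx) / math.sqrt(sp2 * (1 / n1 + 1 / n2)), False


def copa_naive(x, y, r=90.0):
    allv = list(x) + list(y)
    med = median_naive(allv)
    scale = madn_naive(allv, med)
    if scale == 0.0:
        return 0.0, True
    return quantile_naive([(v - med) / scale for v in y], r / 100.0), False


def os_naive(x, y):
    allv = list(x) + list(y)
    med = median_naive(allv)
    scale = madn_naive(allv, med)
    if scale == 0.0:
        return 0.0, True
    z_all = [(v - med) / scale for v in allv]
    cutoff = quantile_naive(z_all, 0.75) + (
        quantile_naive(z_all, 0.75) - quantile_naive(z_all, 0.25)
    )
    zy = [(v - med) / scale for v in y]
    return sum(z for z in zy if z > cutoff), False


def _pooled_madn_naive(x, y):
    mx, my = median_naive(x), median_naive(y)
    dev = [abs(v - mx) for v in x] + [abs(v - my) for v in y]
    scale = MADN * median_naive(dev)
    if scale == 0.0:
        scale = MADN * sum(dev) / len(dev)
    return scale, mx


def ort_naive(x, y):
    scale, mx = _pooled_madn_naive(x, y)
    if scale == 0.0:
        return 0.0, True
    q75 = quantile_naive(x, 0.75)
    cutoff = q75 + (q75 - quantile_naive(x, 0.25))
    return sum((v - mx) / scale for v in y if v > cutoff), False


def most_naive(x, y, mu, sigma):
    """mu/sigma: per-k moments of top-k sums of len(y) standard normals."""
    scale, mx = _pooled_madn_naive(x, y)
    if scale == 0.0:
        return 0.0, True
    ys = sorted(y, reverse=True)
    best = -math.inf
    m = 0.0
    for k in range(1, len(ys) + 1):
        m += (ys[k - 1] - mx) / scale
        best = max(best, (m - mu[k - 1]) / sigma[k - 1])
    return best, False


def lsoss_naive(x, y):
    n1, n2 = len(x), len(y)
    ys = sorted(y, reverse=True)

    def ss(vals):
        mean = sum(vals) / len(vals)
        return sum((v - mean) ** 2 for v in vals)

    best_k, best_sse = None, math.inf
    for k in range(1, n2):
        sse = ss(ys[:k]) + ss(ys[k:])
        if sse < best_sse:  # strict: smallest k kept on ties
            best_k, best_sse = k, sse
    mx = sum(x) / n1
    s2 = (ss(x) + best_sse) / (n1 + n2 - 3)
    if s2 <= 0:
        return 0.0, True
    mean_top = sum(ys[:best_k]) / best_k
    return best_k * (mean_top - mx) / math.sqrt(s2), False


def putative_naive(selections, k_m):
    """selections: dict method -> set of feature IDs."""
    universe = set().union(*selections.values())
    putative = {
        f for f in universe if sum(f in s for s in selections.values()) >= k_m
    }
    accuracy = {
        m: 100.0 * len(s & putative) / len(s) for m, s in selections.items()
    }
    return putative, accuracy


def hypergeom_naive(N, K, n, k):
    """Upper tail by exhaustive summation of the hypergeometric pmf."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(K, n) + 1)
    ) / total


def bh_naive(pvals):
    """Benjamini-Hochberg step-up from the textbook definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, pvals[i] * m / rank)
        adj[i] = val
        prev = val
    return adj
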