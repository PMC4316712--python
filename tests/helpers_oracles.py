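"""Independent brute-force oracles used by the test suite.

Each oracle is a direct, unoptimized transcription of the defining formula
(double loops, exhaustive enumeration), kept free of any code path from the
package implementation it checks.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def exhaustive_max_t(values, min_width=3):
    """O(n^2) search over every admissible arc (i, j).

    Admissible: min_width <= j - i <= n - min_width and each of the left /
    right flanks is empty or >= min_width. Ties broken by smallest i then
    smallest j. Returns (T, i, j); constant input gives T = 0 at the
    leftmost admissible arc, short input the no-split signal (0, 0, n).
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2 * min_width:
        return 0.0, 0, n
    sigma = float(np.std(values, ddof=1))
    if sigma == 0.0 or np.all(values == values[0]):
        return 0.0, 0, min_width
    cs = np.concatenate(([0.0], np.cumsum(values)))
    tot = cs[-1]
    best = (-math.inf, 0, 0)
    for i in range(n):
        if 0 < i < min_width:
            continue
        for j in range(i + min_width, n + 1):
            k = j - i
            if k > n - min_width:
                continue
            right = n - j
            if 0 < right < min_width:
                continue
            raw = abs((cs[j] - cs[i]) - k * tot / n) / math.sqrt(k * (n - k) / n)
            if raw > best[0]:
                best = (raw, i, j)
    return best[0] / sigma, best[1], best[2]


def bh_stepup(p_values):
    """Textbook Benjamini-Hochberg step-up: q_(i) = min_{j>=i} p_(j) m / j."""
    p = list(p_values)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = math.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = min(running, 1.0)
    return q


def welch_t(x, y):
    """Scalar Welch t statistic, degrees of freedom and two-sided p."""
    from scipy import stats

    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


def sam_d(x, y, s0=0.0):
    """SAM d statistic from its defining pooled-standard-error formula."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    ss = ((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()
    s = math.sqrt((1 / nx + 1 / ny) * ss / (nx + ny - 2))
    return (x.mean() - y.mean()) / (s + s0), s


def quantile_norm_small(matrix):
    """Rank-mean quantile normalization by explicit sorting (no ties)."""
    m = np.asarray(matrix, float)
    ref = np.sort(m, axis=0).mean(axis=1)
    out = np.empty_like(m)
    for j in range(m.shape[1]):
        ranks = np.argsort(np.argsort(m[:, j]))
        out[:, j] = ref[ranks]
    return out


def hypergeom_upper_tail(M, K, N, k):
    """P(X >= k) by exact enumeration of the hypergeometric mass."""
    denom = math.comb(M, N)
    total = 0
    for x in range(k, min(K, N) + 1):
        total += math.comb(K, x) * math.comb(M - K, N - x)
    return total / denom


def hypergeom_tail_bruteforce(universe, members, query, k):
    """P(overlap >= k) by enumerating every N-subset of a tiny universe."""
    universe = sorted(universe)
    members = set(members)
    N = len(query)
    hits = tot = 0
    for draw in combinations(universe, N):
        tot += 1
        if len(members.intersection(draw)) >= k:
            hits += 1
    return hits / tot
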