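"""Independent brute-force oracles used to check the implementations.

These deliberately avoid the code paths (and, where feasible, the
libraries) used by the package itself: exact combinatorial tail sums for
the Fisher test, all-pairs loops for Cliff's delta, naive agglomeration
for complete linkage, and direct formulas for small cases.
"""

from fractions import Fraction
from math import comb

import numpy as np


def hypergeom_tail_p(a: int, b: int, c: int, d: int) -> float:
    """Exact one-sided (enrichment) Fisher p for table [[a, b], [c, d]].

    P(X >= a) for X hypergeometric with population a+b+c+d, successes
    a+c, draws a+b; computed with integer binomials (exact rationals).
    """
    N = a + b + c + d
    K = a + c  # total "up"
    n = a + b  # signature margin
    denom = comb(N, n)
    total = Fraction(0)
    for k in range(a, min(K, n) + 1):
        if n - k > N - K:
            continue
        total += Fraction(comb(K, k) * comb(N - K, n - k), denom)
    return float(total)


def hypergeom_two_sided_p(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p: sum of all table probabilities <= observed."""
    N = a + b + c + d
    K = a + c
    n = a + b
    denom = comb(N, n)
    probs = {}
    for k in range(max(0, n - (N - K)), min(K, n) + 1):
        probs[k] = Fraction(comb(K, k) * comb(N - K, n - k), denom)
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


def cliffs_delta_brute(x, y) -> float:
    gt = lt = 0
    for xi in x:
        for yj in y:
            if xi > yj:
                gt += 1
            elif xi < yj:
                lt += 1
    return (gt - lt) / (len(x) * len(y))


def complete_linkage_brute(X, metric="euclidean"):
    """Naive agglomeration; returns sorted merge heights."""
    X = np.asarray(X, dtype=float)

    def dist(u, v):
        if metric == "euclidean":
            return float(np.sqrt(((u - v) ** 2).sum()))
        return float(np.abs(u - v).sum())

    clusters = [[i] for i in range(len(X))]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = max(dist(X[a], X[b])
                        for a in clusters[i] for b in clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return sorted(heights)


def holm_brute(pvals):
    """Step-down Holm adjustment by direct definition."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def bh_brute(pvals):
    """Step-up Benjamini-Hochberg adjustment by direct definition."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        idx = order[rank]
        running = min(running, p[idx] * m / (rank + 1))
        adj[idx] = running
    return adj


def spearman_brute(x, y) -> float:
    """Spearman via the d^2 formula (valid without ties)."""
    rx = np.argsort(np.argsort(x)) + 1
    ry = np.argsort(np.argsort(y)) + 1
    n = len(x)
    d2 = ((rx - ry) ** 2).sum()
    return 1.0 - 6.0 * d2 / (n * (n**2 - 1))
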