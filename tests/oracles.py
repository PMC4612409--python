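"""Independent reference implementations used as test oracles.

Each function here is written directly from the textbook definition of the
quantity it computes, with no code shared with the package, so agreement is a
meaningful check rather than a tautology.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy.stats import t as t_dist


def brute_force_local_affine(
    read: str,
    ref: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -1.0,
) -> float:
    """Best local affine-gap alignment score by exhaustive enumeration.

    Enumerates every pair of equal-length increasing index subsequences of the
    two strings; the aligned columns score match/mismatch and every run of
    skipped positions between consecutive columns pays an affine gap cost
    open + (len − 1) · extend.  Only feasible for short strings (≤ ~8).
    """

    def gapcost(g: int) -> float:
        return 0.0 if g == 0 else gap_open + (g - 1) * gap_extend

    best = 0.0
    n, m = len(read), len(ref)
    for k in range(1, min(n, m) + 1):
        for ri in combinations(range(n), k):
            for tj in combinations(range(m), k):
                s = 0.0
                for a, b in zip(ri, tj):
                    s += match if read[a] == ref[b] else mismatch
                for t in range(k - 1):
                    s += gapcost(ri[t + 1] - ri[t] - 1)
                    s += gapcost(tj[t + 1] - tj[t] - 1)
                if s > best:
                    best = s
    return best


def kendall_tau_b_brute(x, y) -> float:
    """Tie-corrected Kendall tau by explicit pair counting.

    tau-b = (C − D) / sqrt((n0 − n1)(n0 − n2)) with n0 = n(n−1)/2 and n1, n2
    the tied-pair counts in x and y.
    """
    x = list(x)
    y = list(y)
    n = len(x)
    conc = disc = ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                ties_x += 1
                ties_y += 1
            elif dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) // 2
    denom = math.sqrt((n0 - ties_x) * (n0 - ties_y))
    return (conc - disc) / denom if denom > 0 else float("nan")


def bh_stepup(p) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values from the step-up definition:
    q(i) = min_{j ≥ i} (m · p(j) / j) on the ascending sort, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    out = np.empty(m)
    out[order] = q_sorted
    return out


def pooled_t_pvalue(a, b) -> float:
    """Two-sided pooled-variance Student t-test from the textbook formula:
    t = (m1 − m2) / (s_p · sqrt(1/n1 + 1/n2))."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    return 2 * t_dist.sf(abs(t), n1 + n2 - 2)
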