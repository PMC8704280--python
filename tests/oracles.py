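"""Independent brute-force oracles used to freeze and cross-check expected values.

Everything here is written as plain loops / exhaustive enumeration, on purpose
disjoint from the implementation paths it validates.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# weighted connectance: straight-from-formula evaluation
# ---------------------------------------------------------------------------

def connectance_formula(counts) -> float:
    a = [list(map(float, row)) for row in counts]
    P, Q = len(a), len(a[0])
    m = sum(sum(row) for row in a)

    def two_pow_H(vec):
        tot = sum(vec)
        h = 0.0
        for v in vec:
            if v > 0:
                p = v / tot
                h -= p * math.log2(p)
        return 2.0 ** h

    ld = 0.0
    for i in range(P):  # rows
        ld += (sum(a[i]) / m) * two_pow_H(a[i])
    for j in range(Q):  # columns
        col = [a[i][j] for i in range(P)]
        ld += (sum(col) / m) * two_pow_H(col)
    return 0.5 * ld / (P + Q)


# ---------------------------------------------------------------------------
# NODF: double-loop pairwise-overlap evaluation on the binary matrix
# ---------------------------------------------------------------------------

def nodf_bruteforce(binary) -> float:
    B = [[1 if v else 0 for v in row] for row in binary]
    P, Q = len(B), len(B[0])

    def pair_sum(rows):
        n = len(rows)
        total = 0.0
        for i in range(n):
            for k in range(n):
                fi, fk = sum(rows[i]), sum(rows[k])
                if fi > fk > 0:
                    shared = sum(1 for a, b in zip(rows[i], rows[k]) if a and b)
                    total += 100.0 * shared / fk
        return total  # each unordered pair counted once via the fi > fk guard

    cols = [[B[i][j] for i in range(P)] for j in range(Q)]
    denom = P * (P - 1) / 2 + Q * (Q - 1) / 2
    return (pair_sum(B) + pair_sum(cols)) / denom


# ---------------------------------------------------------------------------
# H2': exhaustive enumeration of integer matrices with fixed marginals
# ---------------------------------------------------------------------------

def _fills(row_totals, col_remaining):
    """Yield every non-negative integer matrix with the given marginals."""
    if not row_totals:
        if all(c == 0 for c in col_remaining):
            yield []
        return
    total = row_totals[0]
    Q = len(col_remaining)

    def rows(j, left, prefix):
        if j == Q - 1:
            if left <= col_remaining[j]:
                yield prefix + [left]
            return
        for v in range(min(left, col_remaining[j]) + 1):
            yield from rows(j + 1, left - v, prefix + [v])

    for row in rows(0, total, []):
        reduced = [c - v for c, v in zip(col_remaining, row)]
        for rest in _fills(row_totals[1:], reduced):
            yield [row] + rest


def entropy_of(matrix) -> float:
    m = sum(sum(r) for r in matrix)
    h = 0.0
    for row in matrix:
        for v in row:
            if v > 0:
                h -= (v / m) * math.log(v / m)
    return h


def h2min_enumerate(row_totals, col_totals) -> float:
    """True minimum entropy over every integer matrix with those marginals."""
    return min(entropy_of(M) for M in _fills(list(row_totals), list(col_totals)))


def h2prime_enumerate(counts) -> float:
    counts = [list(map(int, r)) for r in counts]
    m = sum(sum(r) for r in counts)
    h2 = entropy_of(counts)
    row_t = [sum(r) for r in counts]
    col_t = [sum(counts[i][j] for i in range(len(counts))) for j in range(len(counts[0]))]
    h2max = 0.0
    for rt in row_t:
        for ct in col_t:
            p = (rt / m) * (ct / m)
            if p > 0:
                h2max -= p * math.log(p)
    h2min = h2min_enumerate(row_t, col_t)
    val = (h2max - h2) / (h2max - h2min)
    return min(1.0, max(0.0, val))


# ---------------------------------------------------------------------------
# bipartite modularity: exhaustive search over all set partitions of the nodes
# ---------------------------------------------------------------------------

def _set_partitions(n):
    """Restricted-growth-string enumeration of all set partitions of range(n)."""
    labels = [0] * n

    def rec(i, maxlab):
        if i == n:
            yield tuple(labels)
            return
        for lab in range(maxlab + 2):
            labels[i] = lab
            yield from rec(i + 1, max(maxlab, lab))

    yield from rec(1, 0)  # element 0 fixed to label 0


def modularity_exhaustive(counts):
    """(best Q, row labels, col labels) by checking every partition of all nodes."""
    a = [list(map(float, r)) for r in counts]
    P, Q = len(a), len(a[0])
    m = sum(sum(r) for r in a)
    row_t = [sum(r) for r in a]
    col_t = [sum(a[i][j] for i in range(P)) for j in range(Q)]
    B = [[(a[i][j] - row_t[i] * col_t[j] / m) / m for j in range(Q)] for i in range(P)]
    best = (-math.inf, None)
    for part in _set_partitions(P + Q):
        q = 0.0
        for i in range(P):
            bi = B[i]
            gi = part[i]
            for j in range(Q):
                if gi == part[P + j]:
                    q += bi[j]
        if q > best[0]:
            best = (q, part)
    q, part = best
    return q, part[:P], part[P:]


# ---------------------------------------------------------------------------
# robustness: exact mean over every plant removal order
# ---------------------------------------------------------------------------

def robustness_exhaustive(binary) -> float:
    B = [[1 if v else 0 for v in row] for row in binary]
    P, Q = len(B), len(B[0])
    areas = []
    for order in itertools.permutations(range(P)):
        alive_plants = set(range(P))
        ys = [1.0]
        for p in order:
            alive_plants.discard(p)
            surv = sum(
                1 for j in range(Q) if any(B[i][j] for i in alive_plants)
            )
            ys.append(surv / Q)
        area = sum((ys[t] + ys[t + 1]) / 2.0 for t in range(P)) / P
        areas.append(area)
    return sum(areas) / len(areas)


# ---------------------------------------------------------------------------
# one-way ANOVA F from the textbook sums of squares
# ---------------------------------------------------------------------------

def anova_f(groups) -> float:
    all_vals = [v for g in groups for v in g]
    n = len(all_vals)
    k = len(groups)
    grand = sum(all_vals) / n
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    sse = sum((v - sum(g) / len(g)) ** 2 for g in groups for v in g)
    return (ssb / (k - 1)) / (sse / (n - k))
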