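"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately naive -- plain loops, exhaustive
enumeration -- and shares no code path with the package implementation.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np


def compositions(total: int, parts: int):
    """All tuples of ``parts`` non-negative integers summing to ``total``."""
    if parts == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in compositions(total - first, parts - 1):
            yield (first,) + rest


def bounded_compositions(total: int, bounds):
    """Compositions of ``total`` with per-part upper bounds."""
    if len(bounds) == 1:
        if total <= bounds[0]:
            yield (total,)
        return
    for first in range(min(total, bounds[0]) + 1):
        for rest in bounded_compositions(total - first, bounds[1:]):
            yield (first,) + rest


def tables_with_margins(row_totals, col_totals):
    """All non-negative integer tables with the given marginals."""
    row_totals = list(row_totals)
    col_totals = list(col_totals)

    def rec(rows_left, cols_remaining):
        if not rows_left:
            if all(c == 0 for c in cols_remaining):
                yield ()
            return
        r = rows_left[0]
        for row in bounded_compositions(r, tuple(cols_remaining)):
            new_cols = [c - x for c, x in zip(cols_remaining, row)]
            for rest in rec(rows_left[1:], new_cols):
                yield (row,) + rest

    for tab in rec(row_totals, col_totals):
        yield np.array(tab, dtype=np.int64)


def naive_wnodf(w) -> float:
    """Weighted NODF by direct loops over the definition."""
    w = np.asarray(w)
    scores = []
    for mat in (w, w.T):
        totals = [sum(row) for row in mat]
        order = sorted(range(len(totals)), key=lambda i: (-totals[i], i))
        for a in range(len(order)):
            for b in range(a + 1, len(order)):
                u, v = order[a], order[b]
                if totals[u] <= totals[v]:
                    scores.append(0.0)
                    continue
                num = 0
                den = 0
                for j in range(mat.shape[1]):
                    if mat[v, j] > 0:
                        den += 1
                        if mat[v, j] < mat[u, j]:
                            num += 1
                scores.append(100.0 * num / den)
    return sum(scores) / len(scores)


def naive_barber_q(w, row_labels, col_labels) -> float:
    """Barber modularity by explicit double loop."""
    w = np.asarray(w, dtype=float)
    m = w.sum()
    rt = w.sum(axis=1)
    ct = w.sum(axis=0)
    q = 0.0
    for i in range(w.shape[0]):
        for j in range(w.shape[1]):
            if row_labels[i] == col_labels[j]:
                q += w[i, j] - rt[i] * ct[j] / m
    return q / m


def set_partitions(n: int):
    """All set partitions of range(n) as label arrays (restricted growth)."""
    labels = [0] * n

    def rec(i: int, max_label: int):
        if i == n:
            yield tuple(labels)
            return
        for lab in range(max_label + 2):
            labels[i] = lab
            yield from rec(i + 1, max(max_label, lab))

    yield from rec(1, 0) if n > 1 else iter([(0,) * n] if n else [()])


def exhaustive_max_modularity(w) -> float:
    """Maximum Barber Q over every partition of the species set."""
    w = np.asarray(w, dtype=float)
    r, c = w.shape
    best = -np.inf
    for part in set_partitions(r + c):
        q = naive_barber_q(w, part[:r], part[r:])
        if q > best:
            best = q
    return best


def entropy_nats(values) -> float:
    total = float(sum(values))
    h = 0.0
    for v in values:
        if v > 0:
            p = v / total
            h -= p * math.log(p)
    return h


def brute_h2_extremes(row_totals, col_totals) -> tuple[float, float]:
    """(min, max) cell entropy over all integer tables with these margins."""
    lo, hi = np.inf, -np.inf
    for tab in tables_with_margins(row_totals, col_totals):
        h = entropy_nats(tab.ravel())
        lo = min(lo, h)
        hi = max(hi, h)
    return lo, hi


def brute_d_extrema(total: int, q) -> tuple[float, float]:
    """(min, max) KL deviation over integer allocations of ``total``."""
    q = np.asarray(q, dtype=float)
    lo, hi = np.inf, -np.inf
    for alloc in compositions(total, len(q)):
        d = 0.0
        for v, qj in zip(alloc, q):
            if v > 0:
                p = v / total
                d += p * math.log(p / qj)
        lo = min(lo, d)
        hi = max(hi, d)
    return lo, hi


def kl_deviation(alloc, q) -> float:
    total = float(sum(alloc))
    d = 0.0
    for v, qj in zip(alloc, q):
        if v > 0:
            p = v / total
            d += p * math.log(p / qj)
    return d


def brute_wilcoxon_p(diffs, direction: str) -> float:
    """Exact one-tailed signed-rank p by enumerating all sign patterns."""
    diffs = [d for d in diffs if d != 0]
    n = len(diffs)
    absd = [abs(d) for d in diffs]
    # midranks
    order = sorted(range(n), key=lambda i: absd[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j < n and absd[order[j]] == absd[order[i]]:
            j += 1
        mid = (i + 1 + j) / 2.0
        for k in range(i, j):
            ranks[order[k]] = mid
        i = j
    w_obs = sum(r for r, d in zip(ranks, diffs) if d > 0)
    count = 0
    for signs in product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if direction == "decrease":
            count += w <= w_obs + 1e-9
        else:
            count += w >= w_obs - 1e-9
    return count / 2**n


def enumerate_matrices(max_dim: int = 3, max_total: int = 8):
    """All integer matrices up to max_dim x max_dim with 1 <= total <= max_total
    and no all-zero row or column (zero lines carry no weight and reduce to a
    smaller shape, which is enumerated separately)."""
    for r in range(1, max_dim + 1):
        for c in range(1, max_dim + 1):
            n = r * c
            for total in range(1, max_total + 1):
                for flat in compositions(total, n):
                    w = np.array(flat, dtype=np.int64).reshape(r, c)
                    if (w.sum(axis=1) > 0).all() and (w.sum(axis=0) > 0).all():
                        yield w
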