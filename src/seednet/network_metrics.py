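"""Network-level structure metrics for quantitative bipartite networks.

All metrics operate on the visit-count matrix (plants x birds) and accept
either a :class:`~seednet.network.LabeledNetwork` or a plain 2-D integer
array.  Species with zero marginal totals (e.g. species that lost every
link to pruning) are excluded from every metric except the size
bookkeeping done by callers.

Implemented metrics
-------------------
network_size
    Number of species with at least one link.
weighted_connectance
    Quantitative linkage density divided by network size, where linkage
    density weights each species' effective number of partners (the
    exponential of the Shannon entropy of its interaction vector) by its
    marginal total.
weighted_nodf
    Weighted NODF nestedness in [0, 100], based on paired overlap with
    decreasing fill.
h2_prime
    Network-level interaction specialization in [0, 1], the two-dimensional
    Shannon entropy of the interaction matrix standardized between its
    marginal-constrained extremes.
barber_q / lpawb_plus
    Weighted bipartite (Barber) modularity and its maximization by label
    propagation plus module agglomeration.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .exceptions import UndefinedMetricError
from .network import LabeledNetwork


def as_matrix(net) -> np.ndarray:
    """Coerce a LabeledNetwork or array-like to a 2-D integer array."""
    if isinstance(net, LabeledNetwork):
        return net.weights
    w = np.asarray(net)
    if w.ndim != 2:
        raise ValueError("expected a 2-D interaction matrix")
    return w


def _active(w: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Drop zero-total rows and columns; return (trimmed, row_mask, col_mask)."""
    rows = w.sum(axis=1) > 0
    cols = w.sum(axis=0) > 0
    return w[np.ix_(rows, cols)], rows, cols


def _entropy(x: np.ndarray) -> float:
    """Shannon entropy (natural log) of a non-negative vector, normalized."""
    s = x.sum()
    if s <= 0:
        return 0.0
    p = x[x > 0] / s
    return float(-(p * np.log(p)).sum())


def network_size(net) -> int:
    """Total number of species (plants + birds) with at least one link."""
    w = as_matrix(net)
    return int((w.sum(axis=1) > 0).sum() + (w.sum(axis=0) > 0).sum())


def weighted_connectance(net) -> float:
    """Quantitative linkage density divided by network size.

    Linkage density is ``LD = (1/2m) * [sum_j A_j n_j + sum_i A_i n_i]``
    where ``n_k = exp(H_k)`` is species ``k``'s effective partner number
    (Shannon entropy of its interaction vector, natural log).  A uniform
    complete matrix attains the maximum of 0.5 regardless of shape.
    """
    w, _, _ = _active(as_matrix(net))
    m = w.sum()
    if m <= 0:
        raise UndefinedMetricError("weighted connectance undefined for an empty matrix")
    row_tot = w.sum(axis=1)
    col_tot = w.sum(axis=0)
    n_row = np.array([np.exp(_entropy(r)) for r in w])
    n_col = np.array([np.exp(_entropy(c)) for c in w.T])
    ld = ((col_tot * n_col).sum() + (row_tot * n_row).sum()) / (2.0 * m)
    size = w.shape[0] + w.shape[1]
    return float(ld / size)


def weighted_nodf(net) -> float:
    """Weighted NODF nestedness in [0, 100].

    Rows and columns are ordered by decreasing marginal totals.  For an
    ordered pair (richer u, strictly poorer v), the paired score is
    ``100 * #{cells with 0 < w_v < w_u} / #{cells with w_v > 0}``; pairs
    with equal marginal totals score 0 (decreasing-fill convention).  The
    result is the mean over all row pairs and column pairs.
    """
    w, _, _ = _active(as_matrix(net))
    r, c = w.shape
    if r < 2 or c < 2:
        raise UndefinedMetricError("weighted NODF needs >= 2 active rows and columns")

    def axis_scores(mat: np.ndarray) -> list[float]:
        totals = mat.sum(axis=1)
        order = np.argsort(-totals, kind="stable")
        mat = mat[order]
        totals = totals[order]
        scores = []
        n = mat.shape[0]
        for u in range(n):
            for v in range(u + 1, n):
                if totals[u] <= totals[v]:
                    scores.append(0.0)
                    continue
                wv, wu = mat[v], mat[u]
                filled = wv > 0
                overlap = np.count_nonzero(filled & (wv < wu))
                scores.append(100.0 * overlap / np.count_nonzero(filled))
        return scores

    scores = axis_scores(w) + axis_scores(w.T)
    return float(np.mean(scores))


# -- H2' -------------------------------------------------------------------

def _pack_min_entropy(row_tot: np.ndarray, col_tot: np.ndarray,
                      prefer_exact: bool = False) -> np.ndarray:
    """Greedy integer table concentrating mass as much as marginals allow.

    Repeatedly pairs the largest remaining row total with the largest
    remaining column total; with ``prefer_exact``, a row/column pair with
    exactly equal remaining totals (the largest such) is consumed first,
    which often closes a cell completely and lowers the entropy further.
    The result is a vertex of the transportation polytope (at most
    r + c - 1 nonzero cells).
    """
    rr = row_tot.astype(np.int64).copy()
    cc = col_tot.astype(np.int64).copy()
    out = np.zeros((len(rr), len(cc)), dtype=np.int64)
    while True:
        i = j = -1
        if prefer_exact:
            pos_r = {int(v): k for k, v in enumerate(rr) if v > 0}
            matches = [int(v) for v in cc if v > 0 and int(v) in pos_r]
            if matches:
                best = max(matches)
                i = pos_r[best]
                j = int(np.nonzero(cc == best)[0][0])
        if i < 0:
            i = int(np.argmax(rr))
            j = int(np.argmax(cc))
        x = min(rr[i], cc[j])
        if x <= 0:
            break
        out[i, j] += x
        rr[i] -= x
        cc[j] -= x
    return out


def _vertex_descent_entropy(tab: np.ndarray) -> np.ndarray:
    """Reduce table entropy by full-depth 2x2 moves that preserve marginals.

    Entropy is concave, so its minimum over tables with fixed marginals is
    attained at a vertex; moving the full feasible amount around a 2x2
    cycle walks between (near-)vertices.  Iterates to a local optimum.
    """
    tab = tab.copy()
    r, c = tab.shape
    if r < 2 or c < 2:
        return tab
    m = tab.sum()

    def ent(t):
        p = t[t > 0] / m
        return float(-(p * np.log(p)).sum())

    best = ent(tab)
    improved = True
    while improved:
        improved = False
        for i1 in range(r):
            for i2 in range(r):
                if i1 == i2:
                    continue
                for j1 in range(c):
                    for j2 in range(j1 + 1, c):
                        # move t from (i1,j2),(i2,j1) onto (i1,j1),(i2,j2)
                        t = min(tab[i1, j2], tab[i2, j1])
                        if t <= 0:
                            continue
                        cand = tab.copy()
                        cand[i1, j1] += t
                        cand[i2, j2] += t
                        cand[i1, j2] -= t
                        cand[i2, j1] -= t
                        e = ent(cand)
                        if e < best - 1e-12:
                            tab, best = cand, e
                            improved = True
    return tab


def h2_prime(net) -> float:
    """Standardized two-dimensional interaction entropy in [0, 1].

    ``H2`` is the Shannon entropy of the cell probabilities
    ``p_ij = a_ij / m``.  The maximum is the entropy of the continuous
    marginal product distribution (``H2max = H_rows + H_cols``); the
    minimum comes from a greedy integer packing refined by 2x2 descent.
    0 means no specialization beyond what marginals impose, 1 complete
    specialization; the ratio is clamped to [0, 1].
    """
    w, _, _ = _active(as_matrix(net))
    m = w.sum()
    if m <= 0:
        raise UndefinedMetricError("H2' undefined for an empty matrix")
    h2 = _entropy(w.ravel())
    row_tot = w.sum(axis=1)
    col_tot = w.sum(axis=0)
    h2max = _entropy(row_tot) + _entropy(col_tot)
    h2min = min(
        _entropy(_vertex_descent_entropy(
            _pack_min_entropy(row_tot, col_tot, prefer_exact=pe)).ravel())
        for pe in (False, True)
    )
    denom = h2max - h2min
    if denom <= 1e-12:
        # marginals admit a single table: no room for specialization
        return 0.0
    return float(min(1.0, max(0.0, (h2max - h2) / denom)))


# -- Barber modularity and LPAwb+ -----------------------------------------

def _barber_matrix(w: np.ndarray) -> np.ndarray:
    m = w.sum()
    rt = w.sum(axis=1)
    ct = w.sum(axis=0)
    return w - np.outer(rt, ct) / m


def _q_from_labels(w: np.ndarray, row_labels: np.ndarray, col_labels: np.ndarray) -> float:
    B = _barber_matrix(w)
    same = row_labels[:, None] == col_labels[None, :]
    return float((B * same).sum() / w.sum())


def barber_q(net, partition) -> float:
    """Weighted Barber bipartite modularity of a given module partition.

    ``Q = (1/m) * sum_ij [a_ij - A_i A_j / m] * 1{module(i) == module(j)}``.

    ``partition`` is a mapping from species id to module label when ``net``
    is a :class:`LabeledNetwork` (it must cover every species with at least
    one link), or a ``(row_labels, col_labels)`` pair for a raw matrix.
    """
    w = as_matrix(net)
    if isinstance(net, LabeledNetwork) and isinstance(partition, Mapping):
        labels = sorted({v for v in partition.values()})
        code = {lab: k for k, lab in enumerate(labels)}
        row_labels = np.full(len(net.plants), -1)
        col_labels = np.full(len(net.birds), -2)
        for i, p in enumerate(net.plants):
            if net.plant_totals[i] > 0:
                if p not in partition:
                    raise ValueError(f"partition does not cover plant {p!r}")
                row_labels[i] = code[partition[p]]
        for j, b in enumerate(net.birds):
            if net.bird_totals[j] > 0:
                if b not in partition:
                    raise ValueError(f"partition does not cover bird {b!r}")
                col_labels[j] = code[partition[b]]
        # unlinked species get distinct negative labels; they carry no weight
        return _q_from_labels(w, row_labels, col_labels)
    row_labels, col_labels = partition
    return _q_from_labels(w, np.asarray(row_labels), np.asarray(col_labels))


def _propagate(B: np.ndarray, m: float, row_labels: np.ndarray, col_labels: np.ndarray,
               rng: np.random.Generator, max_sweeps: int) -> None:
    """Label propagation: move each species to the adjacent label with the
    largest modularity contribution until no species moves."""
    r, c = B.shape
    nodes = np.arange(r + c)
    for _ in range(max_sweeps):
        changed = False
        rng.shuffle(nodes)
        for node in nodes:
            if node < r:
                i = node
                labs, inv = np.unique(col_labels, return_inverse=True)
                scores = np.zeros(len(labs))
                np.add.at(scores, inv, B[i, :])
                k = int(np.argmax(scores))
                best, best_score = labs[k], scores[k]
                cur = row_labels[i]
                cur_score = scores[labs == cur][0] if cur in labs else 0.0
                if best_score > cur_score + 1e-12 and best != cur:
                    row_labels[i] = best
                    changed = True
            else:
                j = node - r
                labs, inv = np.unique(row_labels, return_inverse=True)
                scores = np.zeros(len(labs))
                np.add.at(scores, inv, B[:, j])
                k = int(np.argmax(scores))
                best, best_score = labs[k], scores[k]
                cur = col_labels[j]
                cur_score = scores[labs == cur][0] if cur in labs else 0.0
                if best_score > cur_score + 1e-12 and best != cur:
                    col_labels[j] = best
                    changed = True
        if not changed:
            break


def _lpawb_once(w: np.ndarray, rng: np.random.Generator,
                tol: float, max_sweeps: int,
                randomize_init: bool = False) -> tuple[np.ndarray, np.ndarray, float]:
    r, c = w.shape
    m = float(w.sum())
    B = _barber_matrix(w)
    row_labels = np.arange(r)
    if randomize_init:
        # diversify restarts: each column joins a random interacting row
        col_labels = np.array(
            [int(rng.choice(np.nonzero(w[:, j])[0])) for j in range(c)]
        )
    else:
        col_labels = np.array([int(np.argmax(B[:, j])) for j in range(c)])
    _propagate(B, m, row_labels, col_labels, rng, max_sweeps)
    q = (B * (row_labels[:, None] == col_labels[None, :])).sum() / m
    # agglomeration: try every pairwise module merge, each followed by
    # re-propagation, and keep the best strictly improving candidate
    while True:
        labs = np.unique(np.concatenate([row_labels, col_labels]))
        if len(labs) < 2:
            break
        best = None
        for a in range(len(labs)):
            for b in range(a + 1, len(labs)):
                rl = row_labels.copy()
                cl = col_labels.copy()
                rl[rl == labs[b]] = labs[a]
                cl[cl == labs[b]] = labs[a]
                _propagate(B, m, rl, cl, rng, max_sweeps)
                q_trial = (B * (rl[:, None] == cl[None, :])).sum() / m
                if q_trial > q + tol and (best is None or q_trial > best[2]):
                    best = (rl, cl, q_trial)
        if best is None:
            break
        row_labels, col_labels, q = best
    return row_labels, col_labels, float(q)


def lpawb_plus(net, seed=None, repeats: int = 1, tol: float = 1e-10,
               max_sweeps: int = 10_000):
    """Maximize weighted Barber modularity by label propagation + merging.

    Runs the two-phase search ``repeats`` times with independent
    deterministic sub-seeds and keeps the best modularity.  Returns
    ``(partition, Q)`` where the partition maps species ids to module
    labels for a :class:`LabeledNetwork`, or is a ``(row_labels,
    col_labels)`` pair for a raw matrix (labels refer to the active
    submatrix with zero-total species removed).
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    w_full = as_matrix(net)
    w, row_mask, col_mask = _active(w_full)
    if w.sum() <= 0:
        raise UndefinedMetricError("modularity undefined for an empty matrix")
    children = np.random.SeedSequence(seed).spawn(repeats)
    best = None
    for k, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        rl, cl, q = _lpawb_once(w, rng, tol, max_sweeps, randomize_init=k > 0)
        if best is None or q > best[2] + 1e-15:
            best = (rl, cl, q)
    rl, cl, q = best
    # canonical relabeling 0..K-1 in order of first appearance
    order: dict[int, int] = {}
    for lab in list(rl) + list(cl):
        if lab not in order:
            order[lab] = len(order)
    rl = np.array([order[lab] for lab in rl])
    cl = np.array([order[lab] for lab in cl])
    if isinstance(net, LabeledNetwork):
        partition: dict[str, int] = {}
        ai = 0
        for i, p in enumerate(net.plants):
            if row_mask[i]:
                partition[p] = int(rl[ai])
                ai += 1
        aj = 0
        for j, b in enumerate(net.birds):
            if col_mask[j]:
                partition[b] = int(cl[aj])
                aj += 1
        return partition, float(q)
    return (rl, cl), float(q)
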