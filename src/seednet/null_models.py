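"""Quantitative null models and the delta-transformation of metrics.

Two null models are provided, both producing integer matrices:

``patefield``
    Uniform random tables conditional on both marginal totals (the
    classical r x c contingency-table shuffle).  Implemented by pairing
    the m row-labeled interaction tokens with a random permutation of the
    m column-labeled tokens.

``quasiswap_count``
    Preserves marginal totals *and* the number of nonzero cells (fill).
    Starts from a Patefield draw and applies 2x2 submatrix updates that
    keep marginals fixed while moving the fill toward the observed value;
    once matched, fill-preserving unit swaps are applied for mixing.

The delta-transformation reports ``observed - mean(null)`` for a metric,
removing the component of the raw value that is expected from network
size and marginal structure alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .exceptions import UndefinedMetricError
from .network_metrics import as_matrix


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def patefield_sample(row_totals, col_totals, seed=None) -> np.ndarray:
    """Draw one integer table with the given marginals, uniformly over the
    token-pairing (multivariate hypergeometric) distribution."""
    rt = np.asarray(row_totals, dtype=np.int64)
    ct = np.asarray(col_totals, dtype=np.int64)
    if np.any(rt < 0) or np.any(ct < 0):
        raise ValueError("marginal totals must be non-negative")
    if rt.sum() != ct.sum() or rt.sum() <= 0:
        raise ValueError("row and column totals must be positive and equal")
    rng = _as_rng(seed)
    rows = np.repeat(np.arange(len(rt)), rt)
    cols = np.repeat(np.arange(len(ct)), ct)
    rng.shuffle(cols)
    out = np.zeros((len(rt), len(ct)), dtype=np.int64)
    np.add.at(out, (rows, cols), 1)
    return out


class _IndexStream:
    """Batched random index pairs; avoids per-draw Generator overhead."""

    def __init__(self, rng: np.random.Generator, r: int, c: int, batch: int = 4096):
        self.rng, self.r, self.c, self.batch = rng, r, c, batch
        self._buf = np.empty((0, 4), dtype=np.int64)
        self._pos = 0

    def next(self) -> tuple[int, int, int, int]:
        while True:
            if self._pos >= len(self._buf):
                draws = np.column_stack(
                    [
                        self.rng.integers(0, self.r, self.batch),
                        self.rng.integers(0, self.r, self.batch),
                        self.rng.integers(0, self.c, self.batch),
                        self.rng.integers(0, self.c, self.batch),
                    ]
                )
                self._buf = draws
                self._pos = 0
            i1, i2, j1, j2 = self._buf[self._pos]
            self._pos += 1
            if i1 != i2 and j1 != j2:
                return int(i1), int(i2), int(j1), int(j2)


def _local_fill(a, b, c, d) -> int:
    return int(a > 0) + int(b > 0) + int(c > 0) + int(d > 0)


def quasiswap_count_sample(matrix, seed=None, max_attempts: int = 500_000,
                           mixing_factor: int = 10) -> np.ndarray:
    """Draw a null matrix preserving marginals and the observed fill.

    After reaching the target fill, ``mixing_factor * n_cells`` additional
    unit-swap attempts are made, applying only those that keep the fill
    unchanged, to decorrelate the sample from the descent path.
    """
    w = np.asarray(matrix, dtype=np.int64)
    if w.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    target_fill = int(np.count_nonzero(w))
    rt = w.sum(axis=1)
    ct = w.sum(axis=0)
    rng = _as_rng(seed)
    M = patefield_sample(rt, ct, rng)
    r, c = M.shape
    if r < 2 or c < 2:
        return M  # marginals admit a unique table
    stream = _IndexStream(rng, r, c)
    fill = int(np.count_nonzero(M))
    attempts = 0
    while fill != target_fill:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                "quasiswap_count did not reach the observed fill within "
                f"{max_attempts} attempts"
            )
        i1, i2, j1, j2 = stream.next()
        a, b = M[i1, j1], M[i1, j2]
        cc, d = M[i2, j1], M[i2, j2]
        before = _local_fill(a, b, cc, d)
        if fill > target_fill:
            # full-depth moves; prefer the direction lowering local fill
            # most, and accept fill-neutral moves to keep the chain mobile
            cand = []
            t = min(a, d)
            if t > 0:
                cand.append((_local_fill(a - t, b + t, cc + t, d - t) - before, t, True))
            t = min(b, cc)
            if t > 0:
                cand.append((_local_fill(a + t, b - t, cc - t, d + t) - before, t, False))
            if cand:
                delta, t, diag = min(cand, key=lambda x: x[0])
                if delta <= 0:
                    sgn = 1 if diag else -1
                    M[i1, j1] -= sgn * t; M[i2, j2] -= sgn * t
                    M[i1, j2] += sgn * t; M[i2, j1] += sgn * t
                    fill += delta
        else:
            # unit moves that split mass into empty cells raise the fill
            if a > 0 and d > 0:
                delta = _local_fill(a - 1, b + 1, cc + 1, d - 1) - before
                if delta > 0:
                    M[i1, j1] -= 1; M[i2, j2] -= 1
                    M[i1, j2] += 1; M[i2, j1] += 1
                    fill += delta
                    continue
            if b > 0 and cc > 0:
                delta = _local_fill(a + 1, b - 1, cc - 1, d + 1) - before
                if delta > 0:
                    M[i1, j2] -= 1; M[i2, j1] -= 1
                    M[i1, j1] += 1; M[i2, j2] += 1
                    fill += delta
    # mixing phase: fill-preserving unit swaps
    for _ in range(mixing_factor * M.size):
        i1, i2, j1, j2 = stream.next()
        a, b = M[i1, j1], M[i1, j2]
        cc, d = M[i2, j1], M[i2, j2]
        before = _local_fill(a, b, cc, d)
        if a > 0 and d > 0 and _local_fill(a - 1, b + 1, cc + 1, d - 1) == before:
            M[i1, j1] -= 1; M[i2, j2] -= 1
            M[i1, j2] += 1; M[i2, j1] += 1
        elif b > 0 and cc > 0 and _local_fill(a + 1, b - 1, cc - 1, d + 1) == before:
            M[i1, j2] -= 1; M[i2, j1] -= 1
            M[i1, j1] += 1; M[i2, j2] += 1
    return M


NULL_MODELS = ("patefield", "quasiswap_count")


@dataclass
class NullEnsemble:
    """A seeded set of randomized matrices under one null model."""

    model: str
    seed: int | None
    samples: list[np.ndarray] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def generate_null_ensemble(net, model: str = "patefield", n_samples: int = 1000,
                           seed=None) -> NullEnsemble:
    """Generate ``n_samples`` null matrices for a network or matrix."""
    if model not in NULL_MODELS:
        raise ValueError(f"unknown null model {model!r}; expected one of {NULL_MODELS}")
    w = as_matrix(net)
    rng = _as_rng(seed)
    samples = []
    rt = w.sum(axis=1)
    ct = w.sum(axis=0)
    for _ in range(n_samples):
        if model == "patefield":
            samples.append(patefield_sample(rt, ct, rng))
        else:
            samples.append(quasiswap_count_sample(w, rng))
    return NullEnsemble(model=model, seed=seed if not isinstance(seed, np.random.Generator) else None,
                        samples=samples)


@dataclass
class DeltaMetric:
    """Observed metric value minus its null-ensemble mean."""

    metric: str
    observed: float
    null_mean: float
    delta: float
    n_samples: int
    n_skipped: int = 0


def delta_transform(metric_fn: Callable, net, ensemble: NullEnsemble,
                    name: str | None = None) -> DeltaMetric:
    """Delta-transform a metric against a null ensemble.

    Samples on which the metric is undefined are skipped and counted; a
    warning is emitted when more than 10% of the ensemble is skipped.
    """
    if ensemble.n_samples == 0:
        raise ValueError("ensemble is empty")
    observed = float(metric_fn(net))
    values = []
    skipped = 0
    for sample in ensemble.samples:
        try:
            values.append(float(metric_fn(sample)))
        except UndefinedMetricError:
            skipped += 1
    if not values:
        raise UndefinedMetricError("metric undefined on every null sample")
    if skipped > 0.1 * ensemble.n_samples:
        warnings.warn(
            f"metric undefined on {skipped}/{ensemble.n_samples} null samples",
            RuntimeWarning,
        )
    null_mean = float(np.mean(values))
    return DeltaMetric(
        metric=name or getattr(metric_fn, "__name__", "metric"),
        observed=observed,
        null_mean=null_mean,
        delta=observed - null_mean,
        n_samples=ensemble.n_samples,
        n_skipped=skipped,
    )
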