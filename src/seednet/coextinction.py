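"""Topological coextinction model for seed-dispersal networks.

Bird species are removed one at a time in order of least to most
interaction frequency (a proxy for abundance, mirroring the expectation
that rare species are lost first).  A plant undergoes dispersal failure
once it has lost at least a threshold fraction (default 75%) of its
original interaction frequency; failure is absorbing.  The survival curve
(fraction of birds removed vs. fraction of plants still serviced) yields

* robustness: the trapezoidal area under the curve, in [0, 1];
* per-plant resilience: the proportion of bird species that had to be
  removed before that plant failed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .network import LabeledNetwork
from .network_metrics import as_matrix


def removal_sequence(net) -> list:
    """Bird removal order: ascending total frequency, ties by species id.

    Birds with zero totals (e.g. dropped by pruning) are excluded.
    """
    w = as_matrix(net)
    totals = w.sum(axis=0)
    if isinstance(net, LabeledNetwork):
        ids = net.birds
    else:
        ids = list(range(w.shape[1]))
    present = [(int(totals[j]), ids[j]) for j in range(len(ids)) if totals[j] > 0]
    present.sort(key=lambda t: (t[0], t[1]))
    return [bird for _, bird in present]


@dataclass
class CoextinctionResult:
    """Removal order, survival curve and failure bookkeeping."""

    removal_order: list
    #: (A+1, 2) array of (fraction birds removed, fraction plants surviving)
    curve: np.ndarray
    #: plant id -> 1-based removal step at which the plant failed
    failure_step: dict
    n_birds: int
    n_plants: int
    threshold: float


def simulate_coextinction(net, threshold: float = 0.75,
                          removal_order: list | None = None) -> CoextinctionResult:
    """Run the ordered bird-removal simulation.

    ``removal_order`` defaults to :func:`removal_sequence` recomputed on
    the given network state; pass an explicit order to reuse the sequence
    derived from another state.  Plants with zero original totals are
    excluded from the curve (with a warning).
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("failure threshold must be in (0, 1]")
    w = as_matrix(net).astype(np.int64)
    if isinstance(net, LabeledNetwork):
        plant_ids = net.plants
        bird_index = {b: j for j, b in enumerate(net.birds)}
    else:
        plant_ids = list(range(w.shape[0]))
        bird_index = {j: j for j in range(w.shape[1])}
    if removal_order is None:
        removal_order = removal_sequence(net)
    if not removal_order:
        raise ValueError("no bird with positive total to remove")

    original = w.sum(axis=1)
    keep = original > 0
    if not np.all(keep):
        warnings.warn("plants with zero totals excluded from the coextinction curve",
                      RuntimeWarning)
    plants = [p for p, k in zip(plant_ids, keep) if k]
    w = w[keep, :]
    original = original[keep]

    A = len(removal_order)
    n_plants = len(plants)
    remaining = original.astype(float).copy()
    failed = np.zeros(n_plants, dtype=bool)
    failure_step: dict = {}
    curve = [(0.0, 1.0)]
    for k, bird in enumerate(removal_order, start=1):
        j = bird_index[bird]
        remaining -= as_matrix(net)[keep, j]
        lost = (original - remaining) / original
        newly = (~failed) & (lost >= threshold - 1e-12)
        for idx in np.nonzero(newly)[0]:
            failure_step[plants[idx]] = k
        failed |= newly
        curve.append((k / A, float((~failed).sum()) / n_plants))
    return CoextinctionResult(
        removal_order=list(removal_order),
        curve=np.array(curve),
        failure_step=failure_step,
        n_birds=A,
        n_plants=n_plants,
        threshold=threshold,
    )


def robustness(result: CoextinctionResult) -> float:
    """Trapezoidal area under the survival curve, in [0, 1]."""
    x, y = result.curve[:, 0], result.curve[:, 1]
    return float(np.trapezoid(y, x))


def resilience_75(result: CoextinctionResult, plant) -> float:
    """Fraction of birds removed before the plant failed (in (0, 1])."""
    if plant not in result.failure_step:
        raise KeyError(f"plant {plant!r} absent from the simulation")
    return result.failure_step[plant] / result.n_birds


def resilience_table(result: CoextinctionResult) -> dict:
    """Per-plant resilience values for all simulated plants."""
    return {p: s / result.n_birds for p, s in result.failure_step.items()}
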