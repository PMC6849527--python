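"""Species-level metrics: degree, interaction frequency, d' and strength.

Degree and interaction frequency are retained (as zero) for species that
lost every link to pruning; d' and species strength are undefined for such
species and reported as missing (NaN), mirroring how means would otherwise
be biased when species drop out.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .network import LabeledNetwork


def _locate(net: LabeledNetwork, species: str) -> tuple[str, int]:
    if species in net.plants:
        return "plant", net.plants.index(species)
    if species in net.birds:
        return "bird", net.birds.index(species)
    raise KeyError(f"unknown species {species!r} in network {net.network_id!r}")


def degree(net: LabeledNetwork, species: str) -> int:
    """Number of partners with a nonzero link (0 allowed after pruning)."""
    guild, idx = _locate(net, species)
    vec = net.weights[idx, :] if guild == "plant" else net.weights[:, idx]
    return int(np.count_nonzero(vec))


def interaction_frequency(net: LabeledNetwork, species: str) -> int:
    """Marginal total of the species (row total A_i or column total A_j)."""
    guild, idx = _locate(net, species)
    vec = net.weights[idx, :] if guild == "plant" else net.weights[:, idx]
    return int(vec.sum())


# -- d' --------------------------------------------------------------------

def _largest_remainder(total: int, shares: np.ndarray) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``shares``."""
    ideal = total * shares / shares.sum()
    base = np.floor(ideal).astype(np.int64)
    short = int(total - base.sum())
    if short > 0:
        frac = ideal - base
        for j in np.argsort(-frac, kind="stable")[:short]:
            base[j] += 1
    return base


def _kl(alloc: np.ndarray, q: np.ndarray) -> float:
    total = alloc.sum()
    mask = alloc > 0
    p = alloc[mask] / total
    return float((p * np.log(p / q[mask])).sum())


def _min_kl_alloc(total: int, q: np.ndarray) -> np.ndarray:
    """Integer allocation minimizing KL divergence from availability ``q``.

    The objective is separable and convex in the allocation, so steepest-
    descent unit exchanges from the proportional (largest-remainder) start
    reach the global integer optimum.
    """
    x = _largest_remainder(total, q)

    def term(v: int, qj: float) -> float:
        return 0.0 if v == 0 else (v / total) * np.log((v / total) / qj)

    while True:
        dec = np.array([term(v - 1, qj) - term(v, qj) if v > 0 else np.inf
                        for v, qj in zip(x, q)])
        inc = np.array([term(v + 1, qj) - term(v, qj) for v, qj in zip(x, q)])
        delta = dec[:, None] + inc[None, :]
        np.fill_diagonal(delta, np.inf)
        j, k = np.unravel_index(int(np.argmin(delta)), delta.shape)
        if delta[j, k] < -1e-13:
            x[j] -= 1
            x[k] += 1
        else:
            return x


def d_prime(net: LabeledNetwork, species: str) -> float:
    """Standardized Kullback-Leibler partner specialization in [0, 1].

    ``d = sum_j p'_j ln(p'_j / q_j)`` measures how far a species' partner
    use ``p'`` deviates from partner availability ``q`` (marginal totals of
    the current network state).  It is standardized between the integer-
    constrained minimum (a proportional allocation of the species' total)
    and maximum (the whole total on the rarest partner), then clamped.
    Returns NaN for a species with no links.
    """
    guild, idx = _locate(net, species)
    if guild == "plant":
        vec = net.weights[idx, :]
        partner_tot = net.bird_totals
    else:
        vec = net.weights[:, idx]
        partner_tot = net.plant_totals
    total = int(vec.sum())
    if total == 0:
        return float("nan")
    m = net.m
    active = partner_tot > 0
    q = partner_tot[active] / m
    v = vec[active]
    d = _kl(v, q)
    d_max = float(-np.log(q.min()))
    d_min = _kl(_min_kl_alloc(total, q), q)
    if d_max - d_min <= 1e-12:
        return 0.0
    return float(min(1.0, max(0.0, (d - d_min) / (d_max - d_min))))


def species_strength(net: LabeledNetwork, bird: str) -> float:
    """Sum over plants of the bird's share of each plant's interactions.

    ``strength(j) = sum_i a_ij / A_i``; over all birds the strengths sum to
    the number of plant species with links.  NaN for a bird with no links.
    """
    guild, j = _locate(net, bird)
    if guild != "bird":
        raise KeyError(f"{bird!r} is a plant; species strength is a frugivore metric")
    col = net.weights[:, j]
    if col.sum() == 0:
        return float("nan")
    rt = net.plant_totals
    mask = rt > 0
    return float((col[mask] / rt[mask]).sum())


def species_report(net: LabeledNetwork, state: str = "original") -> pd.DataFrame:
    """Tidy per-species metric table for one network state.

    Plants get degree, frequency and d'; birds get degree, frequency and
    strength.  Missing values (NaN) mark metrics undefined for zero-total
    species.
    """
    rows = []
    for p in net.plants:
        rows.append(
            {
                "network_id": net.network_id,
                "state": state,
                "guild": "plant",
                "species": p,
                "degree": degree(net, p),
                "frequency": interaction_frequency(net, p),
                "d_prime": d_prime(net, p),
                "strength": float("nan"),
            }
        )
    for b in net.birds:
        freq = interaction_frequency(net, b)
        rows.append(
            {
                "network_id": net.network_id,
                "state": state,
                "guild": "bird",
                "species": b,
                "degree": degree(net, b),
                "frequency": freq,
                "d_prime": float("nan"),
                "strength": species_strength(net, b),
            }
        )
    return pd.DataFrame(rows)
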