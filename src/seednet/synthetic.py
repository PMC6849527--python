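"""Seeded generator of outcome-labeled plant-frugivore visitation networks.

The generator emulates the statistical structure of European bird-fruit
visitation data so every pipeline stage can be exercised without field
data: lognormal species abundances produce skewed interaction-frequency
distributions; a configurable share of links (about a fifth to a half) is
non-mutualistic, but those links carry disproportionately little
interaction frequency (a damping factor < 1); some frugivores interact
exclusively non-mutualistically; and mixed-role birds switch between seed
dispersal and seed predation depending on a latent seed-size vs. bill-gape
threshold, so the same bird can have different outcomes on different
plants.

The generator is a structural emulator, not an estimator: it is not fitted
to any empirical network.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
import numpy as np

from .network import (
    LabeledNetwork,
    SEED_DISPERSAL,
    PULP_PECKING,
    SEED_PREDATION,
)

_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
          "XI", "XII", "XIII", "XIV", "XV"]


def _roman(i: int) -> str:
    return _ROMAN[i] if i < len(_ROMAN) else f"N{i + 1}"


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic ensemble.

    Defaults mirror the empirical setting the pipeline is designed for:
    seven networks of a few dozen species each, non-mutualistic links
    making up 21-48% of links but (via ``damping`` < 1) a much smaller
    share of total interaction frequency.
    """

    n_networks: int = 7
    n_plants: int = 20
    n_birds: int = 25
    #: lognormal sigma of latent species abundances (both guilds)
    plant_abundance_sigma: float = 1.5
    bird_abundance_sigma: float = 1.5
    #: expected total visit count per network before damping
    total_visits: float = 800.0
    #: fractions of birds by role flavor among flipped non-mutualists:
    #: pure pulp peckers, pure seed predators, mixed-role birds
    pulp_fraction: float = 0.12
    predator_fraction: float = 0.13
    mixed_fraction: float = 0.20
    disperser_fraction: float = 0.55
    #: target range for the share of links that are non-mutualistic
    nonmut_link_share: tuple[float, float] = (0.21, 0.48)
    #: multiplier applied to visit counts on non-mutualistic links
    damping: float = 0.25
    #: mixed-role birds destroy seeds smaller than their gape threshold
    gape_low: float = 0.3
    gape_high: float = 0.7
    #: fraction of labels marked as inferred (vs. direct) provenance
    inferred_fraction: float = 0.27
    #: optional negative-binomial dispersion (None -> Poisson counts)
    overdispersion: float | None = None
    seed: int | None = None

    def validate(self) -> None:
        fr = (self.pulp_fraction, self.predator_fraction,
              self.mixed_fraction, self.disperser_fraction)
        if any(f < 0 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError("role fractions must be non-negative and sum to 1")
        if not 0.0 < self.damping <= 1.0:
            raise ValueError("damping must be in (0, 1]")
        lo, hi = self.nonmut_link_share
        if not 0.0 <= lo <= hi < 1.0:
            raise ValueError("invalid non-mutualistic link-share range")
        if min(self.n_networks, self.n_plants, self.n_birds) < 1:
            raise ValueError("all counts must be >= 1")


def _draw_counts(rng: np.random.Generator, mu: np.ndarray,
                 overdispersion: float | None) -> np.ndarray:
    if overdispersion is None:
        return rng.poisson(mu)
    # negative binomial with mean mu and shape k (variance mu + mu^2/k)
    k = overdispersion
    lam = rng.gamma(shape=k, scale=mu / k)
    return rng.poisson(lam)


def generate_network(config: SyntheticConfig, seed, network_id: str = "I",
                     max_resample: int = 20) -> LabeledNetwork:
    """Generate one labeled visitation network.

    Deterministic given ``seed``.  Raises after ``max_resample`` attempts
    if the configuration cannot produce a feasible network (e.g. zero
    links drawn).
    """
    config.validate()
    rng = np.random.default_rng(seed)
    for _ in range(max_resample):
        net = _try_generate(config, rng, network_id)
        if net is not None:
            return net
    raise RuntimeError(f"could not generate a feasible network for {network_id!r}")


def _try_generate(config: SyntheticConfig, rng: np.random.Generator,
                  network_id: str) -> LabeledNetwork | None:
    P, A = config.n_plants, config.n_birds
    p_ab = rng.lognormal(0.0, config.plant_abundance_sigma, P)
    b_ab = rng.lognormal(0.0, config.bird_abundance_sigma, A)
    p_ab /= p_ab.sum()
    b_ab /= b_ab.sum()
    mu = config.total_visits * np.outer(p_ab, b_ab)
    w = _draw_counts(rng, mu, config.overdispersion).astype(np.int64)
    # every species observed at least once: attach isolated species to
    # their highest-propensity partner
    for i in range(P):
        if w[i, :].sum() == 0:
            w[i, int(np.argmax(mu[i, :]))] = 1
    for j in range(A):
        if w[:, j].sum() == 0:
            w[int(np.argmax(mu[:, j])), j] = 1
    n_links = np.count_nonzero(w)
    if n_links == 0:
        return None

    # latent traits for the mixed-role mechanism
    seed_size = rng.uniform(0.0, 1.0, P)
    gape = rng.uniform(config.gape_low, config.gape_high, A)

    # flip birds to non-mutualistic roles, lowest degree first (antagonists
    # have narrower niches than mutualists), until the target link share
    target = rng.uniform(*config.nonmut_link_share)
    roles = np.array(["disperser"] * A, dtype=object)
    degrees = (w > 0).sum(axis=0)
    jitter = rng.uniform(0.0, 0.5, A)
    flip_order = np.argsort(degrees + jitter, kind="stable")
    flavor_p = np.array([config.pulp_fraction, config.predator_fraction,
                         config.mixed_fraction])
    if flavor_p.sum() <= 0:
        flavor_p = np.array([0.0, 0.0, 1.0])
    flavor_p = flavor_p / flavor_p.sum()
    flavors = ("pulp", "predator", "mixed")

    def nonmut_links(roles_arr) -> int:
        count = 0
        for j in range(A):
            col = w[:, j] > 0
            if roles_arr[j] == "pulp":
                count += int(col.sum())
            elif roles_arr[j] == "predator":
                count += int(col.sum())
            elif roles_arr[j] == "mixed":
                count += int((col & (seed_size < gape[j])).sum())
        return count

    if target > 0:
        for j in flip_order:
            if nonmut_links(roles) >= target * n_links:
                break
            roles[j] = flavors[rng.choice(3, p=flavor_p)]
        # guarantee at least one exclusively non-mutualistic frugivore
        if (config.pulp_fraction + config.predator_fraction) > 0 and not any(
            r in ("pulp", "predator") for r in roles
        ):
            roles[flip_order[0]] = "predator"

    outcomes: dict[tuple[int, int], str] = {}
    for j in range(A):
        for i in range(P):
            if w[i, j] == 0:
                continue
            if roles[j] == "disperser":
                outcomes[(i, j)] = SEED_DISPERSAL
            elif roles[j] == "pulp":
                outcomes[(i, j)] = PULP_PECKING
            elif roles[j] == "predator":
                outcomes[(i, j)] = SEED_PREDATION
            else:  # mixed: small seeds are destroyed, large ones dispersed
                outcomes[(i, j)] = (
                    SEED_PREDATION if seed_size[i] < gape[j] else SEED_DISPERSAL
                )

    # damp visit counts on non-mutualistic links: these interactions are
    # more important in qualitative than quantitative terms
    if config.damping < 1.0:
        for (i, j), out in outcomes.items():
            if out != SEED_DISPERSAL:
                w[i, j] = max(1, int(np.floor(config.damping * w[i, j] + 0.5)))

    if w.sum() - sum(
        w[i, j] for (i, j), o in outcomes.items() if o != SEED_DISPERSAL
    ) <= 0:
        return None  # no mutualistic weight left; infeasible draw

    plants = [f"P{i + 1:02d}" for i in range(P)]
    birds = [f"B{j + 1:02d}" for j in range(A)]
    named_outcomes = {(plants[i], birds[j]): out for (i, j), out in outcomes.items()}
    provenance = {
        key: ("inferred" if rng.random() < config.inferred_fraction else "direct")
        for key in named_outcomes
    }
    return LabeledNetwork(
        network_id=network_id,
        plants=plants,
        birds=birds,
        weights=w,
        outcomes=named_outcomes,
        provenance=provenance,
    )


def generate_ensemble(config: SyntheticConfig) -> tuple[dict[str, LabeledNetwork], dict]:
    """Generate ``config.n_networks`` networks with derived sub-seeds.

    Returns the networks (keyed by id) and a manifest recording the
    configuration and every sub-seed, so any single network can be
    regenerated in isolation.
    """
    config.validate()
    master = np.random.default_rng(config.seed)
    sub_seeds = [int(s) for s in master.integers(0, 2**31 - 1, config.n_networks)]
    nets: dict[str, LabeledNetwork] = {}
    for k, sub in enumerate(sub_seeds):
        nid = _roman(k)
        nets[nid] = generate_network(config, sub, network_id=nid)
    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "sub_seeds": {nid: s for nid, s in zip(nets, sub_seeds)},
    }
    return nets, manifest


def nonmut_shares(net: LabeledNetwork) -> tuple[float, float]:
    """Realized (link share, frequency share) of non-mutualistic links."""
    links = 0
    freq = 0
    for (p, b), out in net.outcomes.items():
        if out != SEED_DISPERSAL:
            links += 1
            freq += net.weight(p, b)
    return links / net.n_links, freq / net.m


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
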