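"""Outcome-labeled quantitative bipartite networks.

A visitation network records how often each frugivorous bird species visits
each fleshy-fruited plant species.  Every link additionally carries a
functional outcome: ``seed_dispersal`` (the bird swallows whole fruits and
disperses viable seeds, a mutualism), ``pulp_pecking`` (the bird pecks pulp
and leaves the seed below the parent, an exploitation) or ``seed_predation``
(the bird destroys the seed, an antagonism).  The outcome label makes it
possible to reduce a visitation network to the true seed-dispersal network
by pruning non-mutualistic links.

Conventions: plants are rows, birds are columns, weights are non-negative
integer visit counts.  Species identities are referenced by id externally;
indices are 0-based internally.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import EdgeListError

SEED_DISPERSAL = "seed_dispersal"
PULP_PECKING = "pulp_pecking"
SEED_PREDATION = "seed_predation"
UNCLASSIFIED = "unclassified"

OUTCOMES = (SEED_DISPERSAL, PULP_PECKING, SEED_PREDATION)
NON_MUTUALISTIC = (PULP_PECKING, SEED_PREDATION)

#: Single-letter codes used in label-matrix TSV files.
OUTCOME_CODES = {SEED_DISPERSAL: "D", PULP_PECKING: "P", SEED_PREDATION: "S"}
CODE_OUTCOMES = {v: k for k, v in OUTCOME_CODES.items()}

PRUNE_MODES = ("all_nonmutualistic", "predation_only")
_PRUNE_ALIASES = {
    "all": "all_nonmutualistic",
    "all_nonmutualistic": "all_nonmutualistic",
    "predation": "predation_only",
    "predation_only": "predation_only",
}


def normalize_prune_mode(mode: str) -> str:
    try:
        return _PRUNE_ALIASES[mode]
    except KeyError:
        raise ValueError(f"unknown prune mode {mode!r}; expected one of {PRUNE_MODES}")


@dataclass(frozen=True)
class PlantTraits:
    """Fruit and seed traits used when inferring interaction outcomes."""

    plant: str
    genus: str
    fruit_type: str
    fruit_size_class: int
    seed_size_class: int


def read_traits(path) -> dict[str, PlantTraits]:
    """Read a plant-trait CSV (plant,genus,fruit_type,fruit_size_class,seed_size_class)."""
    df = pd.read_csv(path, dtype=str)
    required = ["plant", "genus", "fruit_type", "fruit_size_class", "seed_size_class"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise EdgeListError(f"traits file missing columns: {missing}")
    out: dict[str, PlantTraits] = {}
    for row in df.itertuples(index=False):
        if row.plant in out:
            raise EdgeListError(f"duplicate trait record for plant {row.plant!r}")
        out[row.plant] = PlantTraits(
            plant=row.plant,
            genus=row.genus,
            fruit_type=row.fruit_type,
            fruit_size_class=int(row.fruit_size_class),
            seed_size_class=int(row.seed_size_class),
        )
    return out


@dataclass
class LabeledNetwork:
    """One quantitative bipartite network with per-link outcome labels.

    Parameters
    ----------
    network_id : str
        Identifier of the network (e.g. a study-site code).
    plants, birds : list of str
        Ordered species ids for rows and columns.
    weights : (n_plants, n_birds) integer array
        Visit counts ``a_ij``.
    outcomes : dict mapping (plant, bird) -> outcome
        One label per nonzero cell.
    provenance : dict mapping (plant, bird) -> {"direct", "inferred"}
        How each label was obtained; defaults to "direct" for all links.
    """

    network_id: str
    plants: list[str]
    birds: list[str]
    weights: np.ndarray
    outcomes: dict[tuple[str, str], str]
    provenance: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights)
        if self.weights.shape != (len(self.plants), len(self.birds)):
            raise ValueError("weights shape does not match species lists")
        if not np.issubdtype(self.weights.dtype, np.integer):
            w = self.weights
            if not np.all(w == np.floor(w)):
                raise ValueError("weights must be integers")
            self.weights = w.astype(np.int64)
        else:
            self.weights = self.weights.astype(np.int64)
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if len(set(self.plants)) != len(self.plants):
            raise ValueError("duplicate plant ids")
        if len(set(self.birds)) != len(self.birds):
            raise ValueError("duplicate bird ids")
        if self.weights.sum() <= 0:
            raise ValueError(f"network {self.network_id!r} has zero total weight")
        self._validate_labels()
        if not self.provenance:
            self.provenance = {k: "direct" for k in self.outcomes}

    def _validate_labels(self, allow_unclassified: bool = True) -> None:
        valid = set(OUTCOMES) | {UNCLASSIFIED}
        for (p, b), out in self.outcomes.items():
            if out not in valid:
                raise ValueError(f"invalid outcome {out!r} for ({p}, {b})")
        for i, p in enumerate(self.plants):
            for j, b in enumerate(self.birds):
                if self.weights[i, j] > 0 and (p, b) not in self.outcomes:
                    raise ValueError(f"nonzero cell ({p}, {b}) has no outcome label")
                if self.weights[i, j] == 0 and (p, b) in self.outcomes:
                    raise ValueError(f"zero cell ({p}, {b}) carries an outcome label")

    # -- basic accessors ---------------------------------------------------
    @property
    def matrix(self) -> np.ndarray:
        return self.weights

    @property
    def m(self) -> int:
        """Grand total interaction frequency."""
        return int(self.weights.sum())

    @property
    def n_links(self) -> int:
        return int(np.count_nonzero(self.weights))

    @property
    def plant_totals(self) -> np.ndarray:
        return self.weights.sum(axis=1)

    @property
    def bird_totals(self) -> np.ndarray:
        return self.weights.sum(axis=0)

    def plant_index(self, plant: str) -> int:
        try:
            return self.plants.index(plant)
        except ValueError:
            raise KeyError(f"unknown plant {plant!r} in network {self.network_id!r}")

    def bird_index(self, bird: str) -> int:
        try:
            return self.birds.index(bird)
        except ValueError:
            raise KeyError(f"unknown bird {bird!r} in network {self.network_id!r}")

    def weight(self, plant: str, bird: str) -> int:
        return int(self.weights[self.plant_index(plant), self.bird_index(bird)])

    def copy(self) -> "LabeledNetwork":
        return LabeledNetwork(
            network_id=self.network_id,
            plants=list(self.plants),
            birds=list(self.birds),
            weights=self.weights.copy(),
            outcomes=dict(self.outcomes),
            provenance=dict(self.provenance),
        )

    def to_edge_list(self) -> pd.DataFrame:
        rows = []
        for i, p in enumerate(self.plants):
            for j, b in enumerate(self.birds):
                w = int(self.weights[i, j])
                if w > 0:
                    rows.append(
                        {
                            "network_id": self.network_id,
                            "plant": p,
                            "bird": b,
                            "count": w,
                            "outcome": self.outcomes[(p, b)],
                            "provenance": self.provenance.get((p, b), "direct"),
                        }
                    )
        return pd.DataFrame(rows, columns=["network_id", "plant", "bird", "count", "outcome", "provenance"])


# -- edge-list I/O ---------------------------------------------------------

EDGE_COLUMNS = ["network_id", "plant", "bird", "count", "outcome", "provenance"]


def read_edge_list(path, allow_unlabeled: bool = False) -> dict[str, LabeledNetwork]:
    """Read an edge-list CSV into one :class:`LabeledNetwork` per network id.

    Duplicate (plant, bird) rows within a network are summed and must share
    one outcome label; conflicting labels are a hard error naming the pair.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in EDGE_COLUMNS if c not in df.columns]
    if missing:
        raise EdgeListError(f"edge list missing columns: {missing}")
    counts = []
    for raw in df["count"]:
        try:
            val = int(raw)
        except ValueError:
            raise EdgeListError(f"non-integer count {raw!r}")
        if val < 1:
            raise EdgeListError(f"count must be >= 1, got {val}")
        counts.append(val)
    df = df.assign(count=counts)

    nets: dict[str, LabeledNetwork] = {}
    for nid in pd.unique(df["network_id"]):
        sub = df[df["network_id"] == nid]
        plants = list(pd.unique(sub["plant"]))
        birds = list(pd.unique(sub["bird"]))
        weights = np.zeros((len(plants), len(birds)), dtype=np.int64)
        outcomes: dict[tuple[str, str], str] = {}
        provenance: dict[tuple[str, str], str] = {}
        pi = {p: i for i, p in enumerate(plants)}
        bi = {b: j for j, b in enumerate(birds)}
        for row in sub.itertuples(index=False):
            key = (row.plant, row.bird)
            out = row.outcome if row.outcome else UNCLASSIFIED
            if out not in OUTCOMES and out != UNCLASSIFIED:
                raise EdgeListError(f"invalid outcome {out!r} for {key} in network {nid!r}")
            if out == UNCLASSIFIED and not allow_unlabeled:
                raise EdgeListError(
                    f"unlabeled interaction {key} in network {nid!r}; "
                    "pass allow_unlabeled=True to defer classification"
                )
            if key in outcomes and outcomes[key] != out:
                raise EdgeListError(
                    f"conflicting outcome labels for pair {key} in network {nid!r}: "
                    f"{outcomes[key]!r} vs {out!r}"
                )
            weights[pi[row.plant], bi[row.bird]] += row.count
            outcomes[key] = out
            prov = row.provenance or "direct"
            # a pair seen both directly and by inference counts as direct
            if provenance.get(key) != "direct":
                provenance[key] = prov
        nets[nid] = LabeledNetwork(
            network_id=nid,
            plants=plants,
            birds=birds,
            weights=weights,
            outcomes=outcomes,
            provenance=provenance,
        )
    return nets


def write_edge_list(nets: Iterable[LabeledNetwork] | Mapping[str, LabeledNetwork], path) -> None:
    if isinstance(nets, Mapping):
        nets = list(nets.values())
    frames = [net.to_edge_list() for net in nets]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_matrix_tsv(net: LabeledNetwork, weights_path, labels_path=None) -> None:
    """Write the adjacency matrix (and optionally outcome codes) as TSV."""
    wdf = pd.DataFrame(net.weights, index=net.plants, columns=net.birds)
    wdf.to_csv(weights_path, sep="\t")
    if labels_path is not None:
        codes = np.full(net.weights.shape, "-", dtype=object)
        for (p, b), out in net.outcomes.items():
            codes[net.plant_index(p), net.bird_index(b)] = OUTCOME_CODES.get(out, "-")
        pd.DataFrame(codes, index=net.plants, columns=net.birds).to_csv(labels_path, sep="\t")


def read_matrix_tsv(weights_path, labels_path, network_id: str) -> LabeledNetwork:
    wdf = pd.read_csv(weights_path, sep="\t", index_col=0)
    ldf = pd.read_csv(labels_path, sep="\t", index_col=0)
    if list(wdf.index) != list(ldf.index) or list(wdf.columns) != list(ldf.columns):
        raise EdgeListError("weight and label matrices have mismatched species")
    plants = [str(p) for p in wdf.index]
    birds = [str(b) for b in wdf.columns]
    weights = wdf.to_numpy()
    outcomes = {}
    for i, p in enumerate(plants):
        for j, b in enumerate(birds):
            if weights[i, j] > 0:
                code = str(ldf.iat[i, j])
                if code not in CODE_OUTCOMES:
                    raise EdgeListError(f"invalid outcome code {code!r} at ({p}, {b})")
                outcomes[(p, b)] = CODE_OUTCOMES[code]
    return LabeledNetwork(network_id=network_id, plants=plants, birds=birds,
                          weights=weights, outcomes=outcomes)


# -- rate conversion -------------------------------------------------------

def rate_to_counts(rate: float, sampling_time: float) -> int:
    """Convert a visitation rate to an integer visit count.

    The count is ``rate x sampling_time`` rounded to the nearest whole
    number, with halves rounded up (so ``rate_to_counts(0.25, 10) == 3``).
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if sampling_time <= 0:
        raise ValueError("sampling_time must be positive")
    return int(math.floor(rate * sampling_time + 0.5))


# -- outcome inference -----------------------------------------------------

def infer_outcome(
    bird: str,
    plant: str,
    known: Iterable[tuple[str, str, str]],
    traits: Mapping[str, PlantTraits],
) -> tuple[str, str]:
    """Infer the outcome of an unobserved (bird, plant) pair.

    Two rules, in order of precedence:

    1. the same bird interacting with a congeneric plant (same genus);
    2. the same bird interacting with a plant of the same fruit type and
       seed-size class.

    Within a rule, conflicting labels are resolved by majority vote; a tie
    under rule 1 is broken by the vote under rule 2, and any remaining tie
    deterministically by lexicographic label order.  Returns
    ``("unclassified", "inferred")`` when no rule fires.
    """
    target = traits.get(plant)
    rule1: list[str] = []
    rule2: list[str] = []
    for b, p, out in known:
        if b != bird or p == plant or out not in OUTCOMES:
            continue
        t = traits.get(p)
        if t is None or target is None:
            continue
        if t.genus == target.genus:
            rule1.append(out)
        elif t.fruit_type == target.fruit_type and t.seed_size_class == target.seed_size_class:
            rule2.append(out)

    def majority(votes: list[str], tiebreak: list[str]) -> str | None:
        if not votes:
            return None
        counts = Counter(votes)
        top = max(counts.values())
        tied = sorted(lab for lab, c in counts.items() if c == top)
        if len(tied) == 1:
            return tied[0]
        if tiebreak:
            sub = Counter(lab for lab in tiebreak if lab in tied)
            if sub:
                top2 = max(sub.values())
                tied2 = sorted(lab for lab, c in sub.items() if c == top2)
                return tied2[0]
        return tied[0]

    label = majority(rule1, rule2)
    if label is None:
        label = majority(rule2, [])
    if label is None:
        return (UNCLASSIFIED, "inferred")
    return (label, "inferred")


def label_missing(
    net: LabeledNetwork,
    known: Iterable[tuple[str, str, str]] | None = None,
    traits: Mapping[str, PlantTraits] | None = None,
) -> LabeledNetwork:
    """Fill unclassified links of ``net`` by congeneric / trait inference.

    ``known`` defaults to the directly classified links of ``net`` itself.
    Links that remain unclassified keep the ``unclassified`` label.
    """
    traits = traits or {}
    if known is None:
        known = [
            (b, p, out)
            for (p, b), out in net.outcomes.items()
            if out in OUTCOMES and net.provenance.get((p, b)) == "direct"
        ]
    known = list(known)
    out_net = net.copy()
    for (p, b), out in net.outcomes.items():
        if out == UNCLASSIFIED:
            label, prov = infer_outcome(b, p, known, traits)
            out_net.outcomes[(p, b)] = label
            out_net.provenance[(p, b)] = prov
    return out_net


# -- pruning ---------------------------------------------------------------

@dataclass
class PruneResult:
    """Outcome of removing non-mutualistic links from a network.

    The pruned network keeps all species rows/columns (some may have zero
    totals); species whose totals dropped to zero are listed separately so
    metric functions can include or exclude them as each metric requires.
    """

    pruned: LabeledNetwork
    dropped_plants: list[str]
    dropped_birds: list[str]
    removed_links: int
    removed_frequency: int


def prune(net: LabeledNetwork, mode: str) -> PruneResult:
    """Zero out links by functional outcome.

    ``all_nonmutualistic`` removes pulp-pecking and seed-predation links,
    leaving the true seed-dispersal network; ``predation_only`` removes only
    seed-predation links.  The input network is left untouched.
    """
    mode = normalize_prune_mode(mode)
    remove = set(NON_MUTUALISTIC) if mode == "all_nonmutualistic" else {SEED_PREDATION}
    weights = net.weights.copy()
    outcomes = {}
    provenance = {}
    removed_links = 0
    removed_frequency = 0
    for (p, b), out in net.outcomes.items():
        i, j = net.plant_index(p), net.bird_index(b)
        if out in remove:
            removed_links += 1
            removed_frequency += int(weights[i, j])
            weights[i, j] = 0
        else:
            outcomes[(p, b)] = out
            provenance[(p, b)] = net.provenance.get((p, b), "direct")
    if weights.sum() <= 0:
        raise ValueError(
            f"pruning mode {mode!r} removed every link of network {net.network_id!r}"
        )
    pruned = LabeledNetwork(
        network_id=net.network_id,
        plants=list(net.plants),
        birds=list(net.birds),
        weights=weights,
        outcomes=outcomes,
        provenance=provenance,
    )
    dropped_plants = [p for i, p in enumerate(net.plants)
                      if net.plant_totals[i] > 0 and weights[i, :].sum() == 0]
    dropped_birds = [b for j, b in enumerate(net.birds)
                     if net.bird_totals[j] > 0 and weights[:, j].sum() == 0]
    return PruneResult(
        pruned=pruned,
        dropped_plants=dropped_plants,
        dropped_birds=dropped_birds,
        removed_links=removed_links,
        removed_frequency=removed_frequency,
    )
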