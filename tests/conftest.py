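import numpy as np
import pytest

from seednet.network import (
    LabeledNetwork,
    PULP_PECKING,
    SEED_DISPERSAL,
    SEED_PREDATION,
)


def net_from_matrix(w, outcome_grid=None, network_id="toy"):
    """Build a LabeledNetwork from a matrix and an optional outcome-code
    grid ('D'/'P'/'S' per cell; defaults to all seed dispersal)."""
    w = np.asarray(w)
    plants = [f"P{i+1}" for i in range(w.shape[0])]
    birds = [f"B{j+1}" for j in range(w.shape[1])]
    code_map = {"D": SEED_DISPERSAL, "P": PULP_PECKING, "S": SEED_PREDATION}
    outcomes = {}
    for i in range(w.shape[0]):
        for j in range(w.shape[1]):
            if w[i, j] > 0:
                code = outcome_grid[i][j] if outcome_grid else "D"
                outcomes[(plants[i], birds[j])] = code_map[code]
    return LabeledNetwork(network_id=network_id, plants=plants, birds=birds,
                          weights=w, outcomes=outcomes)


@pytest.fixture
def mixed_net():
    """2 plants x 3 birds with one link of each outcome type."""
    w = np.array([[4, 2, 0], [1, 0, 3]])
    grid = [["D", "P", "D"], ["D", "D", "S"]]
    return net_from_matrix(w, grid)


@pytest.fixture
def edge_csv(tmp_path):
    path = tmp_path / "edges.csv"
    path.write_text(
        "network_id,plant,bird,count,outcome,provenance\n"
        "I,P1,B1,4,seed_dispersal,direct\n"
        "I,P1,B2,2,pulp_pecking,direct\n"
        "I,P2,B1,1,seed_dispersal,inferred\n"
        "I,P2,B3,3,seed_predation,direct\n"
        "II,P1,B1,5,seed_dispersal,direct\n"
        "II,P2,B2,2,seed_predation,direct\n"
    )
    return path


def random_integer_matrix(rng, max_dim=6, max_val=6):
    """A random integer matrix with at least one positive entry."""
    r = int(rng.integers(2, max_dim + 1))
    c = int(rng.integers(2, max_dim + 1))
    w = rng.integers(0, max_val + 1, size=(r, c))
    if w.sum() == 0:
        w[rng.integers(r), rng.integers(c)] = 1
    return w
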