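"""Core network model: edge-list I/O, rate conversion, inference, pruning."""

import numpy as np
import pytest

import seednet as sn
from seednet.exceptions import EdgeListError
from seednet.network import PlantTraits, UNCLASSIFIED

from conftest import net_from_matrix


class TestEdgeListIO:
    def test_read_builds_one_network_per_id(self, edge_csv):
        nets = sn.read_edge_list(edge_csv)
        assert set(nets) == {"I", "II"}
        net = nets["I"]
        assert net.plants == ["P1", "P2"]
        assert net.birds == ["B1", "B2", "B3"]
        assert net.n_links == 4
        assert net.weight("P1", "B1") == 4
        assert net.outcomes[("P2", "B3")] == sn.SEED_PREDATION
        assert net.provenance[("P2", "B1")] == "inferred"

    def test_duplicate_rows_are_summed(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text(
            "network_id,plant,bird,count,outcome,provenance\n"
            "I,P1,B1,2,seed_dispersal,direct\n"
            "I,P1,B1,2,seed_dispersal,direct\n"
        )
        net = sn.read_edge_list(path)["I"]
        assert net.weight("P1", "B1") == 4

    def test_conflicting_outcomes_error_names_pair(self, tmp_path):
        path = tmp_path / "conflict.csv"
        path.write_text(
            "network_id,plant,bird,count,outcome,provenance\n"
            "I,P1,B1,2,seed_dispersal,direct\n"
            "I,P1,B1,1,seed_predation,direct\n"
        )
        with pytest.raises(EdgeListError, match="P1.*B1"):
            sn.read_edge_list(path)

    def test_non_integer_count_is_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "network_id,plant,bird,count,outcome,provenance\n"
            "I,P1,B1,2.5,seed_dispersal,direct\n"
        )
        with pytest.raises(EdgeListError, match="non-integer"):
            sn.read_edge_list(path)

    def test_write_read_round_trip_is_fixed_point(self, edge_csv, tmp_path):
        nets = sn.read_edge_list(edge_csv)
        out = tmp_path / "roundtrip.csv"
        sn.write_edge_list(nets, out)
        again = sn.read_edge_list(out)
        for nid in nets:
            assert nets[nid].plants == again[nid].plants
            assert nets[nid].birds == again[nid].birds
            assert np.array_equal(nets[nid].weights, again[nid].weights)
            assert nets[nid].outcomes == again[nid].outcomes
            assert nets[nid].provenance == again[nid].provenance

    def test_matrix_tsv_round_trip(self, mixed_net, tmp_path):
        wp, lp = tmp_path / "w.tsv", tmp_path / "l.tsv"
        sn.write_matrix_tsv(mixed_net, wp, lp)
        again = sn.read_matrix_tsv(wp, lp, network_id="toy")
        assert np.array_equal(again.weights, mixed_net.weights)
        assert again.outcomes == mixed_net.outcomes


class TestRateToCounts:
    @pytest.mark.parametrize(
        "rate,time,expected",
        [(0.5, 10, 5), (0.33, 10, 3), (0.25, 10, 3), (0.0, 5, 0), (1.26, 10, 13)],
    )
    def test_rounding_half_up(self, rate, time, expected):
        assert sn.rate_to_counts(rate, time) == expected

    def test_negative_inputs_error(self):
        with pytest.raises(ValueError):
            sn.rate_to_counts(-0.1, 10)
        with pytest.raises(ValueError):
            sn.rate_to_counts(0.5, 0)


TRAITS = {
    "Sorbus aria": PlantTraits("Sorbus aria", "Sorbus", "pome", 2, 1),
    "Sorbus aucuparia": PlantTraits("Sorbus aucuparia", "Sorbus", "pome", 2, 1),
    "Prunus avium": PlantTraits("Prunus avium", "Prunus", "drupe", 2, 3),
    "Prunus padus": PlantTraits("Prunus padus", "Prunus", "drupe", 2, 3),
    "Rubus idaeus": PlantTraits("Rubus idaeus", "Rubus", "berry", 1, 1),
}


class TestInferOutcome:
    def test_congeneric_transfer(self):
        # a finch known to destroy seeds of one rowan species is inferred
        # to destroy the congener's similar seeds too
        known = [("greenfinch", "Sorbus aucuparia", sn.SEED_PREDATION)]
        out, prov = sn.infer_outcome("greenfinch", "Sorbus aria", known, TRAITS)
        assert out == sn.SEED_PREDATION
        assert prov == "inferred"

    def test_no_rule_fires_gives_unclassified(self):
        known = [("blackbird", "Prunus avium", sn.SEED_DISPERSAL)]
        out, _ = sn.infer_outcome("greenfinch", "Rubus idaeus", known, TRAITS)
        assert out == UNCLASSIFIED

    def test_majority_vote_among_congeners(self):
        known = [
            ("tit", "Prunus avium", sn.PULP_PECKING),
            ("tit", "Prunus padus", sn.PULP_PECKING),
            ("tit", "Prunus padus", sn.SEED_PREDATION),
        ]
        out, _ = sn.infer_outcome("tit", "Prunus cerasus", known,
                                  {**TRAITS, "Prunus cerasus":
                                   PlantTraits("Prunus cerasus", "Prunus", "drupe", 2, 3)})
        assert out == sn.PULP_PECKING

    def test_trait_similarity_when_no_congener(self):
        traits = {**TRAITS, "Cornus mas": PlantTraits("Cornus mas", "Cornus", "drupe", 2, 3)}
        known = [("warbler", "Prunus avium", sn.SEED_DISPERSAL)]
        out, _ = sn.infer_outcome("warbler", "Cornus mas", known, traits)
        assert out == sn.SEED_DISPERSAL

    def test_label_missing_fills_unclassified_links(self, tmp_path):
        path = tmp_path / "partial.csv"
        path.write_text(
            "network_id,plant,bird,count,outcome,provenance\n"
            "I,Sorbus aucuparia,greenfinch,3,seed_predation,direct\n"
            "I,Sorbus aria,greenfinch,2,,\n"
        )
        net = sn.read_edge_list(path, allow_unlabeled=True)["I"]
        labeled = sn.label_missing(net, traits=TRAITS)
        assert labeled.outcomes[("Sorbus aria", "greenfinch")] == sn.SEED_PREDATION
        assert labeled.provenance[("Sorbus aria", "greenfinch")] == "inferred"


class TestPrune:
    def test_modes_remove_expected_links(self):
        net = net_from_matrix([[1, 1, 1]], [["D", "P", "S"]])
        assert sn.prune(net, "all_nonmutualistic").pruned.n_links == 1
        assert sn.prune(net, "predation_only").pruned.n_links == 2

    def test_all_dispersal_net_is_identity(self, mixed_net):
        pure = net_from_matrix([[2, 3], [1, 4]])
        res = sn.prune(pure, "all_nonmutualistic")
        assert np.array_equal(res.pruned.weights, pure.weights)
        assert res.dropped_birds == [] and res.dropped_plants == []

    def test_dropped_species_listed(self):
        # B2 is a pure pulp pecker; P2 only interacts with seed predators
        net = net_from_matrix([[2, 3, 0], [0, 0, 4]],
                              [["D", "P", "D"], ["D", "D", "S"]])
        res = sn.prune(net, "all_nonmutualistic")
        assert res.dropped_birds == ["B2", "B3"]
        assert res.dropped_plants == ["P2"]
        # rows/columns are retained with zero totals
        assert res.pruned.weights.shape == net.weights.shape

    def test_original_untouched_and_idempotent(self, mixed_net):
        snapshot = mixed_net.weights.copy()
        once = sn.prune(mixed_net, "all_nonmutualistic").pruned
        assert np.array_equal(mixed_net.weights, snapshot)
        twice = sn.prune(once, "all_nonmutualistic").pruned
        assert np.array_equal(once.weights, twice.weights)

    def test_predation_only_removes_subset(self, mixed_net):
        all_removed = sn.prune(mixed_net, "all_nonmutualistic")
        pred_removed = sn.prune(mixed_net, "predation_only")
        # cells zeroed by predation-only are a subset of those zeroed by all
        zero_all = (all_removed.pruned.weights == 0) & (mixed_net.weights > 0)
        zero_pred = (pred_removed.pruned.weights == 0) & (mixed_net.weights > 0)
        assert np.all(zero_all | ~zero_pred)
        assert pred_removed.removed_links <= all_removed.removed_links

    def test_cellwise_contract(self, mixed_net):
        pruned = sn.prune(mixed_net, "all_nonmutualistic").pruned
        w0, w1 = mixed_net.weights, pruned.weights
        assert np.all((w1 == 0) | (w1 == w0))
        assert w1.sum() <= w0.sum()
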