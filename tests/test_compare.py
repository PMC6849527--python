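"""Paired tests, multiple-test probability and change tables."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import seednet as sn
from seednet.compare import _cv_percent, build_comparison_tables
from seednet.exceptions import UndefinedMetricError

from oracles import brute_wilcoxon_p


class TestWilcoxon:
    def test_five_consistent_decreases(self):
        r = sn.wilcoxon_one_tailed([5, 6, 7, 8, 9], [4, 5, 6, 7, 8], "decrease")
        assert r.p == pytest.approx(1 / 32)

    def test_zero_differences_dropped(self):
        r = sn.wilcoxon_one_tailed([1, 2, 3, 4, 5], [1, 1, 2, 3, 4], "decrease")
        assert r.n == 4
        assert r.p == pytest.approx(1 / 16)

    def test_all_zero_differences_undefined(self):
        with pytest.raises(UndefinedMetricError):
            sn.wilcoxon_one_tailed([1, 2, 3], [1, 2, 3], "decrease")

    def test_antisymmetric_differences_near_half(self):
        before = [0, 0, 0, 0, 0, 0]
        after = [1, -1, 2, -2, 3, -3]
        r = sn.wilcoxon_one_tailed(before, after, "increase")
        assert 0.4 <= r.p <= 0.65

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_matches_sign_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        before = rng.normal(size=n)
        after = before + rng.choice([-2, -1, 1, 2], size=n) * rng.uniform(0.5, 2, n)
        diffs = after - before
        for direction in ("increase", "decrease"):
            r = sn.wilcoxon_one_tailed(before, after, direction)
            assert r.p == pytest.approx(brute_wilcoxon_p(diffs, direction))

    def test_ties_midranked_exact(self):
        before = [0, 0, 0, 0, 0]
        after = [-1, -1, -2, -2, 1]
        r = sn.wilcoxon_one_tailed(before, after, "decrease")
        assert r.p == pytest.approx(brute_wilcoxon_p(np.array(after), "decrease"))

    def test_large_n_normal_approximation_close_to_exact_tail(self):
        rng = np.random.default_rng(1)
        before = rng.normal(size=30)
        after = before - np.abs(rng.normal(size=30))
        r = sn.wilcoxon_one_tailed(before, after, "decrease")
        assert r.p < 1e-4


class TestSpearman:
    def test_perfect_concordance(self):
        r = sn.spearman_one_tailed([1, 2, 3, 4], [10, 20, 30, 40])
        assert r.rho == pytest.approx(1.0)

    def test_perfect_reversal(self):
        r = sn.spearman_one_tailed([1, 2, 3, 4], [4, 3, 2, 1])
        assert r.rho == pytest.approx(-1.0)

    def test_constant_vector_undefined(self):
        with pytest.raises(UndefinedMetricError):
            sn.spearman_one_tailed([1, 1, 1, 1], [1, 2, 3, 4])

    def test_exact_p_matches_full_permutation_enumeration(self):
        from itertools import permutations
        x = [3.0, 1.0, 4.0, 2.0]
        y = [2.5, 0.5, 3.5, 3.0]
        r = sn.spearman_one_tailed(x, y, "increase")
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        rhos = [np.corrcoef(rx, np.array(ry)[list(p)])[0, 1]
                for p in permutations(range(4))]
        expected = np.mean([rr >= r.rho - 1e-12 for rr in rhos])
        assert r.p == pytest.approx(expected)


class TestMoran:
    def test_symmetric_binomial(self):
        assert sn.moran_probability(2, 1, 0.5) == pytest.approx(0.5)

    def test_no_significant_results(self):
        assert sn.moran_probability(6, 0, 0.05) == pytest.approx(0.95**6)

    def test_normalization_over_k(self):
        for n, alpha in [(6, 0.05), (11, 0.2)]:
            total = sum(sn.moran_probability(n, k, alpha) for k in range(n + 1))
            assert total == pytest.approx(1.0)

    def test_invalid_ranges(self):
        with pytest.raises(ValueError):
            sn.moran_probability(3, 4, 0.05)
        with pytest.raises(ValueError):
            sn.moran_probability(3, 1, 1.5)


class TestChangeTables:
    def test_cv_convention_sample_sd(self):
        assert _cv_percent(np.array([2.0, 4.0])) == pytest.approx(47.14, abs=0.01)

    @staticmethod
    def _reports(n_networks=4, effect=-1.0):
        rng = np.random.default_rng(0)
        net_rows, sp_rows = [], []
        for i in range(n_networks):
            nid = f"N{i}"
            for metric in ["size", "weighted_connectance", "wnodf", "h2_prime",
                           "modularity_q", "robustness"]:
                base = rng.uniform(1, 10)
                for state, val in [("original", base),
                                   ("pruned_all", base + effect * rng.uniform(0.5, 1))]:
                    net_rows.append({"network_id": nid, "state": state,
                                     "metric": metric, "value": val})
            for s in range(5):
                for metric, guild in [("degree", "plant"), ("frequency", "plant"),
                                      ("d_prime", "plant"), ("resilience_75", "plant"),
                                      ("strength", "bird")]:
                    base = rng.uniform(1, 5)
                    sp_rows.append({"network_id": nid, "state": "original",
                                    "guild": guild, "species": f"S{s}",
                                    "metric": metric, "value": base})
                    sp_rows.append({"network_id": nid, "state": "pruned_all",
                                    "guild": guild, "species": f"S{s}",
                                    "metric": metric,
                                    "value": base + effect * rng.uniform(0.1, 1)})
        return pd.DataFrame(net_rows), pd.DataFrame(sp_rows)

    def test_schema(self):
        net_df, sp_df = self._reports()
        tables = build_comparison_tables(net_df, sp_df)
        assert len(tables["network_level"]) == 6
        assert len(tables["species_level"]) == 5
        assert set(tables["moran"]["family"]) == {"network_level", "species_level"}
        assert {"mean_abs_change", "mean_pct_change", "cv_pct",
                "wilcoxon_p"} <= set(tables["network_level"].columns)

    def test_identical_states_give_zero_changes_and_undefined_tests(self):
        net_df, sp_df = self._reports(effect=0.0)
        # effect 0 still jitters; build truly identical states instead
        net_df.loc[net_df.state == "pruned_all", "value"] = (
            net_df[net_df.state == "original"]["value"].to_numpy())
        sp_df.loc[sp_df.state == "pruned_all", "value"] = (
            sp_df[sp_df.state == "original"]["value"].to_numpy())
        tables = build_comparison_tables(net_df, sp_df)
        assert np.allclose(tables["network_level"]["mean_abs_change"], 0.0)
        assert tables["network_level"]["wilcoxon_p"].isna().all()

    def test_missing_state_error_names_network(self):
        net_df, sp_df = self._reports()
        net_df = net_df[~((net_df.network_id == "N2") & (net_df.state == "pruned_all"))]
        with pytest.raises(ValueError, match="N2"):
            build_comparison_tables(net_df, sp_df)

    def test_type_one_error_calibration_quick(self):
        # under a true null the one-tailed exact test rejects at <= alpha,
        # close to alpha for n = 20 (fuller calibration in the acceptance suite)
        rng = np.random.default_rng(99)
        rejections = 0
        reps = 300
        for _ in range(reps):
            before = rng.normal(size=20)
            after = before + rng.normal(size=20)
            if sn.wilcoxon_one_tailed(before, after, "decrease").p < 0.05:
                rejections += 1
        rate = rejections / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 3 * se
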