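"""Hypergeometric ORA, BH correction and meta-pathway clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from socionet.enrichment import (
    bh_adjust,
    hypergeom_pvalue,
    meta_pathways,
    overlap_coefficient,
    pathway_ora,
    read_gmt,
    write_gmt,
)

from conftest import enumeration_hypergeom


class TestHypergeomPvalue:
    @pytest.mark.parametrize(
        "k,K,n,N,expected",
        [
            (0, 4, 5, 10, 1.0),
            (3, 4, 5, 10, 66 / 252),
            (6, 6, 6, 6, 1.0),  # degenerate certainty
        ],
    )
    def test_examples(self, k, K, n, N, expected):
        assert hypergeom_pvalue(k, K, n, N) == pytest.approx(expected)

    def test_matches_enumeration_oracle_all_small_universes(self):
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    oracle = enumeration_hypergeom(
                        min(K, n), K, n, N
                    )
                    assert hypergeom_pvalue(
                        min(K, n), K, n, N
                    ) == pytest.approx(oracle, abs=1e-12)
                    mid = min(K, n) // 2
                    oracle_mid = enumeration_hypergeom(mid, K, n, N)
                    assert hypergeom_pvalue(mid, K, n, N) == pytest.approx(
                        oracle_mid, abs=1e-12
                    )

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_pvalue(5, 4, 5, 10)
        with pytest.raises(ValueError):
            hypergeom_pvalue(1, 11, 5, 10)


class TestBHAdjust:
    def test_hand_step_up(self):
        assert np.allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_equal_pvalues_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_output_matches_input_order(self):
        p = [0.04, 0.01, 0.03, 0.02]
        fdr = bh_adjust(p)
        # BH of the sorted values, mapped back: all become 0.04 here
        assert np.allclose(fdr, 0.04)
        p2 = [0.5, 0.001, 0.9]
        fdr2 = bh_adjust(p2)
        assert fdr2[1] == min(fdr2)

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.floats(0, 1, allow_nan=False), min_size=1, max_size=20
        )
    )
    def test_idempotent_monotone(self, pvalues):
        once = bh_adjust(pvalues)
        twice = bh_adjust(once)
        assert np.all(twice >= once - 1e-12)
        assert np.all(once >= np.asarray(pvalues) - 1e-12)


class TestPathwayORA:
    @pytest.fixture()
    def universe(self):
        return {f"u{i}" for i in range(10)}

    def test_size_filter(self, universe):
        genes = sorted(universe)
        big_universe = universe | {f"x{i}" for i in range(300)}
        collection = {
            "too_small": set(genes[:2]),
            "ok": set(genes[:4]),
            "too_big": {f"x{i}" for i in range(201)} | set(genes),
        }
        table = pathway_ora(set(genes[:5]), collection, big_universe)
        assert list(table["name"]) == ["ok"]

    def test_size_filter_applies_after_universe_restriction(self, universe):
        # the 201 out-of-universe members do not count toward the size cap
        genes = sorted(universe)
        collection = {"pw": {f"x{i}" for i in range(201)} | set(genes[:4])}
        table = pathway_ora(set(genes[:5]), collection, universe)
        assert list(table["name"]) == ["pw"]
        assert table.loc[0, "K"] == 4

    def test_toy_pvalue_carried_in_row(self, universe):
        genes = sorted(universe)
        collection = {"pw": set(genes[:4])}
        table = pathway_ora(set(genes[:3]) | {genes[5], genes[6]},
                            collection, universe)
        assert table.loc[0, "p"] == pytest.approx(66 / 252)
        assert table.loc[0, "fdr"] >= table.loc[0, "p"]

    def test_row_count_independent_of_query(self, universe):
        genes = sorted(universe)
        collection = {f"pw{i}": set(genes[i : i + 4]) for i in range(5)}
        t1 = pathway_ora(set(genes[:3]), collection, universe)
        t2 = pathway_ora({genes[9]}, collection, universe)
        assert len(t1) == len(t2)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            pathway_ora({"a"}, {"pw": {"a", "b", "c"}}, set())


class TestGMT:
    def test_round_trip(self, tmp_path):
        sets = {"A": {"g1", "g2", "g3"}, "B": {"g2", "g4", "g5", "g6"}}
        path = tmp_path / "sets.gmt"
        write_gmt(sets, path)
        assert read_gmt(path) == sets

    def test_malformed_and_duplicate_rejected(self, tmp_path):
        bad = tmp_path / "bad.gmt"
        bad.write_text("onlyname\tdesc\n")
        with pytest.raises(ValueError):
            read_gmt(bad)
        dup = tmp_path / "dup.gmt"
        dup.write_text("A\tna\tg1\nA\tna\tg2\n")
        with pytest.raises(ValueError):
            read_gmt(dup)


def _enriched_frame(names):
    return pd.DataFrame(
        {
            "name": names,
            "k": [5] * len(names),
            "fdr": [0.001] * len(names),
        }
    )


class TestMetaPathways:
    def test_overlap_coefficient_example(self):
        a = {"1", "2", "3", "4"}
        b = {"3", "4", "5", "6", "7", "8"}
        assert overlap_coefficient(a, b) == pytest.approx(0.5)

    def test_identical_sets_cluster_together(self):
        sets = {"A": {f"g{i}" for i in range(6)}}
        sets["B"] = set(sets["A"])
        meta = meta_pathways(_enriched_frame(["A", "B"]), sets)
        assert meta.clusters["A"] == meta.clusters["B"]

    def test_disjoint_sets_stay_singletons(self):
        sets = {
            "A": {f"a{i}" for i in range(5)},
            "B": {f"b{i}" for i in range(5)},
            "C": {f"c{i}" for i in range(5)},
        }
        meta = meta_pathways(_enriched_frame(["A", "B", "C"]), sets)
        assert len(set(meta.clusters.values())) == 3

    def test_threshold_sweep_picks_modularity_maximizer(self):
        # two groups of three near-identical pathways; cross-group overlap
        # coefficient 3/11 (~0.27), within-group 10/11 (~0.91): thresholds
        # in (0.27, 0.91) split the graph into two triangles (Q = 0.5) and
        # the smallest such grid point, 0.30, must be selected
        shared = {f"c{i}" for i in range(3)}
        base_a = {f"a{i}" for i in range(7)} | shared
        base_b = {f"b{i}" for i in range(7)} | shared
        sets = {}
        for i in range(3):
            sets[f"A{i}"] = base_a | {f"ua{i}"}
            sets[f"B{i}"] = base_b | {f"ub{i}"}
        meta = meta_pathways(_enriched_frame(sorted(sets)), sets)
        assert meta.threshold == pytest.approx(0.30)
        assert meta.pathway_network_q == pytest.approx(0.5)
        groups = {meta.clusters[f"A{i}"] for i in range(3)}
        assert len(groups) == 1
        assert meta.clusters["B0"] not in groups

    def test_single_eligible_pathway_warns_trivial(self):
        sets = {"A": {"g1", "g2", "g3"}}
        with pytest.warns(UserWarning):
            meta = meta_pathways(_enriched_frame(["A"]), sets)
        assert meta.clusters == {"A": 0}
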