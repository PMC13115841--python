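"""Score recombination, edge retention and adjacency normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.sparse.linalg import eigsh

import socionet as sn
from socionet.interactome import (
    build_interactome,
    channel_columns,
    read_edges,
    read_links,
    recombine_frame,
    recombine_scores,
    write_edges,
)

from conftest import random_er_interactome


class TestRecombineScores:
    @pytest.mark.parametrize(
        "channels,excluded,expected",
        [
            # a single channel at the prior carries no evidence
            ({"experiments": 41}, (), 41),
            # hand-evaluated: s'=0.4786 twice, c=0.7281, t=0.7393
            ({"a": 500, "b": 500}, (), 739),
            # all evidence excluded leaves only the prior
            ({"textmining": 900}, ("textmining",), 41),
            ({}, (), 41),
        ],
    )
    def test_examples(self, channels, excluded, expected):
        assert recombine_scores(channels, excluded, prior=0.041) == expected

    def test_out_of_range_score_rejected(self):
        with pytest.raises(ValueError):
            recombine_scores({"a": 1001})
        with pytest.raises(ValueError):
            recombine_scores({"a": -1})
        with pytest.raises(ValueError):
            recombine_scores({"a": 500}, prior=1.5)

    @settings(max_examples=100, derandomize=True)
    @given(
        base=st.integers(min_value=0, max_value=1000),
        bump=st.integers(min_value=0, max_value=200),
        other=st.integers(min_value=0, max_value=1000),
    )
    def test_monotone_in_each_channel(self, base, bump, other):
        low = recombine_scores({"a": base, "b": other})
        high = recombine_scores({"a": min(1000, base + bump), "b": other})
        assert high >= low


class TestBuildInteractome:
    def test_top_k_medium_per_gene(self):
        # g1 has four medium edges and each partner has three better options
        # elsewhere, so only g1's own top three survive
        edges = [("g1", f"g{i + 2}", 650 - 50 * i) for i in range(4)]
        for partner in ("g2", "g3", "g4", "g5"):
            edges += [(partner, f"{partner}x{j}", 660 + j) for j in range(3)]
        inter = build_interactome(edges)
        g1_edges = {e for e in inter.edges if "g1" in e}
        assert g1_edges == {("g1", "g2"), ("g1", "g3"), ("g1", "g4")}

    def test_union_rule_keeps_partner_top_edges(self):
        # the 500 edge misses g1's top-3 but is g5's best edge, and the
        # either-endpoint rule keeps it
        edges = [
            ("g1", "g2", 650),
            ("g1", "g3", 600),
            ("g1", "g4", 550),
            ("g1", "g5", 500),
        ]
        inter = build_interactome(edges)
        assert ("g1", "g5") in inter.edges

    def test_all_high_confidence_retained(self):
        edges = [(f"a{i}", f"b{i}", 700 + i) for i in range(20)]
        inter = build_interactome(edges, top_k_medium=0)
        assert inter.n_edges == 20

    def test_duplicate_pairs_keep_max_score(self):
        inter = build_interactome(
            [("a", "b", 710), ("b", "a", 930), ("a", "b", 800)]
        )
        assert inter.edges[("a", "b")] == 930

    def test_self_loops_and_unmapped_dropped(self):
        mapping = {"p1": "g1", "p2": "g2", "p3": "g1"}
        inter = build_interactome(
            [("p1", "p3", 900), ("p1", "p2", 800), ("p1", "px", 950)],
            mapping=mapping,
        )
        assert set(inter.edges) == {("g1", "g2")}

    def test_empty_edge_list_gives_empty_interactome(self):
        inter = build_interactome([])
        assert inter.n_genes == 0 and inter.n_edges == 0

    def test_invariant_to_order_and_orientation(self):
        rng = np.random.default_rng(7)
        edges = [
            (f"g{i}", f"g{j}", int(rng.integers(400, 1001)))
            for i in range(12)
            for j in range(i + 1, 12)
            if rng.random() < 0.5
        ]
        ref = build_interactome(edges)
        flipped = [(b, a, s) for a, b, s in edges]
        rng.shuffle(flipped)
        assert build_interactome(flipped).edges == ref.edges

    def test_score_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            build_interactome([("a", "b", 1500)])


class TestNormalizeAdjacency:
    def test_single_edge(self, two_node_interactome):
        W = sn.normalize_adjacency(two_node_interactome).toarray()
        assert np.allclose(W, [[0, 1], [1, 0]])

    def test_path_graph(self):
        inter = sn.Interactome(
            genes=("a", "b", "c"), edges={("a", "b"): 900, ("b", "c"): 900}
        )
        W = sn.normalize_adjacency(inter).toarray()
        assert W[0, 1] == pytest.approx(1 / np.sqrt(2))
        assert W[1, 2] == pytest.approx(1 / np.sqrt(2))
        assert W[0, 2] == 0

    def test_isolated_node_row_is_zero(self):
        inter = sn.Interactome(
            genes=("a", "b", "iso"), edges={("a", "b"): 900}
        )
        W = sn.normalize_adjacency(inter).toarray()
        i = inter.index("iso")
        assert not W[i].any() and not W[:, i].any()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("weighting", ["binary", "score"])
    def test_symmetric_with_bounded_spectrum(self, seed, weighting):
        inter = random_er_interactome(40, 0.1, seed)
        W = sn.normalize_adjacency(inter, weighting=weighting)
        dense = W.toarray()
        assert np.max(np.abs(dense - dense.T)) < 1e-12
        top = eigsh(W, k=1, return_eigenvectors=False, which="LM")
        assert abs(top[0]) <= 1 + 1e-9


class TestIO:
    def test_edge_tsv_round_trip(self, tmp_path):
        inter = random_er_interactome(15, 0.3, 3)
        path = tmp_path / "edges.tsv"
        write_edges(inter, path)
        back = read_edges(path)
        assert back.edges == inter.edges
        # genes are inferred from the edge list, so isolated genes vanish
        connected = tuple(sorted({g for pair in inter.edges for g in pair}))
        assert back.genes == connected

    def test_malformed_edge_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("a\tb\t900\nc\tonly_two\n")
        with pytest.raises(ValueError, match=":2"):
            read_edges(path)

    def test_read_links_gzip_and_channels(self, tmp_path, default_benchmark):
        import gzip

        plain = tmp_path / "links.tsv"
        default_benchmark.links.to_csv(plain, sep="\t", index=False)
        zipped = tmp_path / "links.tsv.gz"
        with gzip.open(zipped, "wt") as fh:
            default_benchmark.links.to_csv(fh, sep="\t", index=False)
        a = read_links(plain)
        b = read_links(zipped)
        pd.testing.assert_frame_equal(a, b)
        assert "textmining" in channel_columns(a)
        assert "combined_score" not in channel_columns(a)

    def test_recombine_frame_matches_scalar(self, default_benchmark):
        df = recombine_frame(default_benchmark.links, ("textmining",))
        chans = channel_columns(default_benchmark.links)
        row = default_benchmark.links.iloc[17]
        expected = recombine_scores(
            {c: int(row[c]) for c in chans}, ("textmining",)
        )
        assert int(df.iloc[17]["score"]) == expected
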