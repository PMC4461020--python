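"""Motif enumeration, classification, census, null model, significance."""

from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from mirdisnet import (
    GraphValidationError,
    MotifClass,
    build_graph,
    census,
    classify,
    enumerate_subgraphs,
    motif_prioritize,
    project_diseases,
    randomize,
    significance,
)
from mirdisnet.synth import er_bipartite, scale_free_bipartite, SynthConfig

from conftest import edge


def brute_force_census(g: nx.Graph):
    """Independent oracle: test every 3-/4-node subset for connectivity and
    classify by hand-rolled degree-sequence rules."""
    counts = {}
    nodes = sorted(g.nodes)
    for k in (3, 4):
        for subset in combinations(nodes, k):
            sub = g.subgraph(subset)
            if not nx.is_connected(sub):
                continue
            degs = tuple(sorted(d for _, d in sub.degree()))
            e = sub.number_of_edges()
            if k == 3:
                cls = MotifClass.PATH3 if e == 2 else MotifClass.TRIANGLE
            elif degs == (1, 1, 2, 2) and e == 3:
                cls = MotifClass.PATH4
            elif degs == (1, 1, 1, 3):
                cls = MotifClass.STAR4
            elif degs == (2, 2, 2, 2) and e == 4:
                cls = MotifClass.CYCLE4
            else:
                cls = MotifClass.OTHER
            counts[cls] = counts.get(cls, 0) + 1
    return counts


class TestEnumerate:
    def test_star_triples(self, star_graph):
        assert enumerate_subgraphs(star_graph, 3) == [
            ("d1", "d2", "m1"),
            ("d1", "d3", "m1"),
            ("d2", "d3", "m1"),
        ]

    def test_four_cycle_single_quad(self, four_cycle):
        assert enumerate_subgraphs(four_cycle, 4) == [("d1", "d2", "m1", "m2")]

    def test_edgeless_graph_empty(self):
        g = nx.empty_graph(5)
        assert enumerate_subgraphs(g, 3) == []

    def test_unsupported_size_rejected(self, star_graph):
        with pytest.raises(GraphValidationError):
            enumerate_subgraphs(star_graph, 5)

    @pytest.mark.parametrize("seed", range(10))
    def test_each_connected_set_exactly_once(self, seed):
        g = er_bipartite(5, 5, 0.4, seed=seed).to_networkx()
        for k in (3, 4):
            found = enumerate_subgraphs(g, k)
            assert len(found) == len(set(found))
            expected = {
                tuple(sorted(s))
                for s in combinations(sorted(g.nodes), k)
                if nx.is_connected(g.subgraph(s))
            }
            assert set(found) == expected


class TestClassify:
    def test_mirna_regulating_two_diseases_is_path(self, star_graph):
        assert classify(star_graph, {"m1", "d1", "d2"}) is MotifClass.PATH3

    def test_square(self, four_cycle):
        assert classify(four_cycle, {"m1", "m2", "d1", "d2"}) is MotifClass.CYCLE4

    def test_three_star(self, star_graph):
        assert classify(star_graph, {"m1", "d1", "d2", "d3"}) is MotifClass.STAR4

    def test_triangle_in_projection(self, star_graph):
        proj = project_diseases(star_graph)
        assert classify(proj, {"d1", "d2", "d3"}) is MotifClass.TRIANGLE

    def test_disconnected_input_rejected(self):
        g = build_graph([edge("m1", "d1", 1), edge("m2", "d2", 1)])
        with pytest.raises(GraphValidationError):
            classify(g, {"m1", "d1", "m2"})


class TestCensus:
    def test_star_counts_and_participation(self, star_graph):
        c = census(star_graph)
        assert c.counts[MotifClass.PATH3] == 3
        assert c.counts[MotifClass.STAR4] == 1
        assert c.counts[MotifClass.PATH4] == 0
        assert c.counts[MotifClass.CYCLE4] == 0
        assert c.participation_of("d1", MotifClass.PATH3) == 2
        assert c.participation_of("m1", MotifClass.PATH3) == 3

    def test_four_cycle_counts(self, four_cycle):
        c = census(four_cycle)
        assert c.counts[MotifClass.PATH3] == 4
        assert c.counts[MotifClass.CYCLE4] == 1
        assert c.counts[MotifClass.PATH4] == 0
        assert c.counts[MotifClass.STAR4] == 0

    def test_single_edge_no_motifs(self, single_edge):
        c = census(single_edge)
        assert all(v == 0 for v in c.counts.values())

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_all_subsets_oracle(self, seed):
        g = er_bipartite(6, 6, 0.35, seed=seed)
        c = census(g)
        oracle = brute_force_census(g.to_networkx())
        for cls in (
            MotifClass.PATH3,
            MotifClass.PATH4,
            MotifClass.STAR4,
            MotifClass.CYCLE4,
        ):
            assert c.counts[cls] == oracle.get(cls, 0)

    @pytest.mark.parametrize("seed", range(10))
    def test_participation_identity(self, seed):
        g = er_bipartite(6, 6, 0.35, seed=seed)
        c = census(g)
        for cls, count in c.counts.items():
            total = sum(
                v for (node, k), v in c.participation.items() if k is cls
            )
            assert total == cls.node_count * count

    def test_relabeling_invariance(self):
        g = er_bipartite(5, 5, 0.4, seed=3)
        mapping = {n: f"x_{n}" for n in g.mirna_ids | g.disease_ids}
        h = nx.relabel_nodes(g.to_networkx(), mapping)
        assert census(g).counts == census(h).counts


class TestRandomize:
    @pytest.mark.parametrize("seed", range(10))
    def test_degrees_bipartiteness_simplicity_preserved(self, seed):
        g = er_bipartite(8, 8, 0.4, seed=seed)
        r = randomize(g, swap_factor=10, seed=seed)
        assert dict(g.to_networkx().degree()) == dict(r.to_networkx().degree())
        assert r.mirna_ids == g.mirna_ids and r.disease_ids == g.disease_ids
        assert r.n_edges == g.n_edges  # simple: no parallel edges created
        r.validate()

    def test_zero_swaps_identity(self, worked_example):
        r = randomize(worked_example, swap_factor=0, seed=1)
        assert set(r.edges) == set(worked_example.edges)

    def test_k22_is_invariant(self, four_cycle):
        r = randomize(four_cycle, swap_factor=50, seed=2)
        assert set(r.edges) == set(four_cycle.edges)

    def test_too_few_edges_rejected(self, single_edge):
        with pytest.raises(GraphValidationError):
            randomize(single_edge, swap_factor=10, seed=0)


class TestSignificance:
    def test_k22_degenerate_ensemble(self, four_cycle):
        result = significance(four_cycle, ensemble_size=10, swap_factor=10, seed=1)
        stats = result.ensemble_stats[MotifClass.CYCLE4]
        assert stats.random_std == 0.0
        assert stats.z_score is None
        assert stats.empirical_p == 1.0

    def test_bit_reproducible_from_seed(self):
        g = er_bipartite(8, 8, 0.35, seed=4)
        a = significance(g, ensemble_size=8, swap_factor=5, seed=99)
        b = significance(g, ensemble_size=8, swap_factor=5, seed=99)
        for cls in a.ensemble_stats:
            sa, sb = a.ensemble_stats[cls], b.ensemble_stats[cls]
            assert (sa.random_mean, sa.random_std, sa.z_score, sa.empirical_p) == (
                sb.random_mean,
                sb.random_std,
                sb.z_score,
                sb.empirical_p,
            )

    def test_heavy_tail_inflates_path3(self):
        g = scale_free_bipartite(SynthConfig(60, 60, 2, seed=12))
        result = significance(g, ensemble_size=12, swap_factor=3, seed=7)
        stats = result.ensemble_stats[MotifClass.PATH3]
        # degree-preserving swaps keep the 2-path count (it depends only on
        # degrees), so the real graph cannot be under-represented
        assert stats.z_score is None or stats.z_score >= 0
        assert stats.real_count >= stats.random_mean

    def test_small_ensemble_rejected(self, four_cycle):
        with pytest.raises(GraphValidationError):
            significance(four_cycle, ensemble_size=1, seed=0)

    def test_report_dataframe_layout(self, four_cycle):
        result = significance(four_cycle, ensemble_size=4, swap_factor=2, seed=0)
        frame = result.to_dataframe()
        assert list(frame.columns) == [
            "class",
            "real_count",
            "random_mean",
            "random_std",
            "z_score",
            "empirical_p",
            "uniqueness",
            "significant",
        ]
        assert set(frame["class"]) == {"path3", "path4", "star4", "cycle4"}


class TestMotifPrioritize:
    def test_star_leaves_tie(self, star_graph):
        result = motif_prioritize(star_graph, {"m1"}, classes=[MotifClass.PATH3])
        assert result == [("d1", 2), ("d2", 2), ("d3", 2)]

    def test_single_edge_no_motifs(self, single_edge):
        assert motif_prioritize(single_edge, {"m1"}) == []

    def test_square_participation(self, four_cycle):
        result = motif_prioritize(
            four_cycle, {"m1", "m2"}, classes=[MotifClass.CYCLE4]
        )
        assert result == [("d1", 1), ("d2", 1)]

    def test_restricted_to_query_subnetwork(self, worked_example):
        # query {m3} sees only d3, d4 -> one path3 through m3
        result = motif_prioritize(worked_example, {"m3"})
        assert result == [("d3", 1), ("d4", 1)]
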