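"""PPI distance permutation test, clustering and enrichment."""

import itertools

import networkx as nx
import numpy as np
import pytest

from translatome.network import (
    MarkedGraph,
    degree_preserving_randomize,
    empirical_pvalue,
    induced_de_subgraph,
    load_ppi,
    mean_marked_distance,
    newman_cluster,
    pathway_enrichment,
    read_gmt,
    write_gmt,
)
from translatome.synthetic import generate_ppi


class TestLoadPpi:
    def test_dedup_selfloop_and_main_component(self, tmp_path):
        p = tmp_path / "edges.tsv"
        p.write_text("a\tb\nb\ta\na\ta\nc\td\nd\te\nc\te\n")
        mg = load_ppi(p)
        # the 3-node component {c,d,e} beats the single edge {a,b}
        assert set(mg.graph.nodes) == {"c", "d", "e"}
        assert mg.graph.number_of_edges() == 3

    def test_pairs_input_and_marked_restriction(self):
        mg = load_ppi([("a", "b"), ("b", "c")], marked={"a", "zzz"})
        assert mg.marked == {"a"}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            load_ppi([])

    def test_generator_output_round_trips(self, tmp_path):
        from translatome.synthetic import write_edge_list

        g, _ = generate_ppi(300, seed=1)
        p = tmp_path / "ppi.tsv"
        write_edge_list(g, p)
        mg = load_ppi(p)
        assert set(mg.graph.nodes) == set(g.nodes)
        assert mg.graph.number_of_edges() == g.number_of_edges()


class TestMeanMarkedDistance:
    def test_adjacent_pair(self):
        g = nx.Graph([("a", "b")])
        assert mean_marked_distance(MarkedGraph(g, {"a", "b"})) == 1.0

    def test_path_endpoints(self):
        g = nx.path_graph(["a", "b", "c"])
        assert mean_marked_distance(MarkedGraph(g, {"a", "c"})) == 2.0

    def test_single_marked_node_rejected(self):
        g = nx.path_graph(3)
        with pytest.raises(ValueError):
            mean_marked_distance(MarkedGraph(g, {0}))

    def test_matches_bruteforce_bfs_on_random_graphs(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            g = nx.gnp_random_graph(int(rng.integers(8, 30)), 0.25, seed=int(rng.integers(1e6)))
            comp = max(nx.connected_components(g), key=len)
            if len(comp) < 4:
                continue
            marked = set(rng.choice(sorted(comp), size=4, replace=False))
            expected = np.mean(
                [
                    nx.shortest_path_length(g, a, b)
                    for a, b in itertools.combinations(sorted(marked), 2)
                ]
            )
            got = mean_marked_distance(MarkedGraph(g.subgraph(comp).copy(), marked))
            assert got == pytest.approx(expected)


class TestRandomize:
    def test_degree_sequence_exactly_preserved(self):
        g, _ = generate_ppi(300, seed=2)
        r = degree_preserving_randomize(g, seed=3)
        assert sorted(d for _, d in r.degree) == sorted(d for _, d in g.degree)
        assert not list(nx.selfloop_edges(r))

    def test_triangle_unchanged_with_warning(self):
        g = nx.complete_graph(3)
        with pytest.warns(UserWarning):
            r = degree_preserving_randomize(g, seed=0)
        assert set(map(frozenset, r.edges)) == set(map(frozenset, g.edges))

    def test_seed_determinism(self):
        g, _ = generate_ppi(200, seed=4)
        e1 = set(map(frozenset, degree_preserving_randomize(g, seed=7).edges))
        e2 = set(map(frozenset, degree_preserving_randomize(g, seed=7).edges))
        assert e1 == e2


class TestEmpiricalPvalue:
    def test_planted_module_detected_at_floor(self):
        g, truth = generate_ppi(500, planted_module_sizes=(30,), seed=5)
        nd = empirical_pvalue(MarkedGraph(g, truth.planted_modules[0]), 100, seed=5)
        assert nd.p == pytest.approx(1 / 101)
        assert nd.p < 1e-2
        assert len(nd.null_values) == 100
        assert nd.observed < nd.null_values.min()

    def test_determinism(self):
        g, truth = generate_ppi(300, planted_module_sizes=(15,), seed=6)
        mg = MarkedGraph(g, truth.planted_modules[0])
        n1 = empirical_pvalue(mg, 20, seed=9)
        n2 = empirical_pvalue(mg, 20, seed=9)
        assert np.array_equal(n1.null_values, n2.null_values)


class TestInducedSubgraph:
    def test_neighbourless_members_dropped(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("c", "d")])
        sub = induced_de_subgraph(g, {"a", "b", "d"})
        assert set(sub.nodes) == {"a", "b"}

    def test_no_internal_edges_gives_empty(self):
        g = nx.Graph([("a", "b"), ("b", "c")])
        with pytest.warns(UserWarning):
            sub = induced_de_subgraph(g, {"a", "c"})
        assert sub.number_of_nodes() == 0

    def test_kept_count_bounded(self):
        g, _ = generate_ppi(200, seed=7)
        rng = np.random.default_rng(0)
        group = set(rng.choice(sorted(g.nodes), 50, replace=False))
        assert induced_de_subgraph(g, group).number_of_nodes() <= len(group)


def _brute_force_best_bipartition_q(g):
    nodes = sorted(g.nodes)
    best = 0.0  # the one-community partition has Q = 0 baseline
    for r in range(1, len(nodes) // 2 + 1):
        for left in itertools.combinations(nodes, r):
            part = [set(left), set(nodes) - set(left)]
            best = max(best, nx.community.modularity(g, part))
    return best


class TestNewman:
    def test_two_cliques_split_cleanly(self):
        g = nx.disjoint_union(nx.complete_graph(6), nx.complete_graph(6))
        g.add_edge(0, 6)
        part = newman_cluster(g)
        assert sorted(map(sorted, part.as_sets())) == [list(range(6)), list(range(6, 12))]

    def test_single_clique_one_community(self):
        part = newman_cluster(nx.complete_graph(7))
        assert len(part.as_sets()) == 1
        assert part.modularity == pytest.approx(0.0)

    def test_q_never_below_baseline(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            g = nx.gnp_random_graph(15, 0.3, seed=int(rng.integers(1e6)))
            if g.number_of_edges() == 0:
                continue
            assert newman_cluster(g).modularity >= -1e-12

    def test_matches_bruteforce_bipartition_on_planted_graphs(self):
        # planted two-block graphs <= 12 nodes where one bisection is optimal
        for seed in range(5):
            g = nx.planted_partition_graph(2, 6, 0.95, 0.05, seed=seed)
            g = nx.Graph(g)
            if not nx.is_connected(g):
                continue
            part = newman_cluster(g)
            if len(part.as_sets()) == 2:
                assert part.modularity == pytest.approx(
                    _brute_force_best_bipartition_q(g), abs=1e-9
                )

    def test_isolated_nodes_own_communities(self):
        g = nx.Graph()
        g.add_nodes_from(["a", "b"])
        part = newman_cluster(g)
        assert len(part.as_sets()) == 2

    def test_module_size_threshold(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(2))
        part = newman_cluster(g)
        assert len(part.modules(min_size=3)) == 1


class TestEnrichment:
    def test_small_pathways_excluded(self):
        universe = {f"g{i}" for i in range(20)}
        paths = {"small": {f"g{i}" for i in range(6)}, "big": {f"g{i}" for i in range(7)}}
        out = pathway_enrichment({"g0"}, paths, universe)
        assert list(out["pathway"]) == ["big"]

    def test_closed_form_complete_overlap(self):
        universe = {f"g{i}" for i in range(10)}
        hit = {f"g{i}" for i in range(5)}
        out = pathway_enrichment(hit, {"p": hit, "pad": universe}, universe, min_pathway=5)
        p = out.set_index("pathway").loc["p", "p"]
        assert p == pytest.approx(1 / 252)

    def test_zero_overlap_p_one(self):
        universe = {f"g{i}" for i in range(30)}
        path = {f"g{i}" for i in range(7)}
        out = pathway_enrichment({f"g{i}" for i in range(20, 25)}, {"p": path}, universe)
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            pathway_enrichment({"a"}, {"p": {"a"}}, set())

    def test_gmt_roundtrip(self, tmp_path):
        paths = {"p1": {"a", "b", "c"}, "p2": {"d", "e"}}
        f = tmp_path / "sets.gmt"
        write_gmt(paths, f)
        assert read_gmt(f) == paths
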