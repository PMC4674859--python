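import math
import random

import pytest

from pathevents.events import make_pair
from pathevents.fixtures import expected_network
from pathevents.network import (
    InteractionNetwork,
    add_curated_edges,
    build_network,
    compute_stats,
    rank_bottlenecks,
    rank_hubs,
    write_stats_tsv,
)
from pathevents.standoff import EventType, PathwayDB, PathwayRecord, UsageError

from .oracles import (
    brute_betweenness,
    brute_clustering,
    brute_components,
    brute_path_stats,
    random_graph,
)


def _net_from_edges(edges):
    net = InteractionNetwork()
    for e in edges:
        a, b = tuple(e)
        net.add_edge(a, b, relation="binding", origin="TEXT_MINED")
    return net


def _net_with_nodes(nodes, edges):
    net = _net_from_edges(edges)
    for n in nodes:
        net.add_node(n)
    return net


class TestBuild:
    def test_nodes_are_exactly_pair_endpoints(self):
        pair = make_pair(
            ("GENE", "uPAR"),
            ("PATHWAY", "FAK/PI3K/Akt signaling"),
            EventType.NEGATIVE_REGULATION,
        )
        net = build_network({pair})
        assert net.node_count == 2 and net.edge_count == 1
        assert net.edge_triples()[0][2] == "neg_reg"

    def test_empty_pair_set(self):
        net = build_network(set())
        assert net.node_count == 0 and net.edge_count == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_node_set_equals_union_of_endpoints(self, seed):
        rng = random.Random(seed)
        pairs = set()
        for _ in range(rng.randrange(1, 15)):
            a, b = rng.sample(range(10), 2)
            pairs.add(make_pair(("GENE", a), ("GENE", b), EventType.BINDING))
        net = build_network(pairs)
        assert net.nodes() == {n for p in pairs for n in p.nodes}

    def test_self_loop_rejected(self):
        net = InteractionNetwork()
        with pytest.raises(UsageError):
            net.add_edge(("GENE", 1), ("GENE", 1), relation="reg", origin="TEXT_MINED")

    def test_member_of_must_link_gene_and_pathway(self):
        net = InteractionNetwork()
        with pytest.raises(UsageError):
            net.add_edge(("GENE", 1), ("GENE", 2), relation="member_of", origin="CURATED")


class TestCuratedEdges:
    DB = PathwayDB(
        {
            "pi3k": PathwayRecord(
                "pi3k",
                "PI3K/Akt pathway",
                frozenset({("KEGG", "PI3K-Akt signaling pathway")}),
                frozenset({207, 5979}),
            )
        }
    )

    def test_membership_edge_added_for_co_present_nodes(self):
        pair = make_pair(("GENE", 207), ("PATHWAY", "pi3k"), EventType.POSITIVE_REGULATION)
        net = add_curated_edges(build_network({pair}), self.DB)
        assert net.edge_count == 2
        assert net.has_member_of_edge(("GENE", 207), ("PATHWAY", "pi3k"))

    def test_no_co_presence_leaves_network_unchanged(self):
        pair = make_pair(("GENE", 1), ("GENE", 2), EventType.BINDING)
        net = build_network({pair})
        out = add_curated_edges(net, self.DB)
        assert out == net

    def test_default_never_adds_nodes(self):
        pair = make_pair(("GENE", 7157), ("PATHWAY", "pi3k"), EventType.REGULATION)
        out = add_curated_edges(build_network({pair}), self.DB)
        assert out.nodes() == {("GENE", 7157), ("PATHWAY", "pi3k")}

    def test_expand_members_adds_member_genes(self):
        pair = make_pair(("GENE", 7157), ("PATHWAY", "pi3k"), EventType.REGULATION)
        out = add_curated_edges(build_network({pair}), self.DB, expand_members=True)
        assert ("GENE", 207) in out.nodes() and ("GENE", 5979) in out.nodes()
        assert out.has_member_of_edge(("GENE", 207), ("PATHWAY", "pi3k"))

    def test_idempotent(self):
        pair = make_pair(("GENE", 207), ("PATHWAY", "pi3k"), EventType.REGULATION)
        once = add_curated_edges(build_network({pair}), self.DB)
        assert add_curated_edges(once, self.DB) == once

    @pytest.mark.parametrize("seed", range(5))
    def test_edge_increase_matches_double_loop_count(self, seed):
        rng = random.Random(seed)
        genes = list(range(1, 9))
        records = {}
        for i in range(4):
            cid = f"p{i}"
            records[cid] = PathwayRecord(
                cid,
                cid,
                frozenset(),
                frozenset(g for g in genes if rng.random() < 0.4),
            )
        db = PathwayDB(records)
        pairs = set()
        for _ in range(8):
            g = rng.choice(genes)
            p = rng.choice(list(records))
            try:
                pairs.add(make_pair(("GENE", g), ("PATHWAY", p), EventType.REGULATION))
            except Exception:
                pass
        net = build_network(pairs)
        out = add_curated_edges(net, db)
        expected_new = sum(
            1
            for g in net.nodes()
            if g[0] == "GENE"
            for p in net.nodes()
            if p[0] == "PATHWAY" and g[1] in records[p[1]].members
        )
        assert out.edge_count - net.edge_count == expected_new


class TestStats:
    def test_triangle(self):
        nodes = [("GENE", i) for i in range(3)]
        net = _net_from_edges(
            {frozenset((nodes[0], nodes[1])), frozenset((nodes[1], nodes[2])), frozenset((nodes[0], nodes[2]))}
        )
        st = compute_stats(net)
        assert st.clustering_coefficient == 1.0
        assert st.connected_components == 1
        assert st.diameter == 1
        assert st.density == 1.0

    def test_three_node_path(self):
        a, b, c = (("GENE", i) for i in range(3))
        net = _net_from_edges({frozenset((a, b)), frozenset((b, c))})
        st = compute_stats(net)
        assert st.characteristic_path_length == pytest.approx(4 / 3)
        assert st.diameter == 2
        assert st.clustering_coefficient == 0.0

    def test_edgeless_network_has_undefined_path_stats(self):
        net = _net_with_nodes([("GENE", 1), ("GENE", 2)], set())
        st = compute_stats(net)
        assert st.diameter is None and st.characteristic_path_length is None
        assert st.connected_components == 2

    def test_multi_edge_pairs_counted_but_paths_use_simple_graph(self):
        a, b = ("GENE", 1), ("PATHWAY", "p")
        net = InteractionNetwork()
        net.add_edge(a, b, relation="pos_reg", origin="TEXT_MINED")
        net.add_edge(a, b, relation="member_of", origin="CURATED")
        st = compute_stats(net)
        assert st.multi_edge_node_pairs == 1
        assert st.edge_count == 2
        assert st.diameter == 1
        assert st.avg_neighbors == 1.0

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_bruteforce_oracles_on_random_graphs(self, seed):
        rng = random.Random(seed)
        nodes, edges = random_graph(rng)
        net = _net_with_nodes(nodes, edges)
        st = compute_stats(net)
        assert st.clustering_coefficient == pytest.approx(brute_clustering(nodes, edges))
        assert st.connected_components == brute_components(nodes, edges)
        diam, cpl = brute_path_stats(nodes, edges)
        assert st.diameter == diam
        if cpl is None:
            assert st.characteristic_path_length is None
        else:
            assert st.characteristic_path_length == pytest.approx(cpl)
        deg_sum = sum(
            1 for e in edges for _ in range(2)
        )
        assert st.avg_neighbors == pytest.approx(deg_sum / len(nodes))
        if len(nodes) > 1:
            assert st.density == pytest.approx(st.avg_neighbors / (len(nodes) - 1))
        assert 0.0 <= st.clustering_coefficient <= 1.0
        assert 1 <= st.connected_components <= len(nodes)
        if st.diameter is not None:
            assert st.diameter >= st.characteristic_path_length

    def test_stats_tsv_roundtrippable_text(self, tmp_path):
        net = _net_from_edges({frozenset((("GENE", 1), ("GENE", 2)))})
        write_stats_tsv(compute_stats(net), tmp_path / "s.tsv")
        content = (tmp_path / "s.tsv").read_text()
        assert "Clustering coefficient\t0\n" in content
        assert content.startswith("Nodes\t2\n")


class TestHubs:
    def test_star_center(self):
        center = ("GENE", 0)
        net = _net_from_edges({frozenset((center, ("GENE", i))) for i in range(1, 4)})
        [top] = rank_hubs(net, 1)
        assert top.node == center and top.score == 3 and top.rank == 1

    def test_degree_counts_edge_multiplicity(self):
        a, b = ("GENE", 1), ("PATHWAY", "p")
        net = InteractionNetwork()
        net.add_edge(a, b, relation="pos_reg", origin="TEXT_MINED")
        net.add_edge(a, b, relation="member_of", origin="CURATED")
        net.add_edge(a, ("GENE", 2), relation="binding", origin="TEXT_MINED")
        assert rank_hubs(net, 1)[0].node == a
        assert rank_hubs(net, 1)[0].score == 3

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_full_sort_oracle(self, seed):
        rng = random.Random(seed)
        nodes, edges = random_graph(rng)
        net = _net_with_nodes(nodes, edges)
        got = rank_hubs(net, len(nodes))
        deg = {n: 0 for n in nodes}
        for e in edges:
            a, b = tuple(e)
            deg[a] += 1
            deg[b] += 1
        expected = sorted(deg.items(), key=lambda kv: (-kv[1], str(kv[0][1])))
        assert [(r.node, r.score) for r in got] == [(n, float(d)) for n, d in expected]
        # scores non-increasing with rank
        assert all(x.score >= y.score for x, y in zip(got, got[1:]))


class TestBottlenecks:
    def test_middle_of_path_has_betweenness_one(self):
        a, b, c = (("GENE", i) for i in range(3))
        net = _net_from_edges({frozenset((a, b)), frozenset((b, c))})
        ranked = rank_bottlenecks(net, 3)
        assert ranked[0].node == b and ranked[0].score == pytest.approx(1.0)
        assert all(r.score == 0.0 for r in ranked[1:])

    def test_single_node_scores_zero(self):
        net = _net_with_nodes([("GENE", 1)], set())
        [r] = rank_bottlenecks(net, 1)
        assert r.score == 0.0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_path_enumeration_oracle(self, seed):
        rng = random.Random(seed)
        nodes, edges = random_graph(rng)
        net = _net_with_nodes(nodes, edges)
        ranked = rank_bottlenecks(net, len(nodes))
        oracle = brute_betweenness(nodes, edges)
        got = {r.node: r.score for r in ranked}
        for n in nodes:
            assert got[n] == pytest.approx(oracle[n], abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_tree_identities(self, seed):
        # On a tree every pair has a unique shortest path, so leaves have
        # betweenness 0 and the total betweenness equals the number of
        # intermediate-node visits: sum of (d - 1) over unordered pairs
        # at distance d >= 2.
        rng = random.Random(seed)
        n = rng.randrange(3, 9)
        nodes = [("GENE", i) for i in range(n)]
        edges = {frozenset((nodes[i], nodes[rng.randrange(0, i)])) for i in range(1, n)}
        net = _net_with_nodes(nodes, edges)
        ranked = {r.node: r.score for r in rank_bottlenecks(net, n)}
        deg = {m: 0 for m in nodes}
        for e in edges:
            a, b = tuple(e)
            deg[a] += 1
            deg[b] += 1
        for m, d in deg.items():
            if d == 1:
                assert ranked[m] == 0.0
        from .oracles import floyd_warshall

        dist = floyd_warshall(nodes, edges)
        intermediate_visits = sum(
            dist[(a, b)] - 1
            for i, a in enumerate(nodes)
            for b in nodes[i + 1:]
            if 2 <= dist[(a, b)] < math.inf
        )
        assert sum(ranked.values()) == pytest.approx(intermediate_visits)


class TestFixtureOracleAgreement:
    @pytest.mark.parametrize("seed", range(10))
    def test_expected_network_agrees_with_builder(self, seed):
        from pathevents.fixtures import FixtureConfig, generate_corpus

        corpus = generate_corpus(FixtureConfig(n_docs=10, seed=seed, n_genes=8, n_pathways=3))
        built = add_curated_edges(
            build_network(corpus.ground_truth.planted_pairs), corpus.pathway_db
        )
        assert built == expected_network(corpus.ground_truth, corpus.pathway_db)
        built_x = add_curated_edges(
            build_network(corpus.ground_truth.planted_pairs),
            corpus.pathway_db,
            expand_members=True,
        )
        assert built_x == expected_network(
            corpus.ground_truth, corpus.pathway_db, expand_members=True
        )
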