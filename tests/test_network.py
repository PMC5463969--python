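from fractions import Fraction

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from omicshub import network as net

from oracles import graph_centralities


def _edges(rows):
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "score"])


def _random_graph(rng, n=30, p=0.12):
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))
    return nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})


class TestBuildDegNetwork:
    def test_score_boundary_inclusive_and_induction(self):
        degs = {"a", "b", "c"}
        edges = _edges([
            ("a", "b", 0.4),   # boundary score kept
            ("a", "c", 0.39),  # below threshold
            ("a", "x", 0.9),   # non-DEG endpoint
            ("b", "b", 0.9),   # self loop
            ("a", "b", 0.8),   # duplicate
        ])
        g = net.build_deg_network(edges, degs)
        assert set(g.edges) == {("a", "b")}
        assert g["a"]["b"]["score"] == pytest.approx(0.4)

    def test_random_edges_match_bruteforce_filtering(self):
        rng = np.random.default_rng(31)
        nodes = [f"n{i}" for i in range(40)]
        degs = set(rng.choice(nodes, 25, replace=False))
        rows = []
        for _ in range(300):
            a, b = rng.choice(nodes, 2, replace=False)
            rows.append((a, b, float(rng.uniform(0, 1))))
        g = net.build_deg_network(_edges(rows), degs, score_min=0.5)
        expected = set()
        for a, b, s in rows:
            if a != b and s >= 0.5 and a in degs and b in degs:
                expected.add(frozenset((a, b)))
        assert {frozenset(e) for e in g.edges} == expected

    def test_degree_sum_is_twice_edge_count(self, small_cohort):
        truth = small_cohort.truth
        degs = truth.de_genes_up | truth.de_genes_down
        g = net.build_deg_network(small_cohort.ppi_edges, degs)
        assert sum(d for _, d in g.degree()) == 2 * g.number_of_edges()


class TestExtractSubnetwork:
    def test_star_center_seed_recovers_star(self):
        g = nx.star_graph(4)
        sub = net.extract_subnetwork(g, {0})
        assert set(sub.nodes) == set(g.nodes) and set(sub.edges) == set(g.edges)

    def test_path_end_seed_takes_one_neighbor(self):
        g = nx.path_graph(["a", "b", "c"])
        sub = net.extract_subnetwork(g, {"a"})
        assert set(sub.nodes) == {"a", "b"} and set(sub.edges) == {("a", "b")}

    def test_missing_seeds_warn_empty(self, caplog):
        g = nx.path_graph(3)
        sub = net.extract_subnetwork(g, {"zz"})
        assert sub.number_of_nodes() == 0

    def test_matches_breadth_one_expansion_and_idempotence(self):
        rng = np.random.default_rng(32)
        for _ in range(10):
            g = _random_graph(rng)
            seeds = set(rng.choice(sorted(g.nodes), 5, replace=False))
            sub = net.extract_subnetwork(g, seeds)
            expected_nodes = set(seeds) & set(g.nodes)
            for s in list(expected_nodes):
                expected_nodes |= set(g.neighbors(s))
            assert set(sub.nodes) == expected_nodes
            expected_edges = {frozenset(e) for e in g.edges
                              if e[0] in expected_nodes and e[1] in expected_nodes}
            assert {frozenset(e) for e in sub.edges} == expected_edges
            again = net.extract_subnetwork(sub, set(sub.nodes))
            assert set(again.nodes) == set(sub.nodes) and set(again.edges) == set(sub.edges)


class TestCentralities:
    def test_five_node_star_hand_enumeration(self):
        table = net.centralities(nx.star_graph(4))
        assert table.loc[0, "degree"] == 4
        assert table.loc[0, "betweenness"] == pytest.approx(6)  # C(4,2) pairs
        assert table.loc[0, "closeness"] == pytest.approx(1.0)
        for leaf in range(1, 5):
            assert table.loc[leaf, "closeness"] == pytest.approx(4 / 7)
            assert table.loc[leaf, "betweenness"] == pytest.approx(0)

    def test_complete_graph_zero_betweenness(self):
        table = net.centralities(nx.complete_graph(4))
        assert np.allclose(table["betweenness"], 0)

    @pytest.mark.parametrize("n", [3, 5, 7])
    def test_path_middle_betweenness(self, n):
        table = net.centralities(nx.path_graph(n))
        mid = n // 2
        expected = ((n + 1) // 2 - 1) * (n // 2)
        assert table.loc[mid, "betweenness"] == pytest.approx(expected)

    def test_isolated_node_closeness_zero(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        g.add_node("c")
        table = net.centralities(g)
        assert table.loc["c", "closeness"] == 0

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            net.centralities(nx.Graph())

    def test_random_graphs_match_bfs_counting_oracle(self):
        rng = np.random.default_rng(33)
        for _ in range(10):
            g = _random_graph(rng)
            table = net.centralities(g)
            oracle = graph_centralities(sorted(g.nodes), list(g.edges))
            for v in g.nodes:
                assert table.loc[v, "degree"] == oracle["degree"][v]
                assert table.loc[v, "betweenness"] == pytest.approx(float(oracle["betweenness"][v]), abs=1e-9)
                assert table.loc[v, "closeness"] == pytest.approx(float(oracle["closeness"][v]), abs=1e-12)

    def test_dense_ranks_share_ties(self):
        g = nx.star_graph(4)
        table = net.centralities(g)
        leaf_ranks = table.loc[1:, "degree_rank"]
        assert set(leaf_ranks) == {2} and table.loc[0, "degree_rank"] == 1


class TestHubRules:
    def _table(self, metric_values: dict) -> pd.DataFrame:
        df = pd.DataFrame(metric_values)
        df.index.name = "gene_id"
        for m in net.METRICS:
            df[f"{m}_rank"] = df[m].rank(method="dense", ascending=False).astype(int)
        return df

    def test_hub_needs_two_metrics_and_candidacy(self):
        n = 15
        degree = list(range(n, 0, -1))
        table = self._table({
            "degree": degree,
            "betweenness": degree,
            "closeness": [x / n for x in degree],
        })
        # node 0 tops everything; node 14 bottoms everything
        hubs = net.hub_call(table, candidates={0, 14}, k=10)
        assert list(hubs.index) == [0]
        # top node not in candidates is excluded
        assert list(net.hub_call(table, candidates={14}, k=10).index) == []
        # unrestricted ranking includes every top node
        assert 0 in set(net.hub_call(table, candidates=set(), k=10, restrict=False).index)

    def test_single_metric_not_enough(self):
        table = self._table({
            "degree": [30] + [20 - i for i in range(14)],
            "betweenness": [0] + list(range(14, 0, -1)),
            "closeness": [0.01] + [(14 - i) / 20 for i in range(14)],
        })
        hubs = net.hub_call(table, candidates=set(table.index), k=5)
        assert 0 not in set(hubs.index)

    def test_ties_at_rank_k_included(self):
        vals = [50, 49, 48, 47, 46, 45, 44, 43, 42, 41, 41, 1]
        table = self._table({"degree": vals, "betweenness": vals, "closeness": [v / 100 for v in vals]})
        hubs = net.hub_call(table, candidates=set(table.index), k=10)
        assert 10 in set(hubs.index)  # shares dense rank 10
        assert 11 not in set(hubs.index)

    def test_cross_network_degree_rule(self):
        t1 = self._table({"degree": [10, 9, 1], "betweenness": [1, 2, 3], "closeness": [0.1, 0.2, 0.3]})
        t2 = self._table({"degree": [10, 1, 9], "betweenness": [1, 2, 3], "closeness": [0.1, 0.2, 0.3]})
        t3 = self._table({"degree": [1, 10, 9], "betweenness": [1, 2, 3], "closeness": [0.1, 0.2, 0.3]})
        out = net.cross_network_degree_rule({"a": t1, "b": t2, "c": t3}, candidates={0, 1, 2})
        # every node is in the degree top-10 of >=2 networks here (tiny tables)
        assert set(out.index) == {0, 1, 2}
        out2 = net.cross_network_degree_rule({"a": t1, "b": t2}, candidates={0}, k=1)
        assert set(out2.index) == {0}
        assert net.cross_network_degree_rule({"a": t1, "b": t2}, candidates={0}, k=1, exclude={0}).empty

    def test_cross_network_rule_matches_bruteforce(self):
        rng = np.random.default_rng(34)
        tables = {}
        for name in ("x", "y", "z"):
            vals = rng.permutation(40) + 1
            tables[name] = self._table({
                "degree": vals, "betweenness": rng.uniform(0, 1, 40), "closeness": rng.uniform(0, 1, 40)})
        candidates = set(rng.choice(40, 15, replace=False))
        out = net.cross_network_degree_rule(tables, candidates, k=10)
        expected = set()
        for node in candidates:
            # dense rank = 1 + number of distinct strictly larger degrees
            hits = sum(
                1 for t in tables.values()
                if 1 + len({v for v in t["degree"] if v > t.loc[node, "degree"]}) <= 10
            )
            if hits >= 2:
                expected.add(node)
        assert set(out.index) == expected

    def test_needs_two_networks(self):
        t = self._table({"degree": [1], "betweenness": [1], "closeness": [1]})
        with pytest.raises(ValueError):
            net.cross_network_degree_rule({"only": t}, candidates={0})
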