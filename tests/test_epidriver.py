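import itertools
from collections import deque

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epihub import epidriver, meth_prep
from epihub.data import ExpressionData

from conftest import make_meth


def expr_of(values, sample_ids, conditions=None):
    frame = pd.DataFrame(values, columns=sample_ids)
    frame.index = [f"g{i}" for i in range(len(frame))]
    meta = pd.DataFrame(
        {"condition": conditions or ["GDM"] * len(sample_ids)},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return ExpressionData(values=frame, samples=meta, level="gene")


class TestMatchSamples:
    def test_identical_sets_keep_expression_order(self):
        expr = expr_of([[1, 2, 3]], ["c", "a", "b"])
        meth = make_meth(pd.DataFrame([[0.1] * 3], index=["cg0"],
                                      columns=["a", "b", "c"]))
        assert epidriver.match_samples(expr, meth) == ["c", "a", "b"]

    def test_partial_overlap(self):
        expr = expr_of([[1, 2, 3]], ["a", "b", "c"])
        meth = make_meth(pd.DataFrame([[0.1] * 3], index=["cg0"],
                                      columns=["b", "c", "d"]))
        assert epidriver.match_samples(expr, meth) == ["b", "c"]

    def test_disjoint_sets_rejected(self):
        expr = expr_of([[1, 2]], ["a", "b"])
        meth = make_meth(pd.DataFrame([[0.1, 0.2]], index=["cg0"],
                                      columns=["x", "y"]))
        with pytest.raises(ValueError):
            epidriver.match_samples(expr, meth)


class TestPearsonTest:
    def test_perfect_anticorrelation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, p = epidriver.pearson_test(x, -x)
        assert r == pytest.approx(-1.0)
        assert p == pytest.approx(0.0)

    def test_hand_computed_r(self):
        r, p = epidriver.pearson_test([1, 2, 3, 4, 5], [2, 1, 4, 3, 6])
        assert r == pytest.approx(10 / np.sqrt(10 * 14.8), abs=1e-4)
        assert r == pytest.approx(0.8220, abs=1e-4)

    def test_orthogonal_vectors(self):
        r, p = epidriver.pearson_test([1, -1, 1, -1], [1, 1, -1, -1])
        assert r == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            x, y = rng.normal(size=(2, 15))
            r, p = epidriver.pearson_test(x, y)
            ref = stats.pearsonr(x, y)
            assert r == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            epidriver.pearson_test([1, 1, 1], [1, 2, 3])


class TestScreenNegative:
    def meth_m(self, values, genes, sample_ids):
        frame = pd.DataFrame(values, columns=sample_ids)
        frame.index = [f"cg{i}" for i in range(len(frame))]
        probes = pd.DataFrame(
            {
                "gene_symbol": genes,
                "region_class": "TSS200",
                "chromosome": "chr1",
                "flag_snp": False,
                "flag_crosshyb": False,
            },
            index=frame.index,
        )
        return make_meth(frame, scale="M", probes=probes)

    def test_strong_negative_pair_retained(self):
        rng = np.random.default_rng(0)
        e = rng.normal(8, 1, size=20)
        expr = expr_of([e], [f"s{i}" for i in range(20)])
        meth = self.meth_m([-e + rng.normal(0, 0.3, 20)], ["g0"],
                           [f"s{i}" for i in range(20)])
        table = epidriver.screen_negative(expr, meth, ["g0"])
        assert len(table) == 1
        assert table.iloc[0]["r"] < -0.8

    def test_positive_correlation_excluded(self):
        e = np.linspace(0, 1, 10)
        expr = expr_of([e], [f"s{i}" for i in range(10)])
        meth = self.meth_m([e], ["g0"], [f"s{i}" for i in range(10)])
        table = epidriver.screen_negative(expr, meth, ["g0"])
        assert table.empty

    def test_alpha_zero_gives_empty_table(self):
        e = np.linspace(0, 1, 10)
        expr = expr_of([e], [f"s{i}" for i in range(10)])
        meth = self.meth_m([-e], ["g0"], [f"s{i}" for i in range(10)])
        table = epidriver.screen_negative(expr, meth, ["g0"], alpha=0.0)
        assert table.empty

    def test_beta_scale_rejected(self):
        e = np.linspace(0.1, 0.9, 10)
        expr = expr_of([e], [f"s{i}" for i in range(10)])
        meth = self.meth_m([e], ["g0"], [f"s{i}" for i in range(10)])
        meth.scale = "beta"
        with pytest.raises(Exception):
            epidriver.screen_negative(expr, meth, ["g0"])

    def test_matches_per_pair_pearson(self):
        rng = np.random.default_rng(3)
        ids = [f"s{i}" for i in range(15)]
        expr = expr_of(rng.normal(size=(3, 15)), ids)
        meth = self.meth_m(rng.normal(size=(5, 15)),
                           ["g0", "g0", "g1", "g2", "g2"], ids)
        table = epidriver.screen_negative(
            expr, meth, ["g0", "g1", "g2"], alpha=1.0
        ).set_index("cpg")
        for cpg, gene in zip([f"cg{i}" for i in range(5)],
                             ["g0", "g0", "g1", "g2", "g2"]):
            r, p = epidriver.pearson_test(
                expr.values.loc[gene], meth.values.loc[cpg]
            )
            if r < 0:
                assert table.loc[cpg, "r"] == pytest.approx(r, abs=1e-12)
                assert table.loc[cpg, "p"] == pytest.approx(p, rel=1e-9)
            else:
                assert cpg not in table.index


class TestBuildNetwork:
    def drivers(self, rows):
        return pd.DataFrame(rows, columns=["gene", "cpg", "r", "p", "n"])

    def test_two_adjacent_drivers_one_cpg_each(self):
        pathway = nx.Graph([("g0", "g1"), ("g1", "g2")])
        table = self.drivers([("g0", "cg0", -0.5, 0.01, 20),
                              ("g1", "cg1", -0.6, 0.01, 20)])
        net = epidriver.build_network(pathway, table)
        assert net.number_of_nodes() == 4
        assert net.number_of_edges() == 3
        assert net.nodes["cg0"]["node_type"] == "cpg"

    def test_isolated_driver_keeps_cpg_edge(self):
        pathway = nx.Graph([("g1", "g2")])
        table = self.drivers([("g0", "cg0", -0.5, 0.01, 20)])
        net = epidriver.build_network(pathway, table)
        assert set(net.nodes) == {"g0", "cg0"}
        assert net.number_of_edges() == 1

    def test_empty_driver_table_rejected(self):
        with pytest.raises(ValueError):
            epidriver.build_network(nx.Graph(), self.drivers([]))


def harmonic_closeness_bfs(graph, u):
    """Oracle: plain BFS accumulation of reciprocal distances."""
    dist = {u: 0}
    q = deque([u])
    while q:
        v = q.popleft()
        for w in graph[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                q.append(w)
    return sum(1.0 / d for v, d in dist.items() if v != u)


def betweenness_by_path_enumeration(graph):
    """Oracle: enumerate all shortest paths per pair via depth-limited DFS."""
    nodes = list(graph.nodes)
    spl = dict(nx.all_pairs_shortest_path_length(graph))
    score = {n: 0.0 for n in nodes}
    for s, t in itertools.combinations(nodes, 2):
        if t not in spl[s]:
            continue
        target_len = spl[s][t]
        paths = []

        def dfs(v, path):
            if len(path) - 1 > target_len:
                return
            if v == t and len(path) - 1 == target_len:
                paths.append(list(path))
                return
            for w in graph[v]:
                if w not in path:
                    dfs(w, path + [w])

        dfs(s, [s])
        for path in paths:
            for v in path[1:-1]:
                score[v] += 1.0 / len(paths)
    return score


class TestCentralities:
    def mixed(self, gene_edges, cpg_edges):
        net = nx.Graph()
        for a, b in gene_edges:
            net.add_node(a, node_type="gene")
            net.add_node(b, node_type="gene")
            net.add_edge(a, b)
        for g, c in cpg_edges:
            net.add_node(g, node_type="gene")
            net.add_node(c, node_type="cpg")
            net.add_edge(g, c)
        return net

    def test_path_closeness(self):
        net = self.mixed([("a", "b"), ("b", "c")], [])
        table = epidriver.centralities(net)
        assert table.loc["b", "closeness"] == pytest.approx(2.0)
        assert table.loc["a", "closeness"] == pytest.approx(1.5)

    def test_star_betweenness(self):
        net = self.mixed([("hub", f"leaf{i}") for i in range(5)], [])
        table = epidriver.centralities(net)
        assert table.loc["hub", "betweenness"] == pytest.approx(10.0)
        assert (table.drop("hub")["betweenness"] == 0).all()

    def test_path_betweenness(self):
        net = self.mixed([("a", "b"), ("b", "c"), ("c", "d")], [])
        table = epidriver.centralities(net)
        assert table.loc["b", "betweenness"] == pytest.approx(2.0)
        assert table.loc["c", "betweenness"] == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_bfs_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 16))
        g = nx.gnp_random_graph(n, 0.25, seed=seed)
        net = nx.relabel_nodes(g, {i: f"n{i}" for i in range(n)})
        nx.set_node_attributes(net, "gene", "node_type")
        table = epidriver.centralities(net)
        oracle_b = betweenness_by_path_enumeration(net)
        for node in net.nodes:
            assert table.loc[node, "closeness"] == pytest.approx(
                harmonic_closeness_bfs(net, node), abs=1e-9
            )
            assert table.loc[node, "betweenness"] == pytest.approx(
                oracle_b[node], abs=1e-9
            )
            assert table.loc[node, "degree"] == net.degree(node)


class TestSelectHubs:
    def table(self, rows):
        frame = pd.DataFrame(
            rows, columns=["gene", "degree", "closeness", "betweenness"]
        ).set_index("gene")
        return frame

    def test_single_dominant_gene(self):
        t = self.table([("a", 9, 9.0, 9.0), ("b", 1, 1.0, 1.0),
                        ("c", 2, 2.0, 0.0)])
        assert epidriver.select_hubs(t, k=1) == ["a"]

    def test_hand_computed_intersection(self):
        t = self.table(
            [
                ("a", 5, 4.0, 10.0),
                ("b", 4, 5.0, 8.0),
                ("c", 3, 1.0, 9.0),   # top-2 betweenness only after a
                ("d", 1, 3.0, 0.0),
                ("e", 2, 2.0, 1.0),
            ]
        )
        # top-2: degree {a,b}, closeness {b,a}, betweenness {a,c}
        assert epidriver.select_hubs(t, k=2) == ["a"]

    def test_k_equal_to_gene_count_returns_all(self):
        t = self.table([("a", 3, 1.0, 0.0), ("b", 2, 2.0, 1.0),
                        ("c", 1, 3.0, 2.0)])
        assert epidriver.select_hubs(t, k=3) == ["a", "b", "c"]

    def test_row_order_invariant(self):
        rows = [("a", 5, 4.0, 1.0), ("b", 4, 5.0, 2.0), ("c", 3, 3.0, 3.0),
                ("d", 2, 2.0, 4.0), ("e", 1, 1.0, 5.0)]
        t1 = self.table(rows)
        t2 = self.table(rows[::-1])
        assert epidriver.select_hubs(t1, k=3) == epidriver.select_hubs(t2, k=3)

    def test_ties_at_kth_rank_included(self):
        t = self.table([("a", 5, 5.0, 5.0), ("b", 3, 3.0, 3.0),
                        ("c", 3, 3.0, 3.0), ("d", 1, 1.0, 1.0)])
        assert epidriver.select_hubs(t, k=2) == ["a", "b", "c"]

    def test_fraction_mode(self):
        rows = [(f"g{i}", 10 - i, float(10 - i), float(10 - i))
                for i in range(10)]
        t = self.table(rows)
        assert epidriver.select_hubs(t, frac=0.1) == ["g0"]
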