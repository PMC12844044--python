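import numpy as np
import pandas as pd
import pytest

from recovermet.network import (
    GroupNetwork,
    NetworkError,
    betweenness,
    build_network,
    differential_network,
    pvalue_ecdf,
    spearman_matrix,
)

from oracles import betweenness_enumeration, spearman_brute


class TestSpearmanMatrix:
    def test_monotone_pair(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [1.0, 4, 9, 16]})
        r, p = spearman_matrix(df)
        assert r.loc["x", "y"] == pytest.approx(1.0)

    def test_antimonotone_pair(self):
        x = np.array([1.0, 1.5, 3, 4, 9])
        df = pd.DataFrame({"x": x, "y": x[::-1]})  # sorted x vs its reversal
        r, _ = spearman_matrix(df)
        assert r.loc["x", "y"] == pytest.approx(-1.0)

    def test_ties_match_bruteforce_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0])
        y = np.array([2.0, 1.0, 3.0, 3.0, 5.0, 4.0])
        df = pd.DataFrame({"x": x, "y": y})
        r, _ = spearman_matrix(df)
        assert r.loc["x", "y"] == pytest.approx(spearman_brute(x, y), abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_full_matrix_matches_oracle_small_samples(self, seed):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.integers(0, 5, size=(8, 4)).astype(float),
                         columns=list("abcd"))
        r, _ = spearman_matrix(X)
        for i in "abcd":
            for j in "abcd":
                if i != j:
                    assert r.loc[i, j] == pytest.approx(
                        spearman_brute(X[i], X[j]), abs=1e-12)

    def test_too_few_samples_rejected(self):
        with pytest.raises(NetworkError, match=">= 4"):
            spearman_matrix(pd.DataFrame(np.ones((3, 2)), columns=["a", "b"]))

    def test_constant_feature_never_an_edge(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"a": rng.normal(size=8), "b": np.ones(8),
                           "c": rng.normal(size=8)})
        r, p = spearman_matrix(df)
        assert np.isnan(r.loc["a", "b"])
        net = build_network(r, p)
        assert all("b" not in e[:2] for e in net.edges)
        assert "b" in net.nodes  # isolated, but retained

    def test_diagonal_fixed(self):
        rng = np.random.default_rng(6)
        r, p = spearman_matrix(pd.DataFrame(rng.normal(size=(6, 3)),
                                            columns=list("abc")))
        assert np.allclose(np.diag(r), 1.0)
        assert np.allclose(np.diag(p), 0.0)


def _matrices(r_dict, p_dict, nodes):
    r = pd.DataFrame(np.eye(len(nodes)), index=nodes, columns=nodes)
    p = pd.DataFrame(np.zeros((len(nodes), len(nodes))), index=nodes, columns=nodes)
    p.values[~np.eye(len(nodes), dtype=bool)] = 1.0
    for (i, j), val in r_dict.items():
        r.loc[i, j] = r.loc[j, i] = val
    for (i, j), val in p_dict.items():
        p.loc[i, j] = p.loc[j, i] = val
    return r, p


class TestBuildNetwork:
    def test_weak_correlations_yield_no_edges(self):
        r, p = _matrices({("a", "b"): 0.5, ("a", "c"): -0.59},
                         {("a", "b"): 0.001, ("a", "c"): 0.001}, list("abc"))
        net = build_network(r, p)
        assert net.edges == [] and set(net.nodes) == {"a", "b", "c"}

    def test_edge_rule_is_strict_on_both_thresholds(self):
        r, p = _matrices({("a", "b"): 0.61, ("a", "c"): 0.61},
                         {("a", "b"): 0.04, ("a", "c"): 0.06}, list("abc"))
        net = build_network(r, p)
        assert [(e[0], e[1]) for e in net.edges] == [("a", "b")]

    def test_raising_threshold_never_adds_edges(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(10, 5)), columns=list("abcde"))
        X["b"] = X["a"] + 0.1 * rng.normal(size=10)
        r, p = spearman_matrix(X)
        edges = [len(build_network(r, p, r_threshold=t).edges)
                 for t in (0.3, 0.5, 0.7, 0.9)]
        assert edges == sorted(edges, reverse=True)

    def test_edge_count_invariant_under_relabelling(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(12, 4)), columns=list("abcd"))
        X["d"] = X["c"] * 2 + 0.05 * rng.normal(size=12)
        r, p = spearman_matrix(X)
        n1 = len(build_network(r, p).edges)
        relabel = {"a": "z", "b": "y", "c": "x", "d": "w"}
        r2 = r.rename(index=relabel, columns=relabel)
        p2 = p.rename(index=relabel, columns=relabel)
        assert len(build_network(r2, p2).edges) == n1


def _graph_network(nodes, edge_pairs):
    r = pd.DataFrame(np.eye(len(nodes)), index=nodes, columns=nodes)
    p = pd.DataFrame(np.ones((len(nodes), len(nodes))), index=nodes, columns=nodes)
    np.fill_diagonal(p.values, 0.0)
    for i, j in edge_pairs:
        r.loc[i, j] = r.loc[j, i] = 0.9
        p.loc[i, j] = p.loc[j, i] = 0.001
    return build_network(r, p)


class TestBetweenness:
    def test_path_graph(self):
        net = _graph_network(list("abc"), [("a", "b"), ("b", "c")])
        b = betweenness(net)
        assert b["b"] == pytest.approx(1.0)
        assert b["a"] == b["c"] == 0.0

    def test_star_center_counts_all_leaf_pairs(self):
        net = _graph_network(list("cwxyz"),
                             [("c", n) for n in "wxyz"])
        b = betweenness(net)
        assert b["c"] == pytest.approx(6.0)  # C(4, 2)
        assert all(b[n] == 0.0 for n in "wxyz")

    def test_complete_graph_all_zero(self):
        nodes = list("abcd")
        net = _graph_network(nodes, [(i, j) for k, i in enumerate(nodes)
                                     for j in nodes[k + 1:]])
        assert np.allclose(betweenness(net), 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_graphs_match_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        nodes = list("abcdefg")
        pairs = [(i, j) for k, i in enumerate(nodes) for j in nodes[k + 1:]]
        edges = [pq for pq in pairs if rng.random() < 0.4]
        net = _graph_network(nodes, edges)
        expected = betweenness_enumeration(nodes, edges)
        got = betweenness(net)
        for node in nodes:
            assert got[node] == pytest.approx(expected[node], abs=1e-9)


class TestDifferentialNetwork:
    def _nets(self, seed=0, shift=0.0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(14, 4)), columns=list("abcd"))
        X["b"] = X["a"] * (1 + shift) + 0.3 * rng.normal(size=14)
        r, p = spearman_matrix(X)
        return build_network(r, p, pathways={"a": "purine", "b": "lipid_peroxidation",
                                             "c": "other", "d": "other"})

    def test_identical_inputs_give_zero_deltas(self):
        net = self._nets()
        diff = differential_network(net, net)
        assert np.allclose(diff.delta_r, 0.0)
        assert np.allclose(diff.delta_betweenness, 0.0)
        assert (diff.strong_edge_delta == 0).all()

    def test_arm_swap_antisymmetry(self):
        n1, n2 = self._nets(seed=1), self._nets(seed=2, shift=0.5)
        d12 = differential_network(n1, n2)
        d21 = differential_network(n2, n1)
        assert np.allclose(d12.delta_r, -d21.delta_r, equal_nan=True)
        assert np.allclose(d12.delta_betweenness, -d21.delta_betweenness)
        assert (d12.strong_edge_delta == -d21.strong_edge_delta).all()

    def test_strong_edge_delta_is_integer(self):
        d = differential_network(self._nets(seed=3), self._nets(seed=4, shift=1.0))
        assert d.strong_edge_delta.dtype.kind == "i"

    def test_node_mismatch_rejected(self):
        n1 = self._nets()
        n2 = self._nets()
        n2.nodes = list("abce")
        with pytest.raises(NetworkError, match="node sets"):
            differential_network(n1, n2)

    def test_pathway_pair_means(self):
        n1, n2 = self._nets(seed=5), self._nets(seed=6)
        diff = differential_network(n1, n2)
        table = diff.pathway_pair_mean_delta
        row = table[(table.pathway_a == "lipid_peroxidation")
                    & (table.pathway_b == "purine")]
        assert row["n_pairs"].iloc[0] == 1  # single a-b cross pair
        expected = diff.delta_r.loc["a", "b"]
        assert row["mean_delta_r"].iloc[0] == pytest.approx(expected)


class TestPvalueEcdf:
    def test_boundary_values(self):
        table = pvalue_ecdf([0.2, 0.5, 0.9])
        assert table["ecdf"].iloc[-1] == 1.0   # ECDF at 1
        assert table["ecdf"].iloc[0] == 0.0    # ECDF below the minimum

    def test_uniform_sample_close_to_identity(self):
        rng = np.random.default_rng(9)
        table = pvalue_ecdf(rng.random(10_000))
        sup = np.max(np.abs(table["ecdf"] - table["p"]))
        assert sup < 0.03

    def test_empty_input_rejected(self):
        with pytest.raises(NetworkError, match="empty"):
            pvalue_ecdf([])
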