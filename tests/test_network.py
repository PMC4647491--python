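"""Clustering, co-expression network, connectivity and antisense screen."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from codewise import (
    assign_superclusters,
    build_network,
    categorize_sv_domains,
    center_normalize,
    degree_of_connectivity,
    find_hubs,
    kmeans_cluster,
    nearest_neighbors,
    sense_antisense_screen,
    supercluster_connectivity,
)
from codewise.io import DomainHit


class TestCenterNormalize:
    def test_closed_form(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0]], index=["t"], columns=list("abc"))
        out = center_normalize(m)
        np.testing.assert_allclose(out.loc["t"].values,
                                   np.array([-1, 0, 1]) / np.sqrt(2))

    def test_constant_row_flagged_and_zeroed(self):
        m = pd.DataFrame([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]],
                         index=["flat", "ok"])
        with pytest.warns(UserWarning, match="constant"):
            out = center_normalize(m)
        assert (out.loc["flat"] == 0).all()

    def test_normalization_contract(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.exponential(2.0, (40, 10)))
        out = center_normalize(m)
        np.testing.assert_allclose(out.sum(axis=1), 0.0, atol=1e-12)
        ss = (out ** 2).sum(axis=1)
        assert np.allclose(ss, 1.0) or set(np.round(ss, 9)) <= {0.0, 1.0}


class TestKmeans:
    def test_recovers_two_separated_groups(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.0, 0.05, (20, 6)) + [0, 0, 0, 5, 5, 5]
        b = rng.normal(0.0, 0.05, (20, 6)) + [5, 5, 5, 0, 0, 0]
        m = pd.DataFrame(np.vstack([a, b]),
                         index=[f"t{i}" for i in range(40)])
        labels = [x.cluster_id for x in kmeans_cluster(m, 2, 50, seed=0)]
        assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1
        assert labels[0] != labels[20]

    def test_k_equals_rows_is_degenerate(self):
        m = pd.DataFrame(np.eye(4) * 10)
        labels = [x.cluster_id for x in kmeans_cluster(m, 4, 10, seed=0)]
        assert len(set(labels)) == 4

    def test_same_seed_identical(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.normal(size=(30, 8)))
        a = kmeans_cluster(m, 5, 20, seed=9)
        b = kmeans_cluster(m, 5, 20, seed=9)
        assert a == b

    def test_k_larger_than_rows_rejected(self):
        m = pd.DataFrame(np.eye(3))
        with pytest.raises(ValueError):
            kmeans_cluster(m, 4, 10, seed=0)


class TestSuperclusters:
    def test_identity_and_surjective_mappings(self):
        m = pd.DataFrame(np.random.default_rng(0).normal(size=(25, 5)))
        assignments = kmeans_cluster(m, 5, 10, seed=0)
        ident = assign_superclusters(assignments,
                                     {i: str(i) for i in range(5)})
        assert all(a.supercluster_id == str(a.cluster_id) for a in ident)
        merged = assign_superclusters(
            assignments, {i: "early" if i < 3 else "dt" for i in range(5)})
        assert set(a.supercluster_id for a in merged) <= {"early", "dt"}
        # partition conservation
        assert len(merged) == len(assignments)

    def test_unmapped_cluster_id_rejected(self):
        m = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 4)))
        assignments = kmeans_cluster(m, 3, 10, seed=0)
        with pytest.raises(ValueError):
            assign_superclusters(assignments, {0: "a", 1: "b"})


def brute_force_edges(matrix: pd.DataFrame, threshold: float, rule: str):
    edges = set()
    for a, b in itertools.combinations(matrix.index, 2):
        r = sps.pearsonr(matrix.loc[a], matrix.loc[b])[0]
        strength = r if rule == "signed_positive" else abs(r)
        if strength >= threshold:
            edges.add(frozenset((a, b)))
    return edges


class TestBuildNetwork:
    def test_identical_rows_edge_weight_one(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0]], index=["a", "b"])
        g = build_network(m, 0.9)
        assert g["a"]["b"]["weight"] == pytest.approx(1.0)

    def test_edge_rule_contrast_on_anticorrelated_rows(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]], index=["a", "b"])
        assert not build_network(m, 0.9).has_edge("a", "b")
        assert build_network(m, 0.9, "absolute").has_edge("a", "b")

    @pytest.mark.parametrize("rule", ["signed_positive", "absolute"])
    def test_matches_all_pairs_oracle(self, rule):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(3, 10))
        rows = [base[i % 3] + rng.normal(0, sd, 10)
                for i, sd in enumerate(rng.uniform(0.05, 2.0, 30))]
        m = pd.DataFrame(rows, index=[f"t{i}" for i in range(30)])
        g = build_network(m, 0.8, rule)
        assert {frozenset(e) for e in g.edges} == brute_force_edges(m, 0.8, rule)

    def test_threshold_compliance_and_symmetry(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame(rng.normal(size=(20, 8)))
        g = build_network(m, 0.5)
        for a, b, d in g.edges(data=True):
            assert d["weight"] >= 0.5
            assert g.has_edge(b, a)
        assert not any(a == b for a, b in g.edges)

    def test_constant_rows_excluded_with_warning(self):
        m = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [2.0, 4.0, 6.0]],
                         index=["flat", "a", "b"])
        with pytest.warns(UserWarning, match="constant"):
            g = build_network(m, 0.9)
        assert g.degree["flat"] == 0 and g.has_edge("a", "b")


def star_network(n_leaves=9, supercluster="dt"):
    g = nx.Graph(threshold=0.9, edge_rule="signed_positive")
    g.add_node("hub", supercluster=supercluster)
    for i in range(n_leaves):
        g.add_node(f"leaf{i}", supercluster=supercluster)
        g.add_edge("hub", f"leaf{i}", weight=0.95)
    return g


class TestConnectivity:
    def test_worked_example_five_of_ten(self):
        g = star_network(n_leaves=9)
        # keep only 5 of the 9 spokes: hub connected to 5 nodes in a
        # 10-node super-cluster
        for i in range(5, 9):
            g.remove_edge("hub", f"leaf{i}")
        rec = degree_of_connectivity(g, "hub", "dt")
        assert (rec.m, rec.n) == (5, 10)
        assert rec.degree == 0.5

    def test_isolated_node_and_complete_graph(self):
        g = nx.Graph()
        for i in range(6):
            g.add_node(f"n{i}", supercluster="sc")
        assert degree_of_connectivity(g, "n0", "sc").degree == 0
        for a, b in itertools.combinations(range(6), 2):
            g.add_edge(f"n{a}", f"n{b}")
        for i in range(6):
            assert degree_of_connectivity(g, f"n{i}", "sc").degree == 5 / 6

    def test_invariant_to_outside_node_insertion(self):
        g = star_network()
        before = degree_of_connectivity(g, "hub", "dt").degree
        g.add_node("outsider", supercluster="early")
        g.add_node("outsider2")  # no supercluster at all
        assert degree_of_connectivity(g, "hub", "dt").degree == before

    def test_empty_supercluster_rejected(self):
        with pytest.raises(ValueError):
            degree_of_connectivity(star_network(), "hub", "nope")

    def test_supercluster_connectivity_median(self):
        g = nx.Graph()
        for i in range(3):
            g.add_node(f"n{i}", supercluster="sc")
        g.add_edge("n0", "n1")  # degrees m: 1, 1, 0 -> /3
        assert supercluster_connectivity(g, "sc") == pytest.approx(1 / 3)

    def test_supercluster_connectivity_matches_sort_oracle(self):
        rng = np.random.default_rng(5)
        g = nx.gnp_random_graph(20, 0.3, seed=1)
        g = nx.relabel_nodes(g, {i: f"t{i}" for i in range(20)})
        nx.set_node_attributes(g, "sc", "supercluster")
        degs = sorted(degree_of_connectivity(g, n, "sc").degree for n in g)
        mid = (degs[9] + degs[10]) / 2  # even count: mean of central pair
        assert supercluster_connectivity(g, "sc") == pytest.approx(mid)


class TestHubs:
    def test_star_center_is_unique_top_hub(self):
        ranked = find_hubs(star_network(), "dt", top_n=3)
        assert ranked[0].transcript_id == "hub"
        assert ranked[0].degree == 9 / 10

    def test_tie_breaks_lexicographically(self):
        g = nx.Graph()
        for n in ("b", "a", "c"):
            g.add_node(n, supercluster="sc")
        g.add_edge("a", "b")
        ranked = find_hubs(g, "sc", top_n=2, dedupe_by_gene=False)
        assert [r.transcript_id for r in ranked] == ["a", "b"]

    def test_dedupe_keeps_best_isoform_per_gene(self):
        g = star_network()
        nx.set_node_attributes(
            g, {"hub": "geneA", "leaf0": "geneA", "leaf1": "geneB"}, "gene_id")
        ranked = find_hubs(g, "dt", top_n=10, dedupe_by_gene=True)
        ids = [r.transcript_id for r in ranked]
        assert "hub" in ids and "leaf0" not in ids
        ranked_all = find_hubs(g, "dt", top_n=10, dedupe_by_gene=False)
        assert "leaf0" in [r.transcript_id for r in ranked_all]


class TestNearestNeighbors:
    def test_isolated_and_star(self):
        g = star_network()
        g.add_node("loner", supercluster="dt")
        sub = nearest_neighbors(g, "loner")
        assert list(sub.nodes) == ["loner"]
        whole = nearest_neighbors(g, "hub")
        assert set(whole.nodes) == set(g.nodes) - {"loner"}
        assert whole.nodes["leaf0"]["supercluster"] == "dt"

    def test_neighbor_set_matches_adjacency_oracle(self):
        g = nx.gnp_random_graph(15, 0.3, seed=2)
        adj = nx.to_numpy_array(g)
        for node in g:
            sub = nearest_neighbors(g, node)
            expected = {n for n in g if adj[node, n]} | {node}
            assert set(sub.nodes) == expected

    def test_unknown_node_rejected(self):
        with pytest.raises(KeyError):
            nearest_neighbors(star_network(), "ghost")


class TestSenseAntisenseScreen:
    def matrix(self, rows, ids):
        return pd.DataFrame(rows, index=ids,
                            columns=[f"d{i}" for i in range(len(rows[0]))])

    def test_identical_profiles_perfectly_correlated(self):
        prof = np.linspace(1, 10, 10)
        m = self.matrix([prof, prof * 2], ["s", "as"])
        (pair,), summary = sense_antisense_screen(m, [("s", "as")])
        assert pair.r == pytest.approx(1.0)
        assert pair.significant and pair.p_value < 0.05
        assert summary["n_significant"] == 1

    def test_r_matches_covariance_formula_oracle(self):
        rng = np.random.default_rng(8)
        m = self.matrix(rng.normal(size=(100, 10)),
                        [f"t{i}" for i in range(100)])
        pairs = [(f"t{2 * i}", f"t{2 * i + 1}") for i in range(50)]
        results, _ = sense_antisense_screen(m, pairs)
        for pair in results:
            x = m.loc[pair.sense_id].values
            y = m.loc[pair.antisense_id].values
            xc, yc = x - x.mean(), y - y.mean()
            r = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
            assert abs(pair.r - r) < 1e-12

    def test_constant_member_flagged_not_significant(self):
        m = self.matrix([[1.0] * 5, [1, 2, 3, 4, 5]], ["flat", "x"])
        (pair,), _ = sense_antisense_screen(m, [("flat", "x")])
        assert not pair.significant and "constant" in pair.note
        assert np.isnan(pair.r)

    def test_missing_member_rejected(self):
        m = self.matrix([[1, 2, 3]], ["a"])
        with pytest.raises(KeyError):
            sense_antisense_screen(m, [("a", "ghost")])


class TestCategorizeSvDomains:
    def hits(self, composition):
        return [DomainHit(tid, acc, acc, False)
                for tid, accs in composition.items() for acc in accs]

    def test_disparate_similar_and_no_domain(self):
        assert categorize_sv_domains(
            ["a", "b"], self.hits({"a": ["PKc", "EFh"], "b": ["PKc"]})
        ) == "disparate"
        assert categorize_sv_domains(
            ["a", "b"], self.hits({"a": ["PKc"], "b": ["PKc", "PKc"]})
        ) == "similar"
        assert categorize_sv_domains(
            ["a", "b"], self.hits({"a": [], "b": ["PKc"]})
        ) == "no_known_domain"

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError):
            categorize_sv_domains(["only"], [])
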