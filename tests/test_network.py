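"""Correlation networks, communities, cliques and node reductions."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import stressfactor as sf
from conftest import make_matrix


def _layers(seed=0, n=20, p=5, q=4):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((p, n))
    Y = rng.standard_normal((q, n))
    x = make_matrix(X, prefix="g")
    y = sf.OmicsMatrix(Y, [f"m{i}" for i in range(q)], x.sample_ids,
                       layer="metabolome", scale="log2")
    return x, y


class TestPairwiseCorrelations:
    def test_identical_profiles_give_r_one(self):
        x, y = _layers(0)
        y.values[0] = x.values[0]
        cand = sf.pairwise_correlations(x, y)
        row = cand[(cand["source"] == "g0") & (cand["target"] == "m0")]
        assert row["r"].iloc[0] == pytest.approx(1.0)

    def test_symmetry_of_within_layer_edges(self):
        x, _ = _layers(1)
        cand = sf.pairwise_correlations(x, classes=("gene-gene",))
        r_direct = {(s, t): r for s, t, r in zip(cand["source"],
                                                 cand["target"], cand["r"])}
        corr = np.corrcoef(x.values)
        for (s, t), r in r_direct.items():
            i, j = int(s[1:]), int(t[1:])
            assert r == pytest.approx(corr[i, j], abs=1e-12)
            assert r == pytest.approx(corr[j, i], abs=1e-12)

    def test_p_value_matches_permutation_null(self):
        # the t-transform p agrees with an empirical permutation null
        rng = np.random.default_rng(2)
        a, b = rng.standard_normal(20), rng.standard_normal(20)
        x = make_matrix(a[None, :], prefix="g")
        y = sf.OmicsMatrix(b[None, :], ["m0"], x.sample_ids,
                           layer="metabolome", scale="log2")
        p_model = sf.pairwise_correlations(x, y)["p_value"].iloc[0]
        r_obs = abs(np.corrcoef(a, b)[0, 1])
        perm = np.zeros(10_000)
        for i in range(10_000):
            perm[i] = abs(np.corrcoef(a, rng.permutation(b))[0, 1])
        p_perm = (perm >= r_obs).mean()
        assert abs(p_model - p_perm) < 0.02

    def test_constant_variable_excluded(self, caplog):
        x, y = _layers(3)
        x.values[2] = 7.0
        with caplog.at_level("INFO"):
            cand = sf.pairwise_correlations(x, y)
        assert "g2" not in set(cand["source"])

    def test_minimum_sample_requirement(self):
        x, y = _layers(4, n=3)
        with pytest.raises(ValueError, match="at least 4"):
            sf.pairwise_correlations(x, y)


def _cand(rows):
    return pd.DataFrame(rows, columns=["source", "target", "edge_class",
                                       "r", "p_value", "p_adjusted"])


class TestBuildNetwork:
    def test_single_qualifying_pair(self):
        cand = _cand([("g1", "m1", "gene-mass", 0.9, 1e-9, 1e-8)])
        g = sf.build_network(cand)
        assert g.number_of_nodes() == 2 and g.number_of_edges() == 1
        assert g.nodes["g1"]["node_type"] == "gene"

    def test_gene_gene_edges_need_admitted_endpoints(self):
        cand = _cand([
            ("g1", "m1", "gene-mass", 0.9, 1e-9, 1e-8),
            ("g1", "g2", "gene-gene", 0.9, 1e-9, 1e-8),   # g2 not admitted
            ("g1", "g3", "gene-gene", 0.95, 1e-10, 1e-9),
            ("g3", "m1", "gene-mass", 0.88, 1e-9, 1e-8),
        ])
        g = sf.build_network(cand)
        assert "g2" not in g
        assert g.has_edge("g1", "g3")

    def test_negative_and_subthreshold_edges_excluded(self):
        cand = _cand([
            ("g1", "m1", "gene-mass", -0.95, 1e-9, 1e-8),
            ("g2", "m2", "gene-mass", 0.80, 1e-9, 1e-8),
        ])
        g = sf.build_network(cand)
        assert g.number_of_nodes() == 0

    def test_planted_module_forms_one_component(self):
        rng = np.random.default_rng(5)
        factor = rng.standard_normal(30)
        genes = factor[None, :] + 0.2 * rng.standard_normal((10, 30))
        masses = factor[None, :] + 0.2 * rng.standard_normal((3, 30))
        x = make_matrix(genes, prefix="g")
        y = sf.OmicsMatrix(masses, [f"m{i}" for i in range(3)], x.sample_ids,
                           layer="metabolome", scale="log2")
        cand = sf.pairwise_correlations(
            x, y, classes=("gene-mass", "gene-gene", "mass-mass"))
        g = sf.build_network(cand, sf.Thresholds(edge_r=0.85))
        assert g.number_of_nodes() == 13
        assert nx.number_connected_components(g) == 1

    def test_raising_edge_r_shrinks_graph(self):
        rng = np.random.default_rng(6)
        factor = rng.standard_normal(25)
        x = make_matrix(factor[None, :] * np.linspace(1, 0.2, 8)[:, None]
                        + 0.3 * rng.standard_normal((8, 25)), prefix="g")
        y = sf.OmicsMatrix(
            factor[None, :] * np.linspace(1, 0.4, 4)[:, None]
            + 0.3 * rng.standard_normal((4, 25)),
            [f"m{i}" for i in range(4)], x.sample_ids,
            layer="metabolome", scale="log2")
        cand = sf.pairwise_correlations(
            x, y, classes=("gene-mass", "gene-gene", "mass-mass"))
        prev_nodes, prev_edges = None, None
        for r in (0.5, 0.7, 0.9):
            g = sf.build_network(cand, sf.Thresholds(edge_r=r, edge_alpha=1.0))
            if prev_nodes is not None:
                assert set(g.nodes) <= prev_nodes
                assert set(map(frozenset, g.edges)) <= prev_edges
            prev_nodes, prev_edges = set(g.nodes), set(map(frozenset, g.edges))


class TestSubmoduleView:
    def test_anti_correlated_blocks(self):
        rng = np.random.default_rng(7)
        factor = rng.standard_normal(40)
        block_a = factor[None, :] + 0.1 * rng.standard_normal((3, 40))
        block_b = -factor[None, :] + 0.1 * rng.standard_normal((3, 40))
        x = make_matrix(np.vstack([block_a, block_b]), prefix="g")
        cand = sf.pairwise_correlations(x, classes=("gene-gene",))
        g = sf.submodule_view(cand, list(x.variable_ids), 0.75, 0.75)
        for u, v, d in g.edges(data=True):
            same_block = (int(u[1:]) < 3) == (int(v[1:]) < 3)
            assert d["sign"] == (1 if same_block else -1)

    def test_impossible_positive_threshold(self):
        cand = _cand([("g1", "g2", "gene-gene", 0.99, 1e-9, 1e-8)])
        g = sf.submodule_view(cand, ["g1", "g2"], pos_r=1.0, neg_r=1.0)
        assert g.number_of_edges() == 0

    def test_single_variable_empty_edges_and_unknown_id(self):
        cand = _cand([("g1", "g2", "gene-gene", 0.99, 1e-9, 1e-8)])
        assert sf.submodule_view(cand, ["g1"]).number_of_edges() == 0
        with pytest.raises(ValueError, match="unknown"):
            sf.submodule_view(cand, ["nope"])


def _clique_graph(*cliques, extra_edges=()):
    g = nx.Graph()
    for nodes in cliques:
        for u, v in itertools.combinations(nodes, 2):
            g.add_edge(u, v, sign=1)
    for u, v in extra_edges:
        g.add_edge(u, v, sign=1)
    return g


class TestLabelPropagation:
    def test_disjoint_triangles_two_communities(self):
        g = _clique_graph(["a", "b", "c"], ["x", "y", "z"])
        part = sf.label_propagation(g, seed=1)
        labels = part["labels"]
        assert labels["a"] == labels["b"] == labels["c"]
        assert labels["x"] == labels["y"] == labels["z"]
        assert labels["a"] != labels["x"]

    def test_edgeless_graph_singletons(self):
        g = nx.Graph()
        g.add_nodes_from("abcd")
        part = sf.label_propagation(g, seed=0)
        assert len(set(part["labels"].values())) == 4

    def test_two_cliques_with_bridge_usually_split(self):
        g = _clique_graph(list("abcde"), list("vwxyz"),
                          extra_edges=[("a", "v")])
        hits = 0
        for seed in range(50):
            labels = sf.label_propagation(g, seed=seed)["labels"]
            if len(set(labels.values())) == 2:
                hits += 1
        assert hits >= 45

    def test_fixed_point_property(self):
        rng = np.random.default_rng(8)
        for trial in range(10):
            g = nx.gnp_random_graph(25, 0.15, seed=int(rng.integers(1e6)))
            nx.set_edge_attributes(g, 1, "sign")
            labels = sf.label_propagation(g, seed=trial)["labels"]
            for node in g:
                neigh = list(g.neighbors(node))
                if not neigh:
                    continue
                counts = {}
                for v in neigh:
                    counts[labels[v]] = counts.get(labels[v], 0) + 1
                assert counts.get(labels[node], 0) == max(counts.values())

    def test_deterministic_given_seed(self):
        g = _clique_graph(list("abcd"), list("wxyz"),
                          extra_edges=[("a", "w")])
        runs = [sf.label_propagation(g, seed=5)["labels"] for _ in range(3)]
        assert runs[0] == runs[1] == runs[2]

    def test_consensus_over_seeds(self):
        g = _clique_graph(list("abcde"), list("vwxyz"),
                          extra_edges=[("a", "v")])
        part = sf.consensus_label_propagation(g, seeds=list(range(9)))
        labels = part["labels"]
        assert len({labels[c] for c in "abcde"}) == 1
        assert len({labels[c] for c in "vwxyz"}) == 1


def _brute_force_maximal_cliques(g, min_size):
    nodes = list(g.nodes)
    cliques = []
    for r in range(min_size, len(nodes) + 1):
        for sub in itertools.combinations(nodes, r):
            if all(g.has_edge(u, v) for u, v in itertools.combinations(sub, 2)):
                cliques.append(frozenset(sub))
    maximal = [c for c in cliques
               if not any(c < other for other in cliques)]
    return sorted((tuple(sorted(c)) for c in maximal),
                  key=lambda c: (-len(c), c))


class TestMaximalCliques:
    def test_triangle_and_path(self):
        tri = _clique_graph(["a", "b", "c"])
        assert sf.maximal_cliques(tri) == [("a", "b", "c")]
        path = _clique_graph(["a", "b"], ["b", "c"])
        assert sf.maximal_cliques(path, min_size=2) == [("a", "b"), ("b", "c")]

    def test_matches_exhaustive_oracle_on_random_graphs(self):
        rng = np.random.default_rng(9)
        for trial in range(30):
            n = int(rng.integers(4, 13))
            g = nx.gnp_random_graph(n, float(rng.uniform(0.2, 0.7)),
                                    seed=int(rng.integers(1e6)))
            nx.set_edge_attributes(g, 1, "sign")
            assert sf.maximal_cliques(g, min_size=2) == \
                _brute_force_maximal_cliques(g, 2)

    def test_mass_requirement_filter(self):
        g = _clique_graph(["g1", "g2", "g3"], ["g4", "m1"])
        g.nodes["m1"]["node_type"] = "mass"
        for n in ("g1", "g2", "g3", "g4"):
            g.nodes[n]["node_type"] = "gene"
        cliques = sf.maximal_cliques(g, min_size=2, require_mass=True)
        assert cliques == [("g4", "m1")]


class TestTopGenesPerMass:
    def test_keeps_k_best_partners(self):
        rows = [("g%d" % i, "m1", "gene-mass", 0.99 - 0.01 * i, 1e-9, 1e-8)
                for i in range(5)]
        kept = sf.top_genes_per_mass(_cand(rows), k=3)
        assert kept == ["g0", "g1", "g2"]

    def test_fewer_partners_all_kept_and_union_dedup(self):
        rows = [
            ("g1", "m1", "gene-mass", 0.9, 1e-9, 1e-8),
            ("g1", "m2", "gene-mass", 0.95, 1e-9, 1e-8),
            ("g2", "m2", "gene-mass", 0.91, 1e-9, 1e-8),
        ]
        kept = sf.top_genes_per_mass(_cand(rows), k=3)
        assert kept == ["g1", "g2"]
        with pytest.raises(ValueError):
            sf.top_genes_per_mass(_cand(rows), k=0)


class TestCrossTargetedEdges:
    def test_identical_profile_gives_unit_edge(self):
        x, _ = _layers(10, n=25, p=3)
        targeted = sf.OmicsMatrix(
            x.values[[0]], ["sucrose"], x.sample_ids,
            layer="targeted_metabolome", scale="log2")
        edges = sf.cross_targeted_edges(x, targeted, r_thresh=0.85)
        assert len(edges) == 1
        assert edges["r"].iloc[0] == pytest.approx(1.0)

    def test_min_connection_filter(self):
        rng = np.random.default_rng(11)
        factor = rng.standard_normal(30)
        genes = factor[None, :] + 0.1 * rng.standard_normal((4, 30))
        x = make_matrix(genes, prefix="g")
        targeted = sf.OmicsMatrix(
            factor[None, :] + 0.1 * rng.standard_normal((1, 30)),
            ["met1"], x.sample_ids, layer="targeted_metabolome", scale="log2")
        edges = sf.cross_targeted_edges(x, targeted, r_thresh=0.85,
                                        min_gene_connections=10)
        assert edges.empty  # only 4 possible gene partners
        edges = sf.cross_targeted_edges(x, targeted, r_thresh=0.85)
        assert len(edges) == 4

    def test_independent_noise_yields_no_edges(self):
        for seed in range(20):
            rng = np.random.default_rng(400 + seed)
            x = make_matrix(rng.standard_normal((5, 56)), prefix="g")
            targeted = sf.OmicsMatrix(
                rng.standard_normal((2, 56)), ["t1", "t2"], x.sample_ids,
                layer="targeted_metabolome", scale="log2")
            edges = sf.cross_targeted_edges(x, targeted, r_thresh=0.85)
            assert edges.empty

    def test_no_shared_samples_rejected(self):
        x, _ = _layers(12)
        targeted = sf.OmicsMatrix(
            np.ones((1, 2)) + np.arange(2), ["t1"], ["q1", "q2"],
            layer="targeted_metabolome", scale="log2")
        with pytest.raises(ValueError, match="shared"):
            sf.cross_targeted_edges(x, targeted)
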