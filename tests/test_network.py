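"""Co-occurrence matrix, bipartite network and eigenvector centrality."""

import random

import networkx as nx
import numpy as np
import pytest

from conftest import matrix_from_counts, pairs_from_counts

from acuassoc.network import (
    BipartiteNetwork,
    build_matrix,
    build_network,
    eigenvector_centrality,
    export_network,
    frequency_table,
    load_network,
)
from acuassoc.preprocessing import extract_pairs
from acuassoc.synthetic import default_config, generate_cohort


def dense_centrality(graph: nx.Graph) -> dict[str, float]:
    """Independent oracle: per-component dense eigendecomposition, components
    scaled by spectral radius, global max 1."""
    comps = []
    for component in nx.connected_components(graph):
        nodes = sorted(component)
        w = nx.to_numpy_array(graph.subgraph(nodes), nodelist=nodes, weight="weight")
        values, vectors = np.linalg.eigh(w)
        v = np.abs(vectors[:, -1])
        comps.append((nodes, v, values[-1]))
    lam_max = max(ev for _, _, ev in comps)
    scores = {}
    for nodes, v, ev in comps:
        scale = (ev / lam_max) / v.max() if v.max() > 0 else 0.0
        for node, value in zip(nodes, v):
            scores[node] = value * scale
    peak = max(scores.values())
    return {n: s / peak for n, s in scores.items()}


def random_bipartite(rng: random.Random, max_nodes: int = 50) -> BipartiteNetwork:
    n_d = rng.randint(1, max_nodes // 2)
    n_a = rng.randint(1, max_nodes - n_d)
    graph = nx.Graph()
    for i in range(n_d):
        for j in range(n_a):
            if rng.random() < 0.3:
                graph.add_node(f"U{20+i}", kind="diagnosis")
                graph.add_node(f"A{j}", kind="acupoint")
                graph.add_edge(f"U{20+i}", f"A{j}", weight=rng.randint(1, 80))
    if graph.number_of_edges() == 0:
        graph.add_edge("U20", "A0", weight=1)
    return BipartiteNetwork(graph)


class TestBuildMatrix:
    def test_direct_counts(self):
        m = matrix_from_counts({("U61", "ST36"): 2, ("U61", "LI4"): 1, ("U62", "ST36"): 1})
        assert m.counts.at["U61", "ST36"] == 2
        assert m.counts.at["U61", "LI4"] == 1
        assert m.counts.at["U62", "ST36"] == 1
        assert m.counts.at["U62", "LI4"] == 0
        assert m.n_pairs == 4
        assert list(m.row_totals) == [3, 1]

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            build_matrix([])

    def test_sum_conserved_and_order_invariant(self):
        pairs = extract_pairs(generate_cohort(default_config(), seed=1))
        m = build_matrix(pairs)
        assert m.n_pairs == len(pairs)
        shuffled = list(pairs)
        random.Random(0).shuffle(shuffled)
        assert build_matrix(shuffled).counts.equals(m.counts)


class TestFrequencyTable:
    def test_percentages_round_half_up(self):
        m = matrix_from_counts({("U61", "ST36"): 32, ("U61", "BL1"): 428})
        table = frequency_table(m, top_k=2)
        st36 = table[table.acupoint == "ST36"].iloc[0]
        assert st36.row_total == 460
        assert st36.percent == 7.0

    def test_zero_count_percent(self):
        m = matrix_from_counts({("U61", "ST36"): 5, ("U62", "ST36"): 5, ("U62", "LI4"): 5})
        table = frequency_table(m, top_k=2)
        u61 = table[table.diagnosis == "U61"]
        assert list(u61.percent) == [100.0, 0.0]

    def test_ties_broken_by_code_order(self):
        m = matrix_from_counts({("U61", "ST36"): 3, ("U61", "LI4"): 3, ("U61", "BL2"): 3})
        table = frequency_table(m, top_k=3)
        assert list(table.acupoint) == ["BL2", "LI4", "ST36"]


class TestBuildNetwork:
    def test_strict_threshold_boundary(self):
        m = matrix_from_counts({("U61", "ST36"): 10, ("U61", "LI4"): 11})
        net = build_network(m, min_cooccurrence=10)
        assert not net.graph.has_edge("U61", "ST36")
        assert net.graph.edges[("U61", "LI4")]["weight"] == 11
        inclusive = build_network(m, min_cooccurrence=10, inclusive=True)
        assert inclusive.graph.has_edge("U61", "ST36")

    def test_all_below_threshold_gives_empty_network(self):
        m = matrix_from_counts({("U61", "ST36"): 3})
        net = build_network(m, min_cooccurrence=10)
        assert net.graph.number_of_nodes() == 0
        with pytest.raises(ValueError):
            eigenvector_centrality(net)

    def test_raising_threshold_never_adds_edges(self):
        pairs = extract_pairs(generate_cohort(default_config(n_doctors=20), seed=3))
        m = build_matrix(pairs)
        previous = None
        for threshold in (0, 2, 5, 10, 20):
            edges = {frozenset(e) for e in build_network(m, threshold).graph.edges()}
            if previous is not None:
                assert edges <= previous
            previous = edges


class TestCentrality:
    def test_star_closed_form(self):
        graph = nx.Graph()
        for i in range(4):
            graph.add_edge("ST36", f"U{61+i}", weight=1)
        scores = eigenvector_centrality(BipartiteNetwork(graph))
        assert scores["ST36"] == pytest.approx(1.0, abs=1e-10)
        for i in range(4):  # leaves sit at 1/sqrt(n) of the hub
            assert scores[f"U{61+i}"] == pytest.approx(0.5, abs=1e-8)

    def test_single_edge_symmetric(self):
        graph = nx.Graph([("U61", "ST36", {"weight": 17})])
        scores = eigenvector_centrality(BipartiteNetwork(graph))
        assert scores == pytest.approx({"U61": 1.0, "ST36": 1.0})

    def test_matches_dense_oracle_on_random_bipartite_graphs(self):
        for seed in range(25):
            net = random_bipartite(random.Random(seed))
            scores = eigenvector_centrality(net)
            oracle = dense_centrality(net.graph)
            for node in oracle:
                assert scores[node] == pytest.approx(oracle[node], abs=1e-8)

    def test_invariant_to_relabeling_and_weight_scaling(self):
        net = random_bipartite(random.Random(99))
        scores = eigenvector_centrality(net)
        scaled = nx.Graph()
        mapping = {n: f"x_{n}" for n in net.graph.nodes}
        for u, v, d in net.graph.edges(data=True):
            scaled.add_edge(mapping[u], mapping[v], weight=7.5 * d["weight"])
        scaled_scores = eigenvector_centrality(BipartiteNetwork(scaled))
        for node, score in scores.items():
            assert scaled_scores[mapping[node]] == pytest.approx(score, abs=1e-8)

    def test_hub_linked_to_all_diagnoses_scores_one(self):
        """An acupoint tied to every diagnosis with the largest weights is the
        network's most central node."""
        counts = {("U%d" % (60 + i), "ST36"): 50 for i in range(6)}
        counts.update({("U%d" % (60 + i), "BL%d" % (i + 1)): 12 for i in range(6)})
        net = build_network(matrix_from_counts(counts), 10)
        scores = eigenvector_centrality(net)
        assert scores["ST36"] == pytest.approx(1.0)
        assert max(scores, key=scores.get) == "ST36"


class TestExport:
    def test_gexf_parses_and_counts(self, tmp_path):
        graph = nx.Graph()
        graph.add_edge("U61", "ST36", weight=12)
        graph.add_edge("U61", "LI4", weight=15)
        for n in graph.nodes:
            graph.nodes[n]["kind"] = "diagnosis" if n.startswith("U") else "acupoint"
        net = BipartiteNetwork(graph)
        path = export_network(net, tmp_path / "net.gexf", "gexf")
        import xml.etree.ElementTree as ET

        root = ET.parse(path).getroot()
        ns = {"g": root.tag.split("}")[0].strip("{")}
        assert len(root.findall(".//g:node", ns)) == 3
        assert len(root.findall(".//g:edge", ns)) == 2

    @pytest.mark.parametrize("fmt", ["gexf", "graphml"])
    def test_round_trip_preserves_edges_weights_centrality(self, tmp_path, fmt):
        net = random_bipartite(random.Random(5))
        eigenvector_centrality(net)
        path = export_network(net, tmp_path / f"net.{fmt}", fmt)
        back = load_network(path, fmt)
        assert set(back.graph.edges()) == set(net.graph.edges())
        for u, v, d in net.graph.edges(data=True):
            assert float(back.graph.edges[u, v]["weight"]) == pytest.approx(d["weight"])
        for node, score in net.centrality.items():
            assert back.centrality[node] == pytest.approx(score, abs=1e-6)

    def test_unknown_format_raises(self, tmp_path):
        net = BipartiteNetwork(nx.Graph([("a", "b", {"weight": 1})]))
        with pytest.raises(ValueError):
            export_network(net, tmp_path / "x", "dot")
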