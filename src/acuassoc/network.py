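"""Diagnosis x acupoint co-occurrence counts, bipartite network and centrality.

The contingency matrix counts pair instances; edges with count above a
threshold (strict ``> 10`` by default, matching the convention that rare
pairings are noise at ~800-record scale) form a bipartite
diagnosis-acupoint graph.  Node importance is eigenvector centrality of the
symmetrized weighted adjacency: in the natural diagnosis->acupoint digraph
acupoints have zero out-degree and directed eigenvector centrality is
degenerate, so scores are computed on the undirected weighted graph and
max-normalized to 1.  Broadly indicated points shared by many patterns
(ST36, LI4) therefore sit at the top of the ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import networkx as nx
import numpy as np
import pandas as pd

from .preprocessing import PairInstance
from .vocab import acupoint_sort_key

__all__ = [
    "CooccurrenceMatrix",
    "BipartiteNetwork",
    "build_matrix",
    "frequency_table",
    "build_network",
    "eigenvector_centrality",
    "export_network",
    "load_network",
]

POWER_ITERATION_TOL = 1e-12
POWER_ITERATION_MAX_ITER = 10_000


@dataclass
class CooccurrenceMatrix:
    """Integer contingency counts with diagnoses as rows, acupoints as columns."""

    counts: pd.DataFrame  # index: diagnosis codes, columns: acupoint codes

    @property
    def diagnoses(self) -> list[str]:
        return list(self.counts.index)

    @property
    def acupoints(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def n_pairs(self) -> int:
        return int(self.counts.to_numpy().sum())


def build_matrix(pairs: Sequence[PairInstance]) -> CooccurrenceMatrix:
    """Count pair instances into a dense contingency matrix.

    Rows and columns are sorted (diagnoses lexicographically, acupoints in
    natural code order) so the layout is independent of pair order.
    """
    if len(pairs) == 0:
        raise ValueError("cannot build a co-occurrence matrix from zero pairs")
    frame = pd.DataFrame(
        {"diagnosis": [p.diagnosis for p in pairs], "acupoint": [p.acupoint for p in pairs]}
    )
    counts = frame.groupby(["diagnosis", "acupoint"]).size().unstack(fill_value=0)
    counts = counts.reindex(
        index=sorted(counts.index),
        columns=sorted(counts.columns, key=acupoint_sort_key),
    )
    return CooccurrenceMatrix(counts.astype(int))


def _round_half_up(value: float, decimals: int = 1) -> float:
    return float(Decimal(repr(value)).quantize(Decimal(f"1e-{decimals}"), ROUND_HALF_UP))


def frequency_table(matrix: CooccurrenceMatrix, top_k: int = 5) -> pd.DataFrame:
    """Per-diagnosis top-k acupoints with counts and percentages of row total.

    Percentages are ``100 * count / row_total`` rounded half-up to one
    decimal (the convention used in published prescription-frequency
    tables); ties in count are broken by acupoint code order.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    rows = []
    for diagnosis in matrix.diagnoses:
        row = matrix.counts.loc[diagnosis]
        total = int(row.sum())
        ranked = sorted(
            row.items(), key=lambda kv: (-kv[1], acupoint_sort_key(kv[0]))
        )[:top_k]
        for rank, (acupoint, count) in enumerate(ranked, start=1):
            pct = _round_half_up(100.0 * count / total) if total else 0.0
            rows.append(
                {
                    "diagnosis": diagnosis,
                    "rank": rank,
                    "acupoint": acupoint,
                    "count": int(count),
                    "row_total": total,
                    "percent": pct,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class BipartiteNetwork:
    """Thresholded diagnosis-acupoint graph with optional centrality scores."""

    graph: nx.Graph
    min_cooccurrence: float = 10
    centrality: dict[str, float] = field(default_factory=dict)

    @property
    def diagnoses(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d.get("kind") == "diagnosis"]

    @property
    def acupoints(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d.get("kind") == "acupoint"]


def build_network(
    matrix: CooccurrenceMatrix,
    min_cooccurrence: float = 10,
    inclusive: bool = False,
) -> BipartiteNetwork:
    """Keep edges whose count exceeds the threshold (strictly, by default).

    Isolated nodes are not present: a node exists iff it has a surviving
    edge.  ``inclusive=True`` switches the comparison to ``>=``.
    """
    if min_cooccurrence < 0:
        raise ValueError("min_cooccurrence must be non-negative")
    graph = nx.Graph()
    counts = matrix.counts
    for diagnosis in counts.index:
        for acupoint in counts.columns:
            w = int(counts.at[diagnosis, acupoint])
            keep = w >= min_cooccurrence if inclusive else w > min_cooccurrence
            if keep and w > 0:
                graph.add_node(diagnosis, kind="diagnosis", bipartite=0)
                graph.add_node(acupoint, kind="acupoint", bipartite=1)
                graph.add_edge(diagnosis, acupoint, weight=w)
    return BipartiteNetwork(graph, min_cooccurrence=min_cooccurrence)


def _power_iteration(weights: np.ndarray) -> tuple[np.ndarray, float]:
    """Perron vector and value of a symmetric non-negative matrix.

    Iterates on ``W + sI`` (s = max row sum) so the Perron root strictly
    dominates in magnitude even on bipartite graphs, whose +/-lambda_max
    spectral pair makes plain power iteration oscillate.  The shift changes
    neither eigenvectors nor the ordering of eigenvalues.
    """
    n = weights.shape[0]
    shift = float(weights.sum(axis=1).max())
    if shift == 0.0:  # no edges within this block
        return np.zeros(n), 0.0
    shifted = weights + shift * np.eye(n)
    v = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(POWER_ITERATION_MAX_ITER):
        v = shifted @ v
        v /= np.linalg.norm(v)
        # converged when the relative eigen-residual is below tolerance
        image = weights @ v
        eigenvalue = float(v @ image)
        if np.max(np.abs(image - eigenvalue * v)) <= POWER_ITERATION_TOL * max(eigenvalue, 1e-300):
            break
    v = np.abs(v)  # Perron vector of a connected non-negative block is positive
    eigenvalue = float(v @ weights @ v)
    return v, eigenvalue


def eigenvector_centrality(network: BipartiteNetwork) -> dict[str, float]:
    """Max-normalized eigenvector centrality on the symmetrized weighted graph.

    Disconnected graphs are handled per connected component: each
    component's Perron vector is scaled by its spectral radius relative to
    the global maximum, then all scores are normalized so the top node is 1.
    Scores are also written onto the graph nodes as the ``centrality``
    attribute and cached on the network object.
    """
    graph = network.graph
    if graph.number_of_edges() == 0:
        raise ValueError("centrality is undefined on an empty network")
    scores: dict[str, float] = {}
    component_results = []
    for component in nx.connected_components(graph):
        nodes = sorted(component)
        sub = graph.subgraph(nodes)
        weights = nx.to_numpy_array(sub, nodelist=nodes, weight="weight")
        vector, eigenvalue = _power_iteration(weights)
        component_results.append((nodes, vector, eigenvalue))
    lam_max = max(ev for _, _, ev in component_results)
    for nodes, vector, eigenvalue in component_results:
        top = vector.max()
        scale = (eigenvalue / lam_max) / top if top > 0 else 0.0
        for node, value in zip(nodes, vector):
            scores[node] = float(value * scale)
    peak = max(scores.values())
    if peak > 0:
        scores = {n: s / peak for n, s in scores.items()}
    nx.set_node_attributes(graph, scores, "centrality")
    network.centrality = scores
    return scores


def export_network(
    network: BipartiteNetwork, path: Union[str, Path], format: str = "gexf"
) -> Path:
    """Write the graph (node kind, edge weight, centrality) as GEXF or GraphML."""
    path = Path(path)
    if not network.centrality and network.graph.number_of_edges() > 0:
        eigenvector_centrality(network)
    if format == "gexf":
        nx.write_gexf(network.graph, path)
    elif format == "graphml":
        nx.write_graphml(network.graph, path)
    else:
        raise ValueError(f"unsupported export format: {format!r}")
    return path


def load_network(path: Union[str, Path], format: str = "gexf") -> BipartiteNetwork:
    path = Path(path)
    if format == "gexf":
        graph = nx.read_gexf(path)
    elif format == "graphml":
        graph = nx.read_graphml(path)
    else:
        raise ValueError(f"unsupported export format: {format!r}")
    centrality = {
        n: float(d["centrality"]) for n, d in graph.nodes(data=True) if "centrality" in d
    }
    return BipartiteNetwork(nx.Graph(graph), centrality=centrality)
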