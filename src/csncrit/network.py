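"""Threshold networks, Erdos-Renyi nulls, centralities and assortativity.

A chemical space network at cut-off ``t`` keeps an (unweighted) edge for
every molecule pair with similarity strictly greater than ``t``. Its null
model is the uniform G(N, E) random graph with the same number of nodes and
edges, so the two have exactly equal mean degree and any structural
difference (giant-component location, assortativity) is attributable to the
similarity geometry rather than edge density.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from csncrit.mcs import SimilarityStore


@dataclass
class ThresholdNetwork:
    """Unweighted graph obtained by thresholding a similarity store."""

    graph: nx.Graph
    threshold: float | None = None

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def e(self) -> int:
        return self.graph.number_of_edges()

    @property
    def e_max(self) -> int:
        n = self.n_nodes
        return n * (n - 1) // 2

    @property
    def p(self) -> float:
        """Connection probability p = E / E_max."""
        return self.e / self.e_max if self.e_max else 0.0

    def to_edgelist_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["node_i", "node_j"])
            for u, v in sorted(self.graph.edges()):
                writer.writerow([u, v])

    def to_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, str(path))


@dataclass
class CentralityProfile:
    """Per-node degree, betweenness and eigenvector centrality."""

    nodes: list
    degree: np.ndarray
    betweenness: np.ndarray
    eigenvector: np.ndarray

    @property
    def mean_degree(self) -> float:
        return float(self.degree.mean()) if len(self.degree) else 0.0

    @property
    def mean_betweenness(self) -> float:
        return float(self.betweenness.mean()) if len(self.betweenness) else 0.0

    @property
    def mean_eigenvector(self) -> float:
        return float(self.eigenvector.mean()) if len(self.eigenvector) else 0.0

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["node_id", "degree", "betweenness", "eigenvector"])
            for i, node in enumerate(self.nodes):
                writer.writerow(
                    [node, int(self.degree[i]), f"{self.betweenness[i]:.8g}",
                     f"{self.eigenvector[i]:.8g}"]
                )


def build_network(store: SimilarityStore, t: float) -> ThresholdNetwork:
    """Build the threshold network with edges where s_ij > t (strict).

    Every molecule is a node, connected or not, so N is constant across the
    sweep. ``t`` must be at or above the store floor: pairs below the floor
    were never computed and cannot be thresholded.
    """
    if t < store.floor:
        raise ValueError(
            f"threshold {t} is below the store floor {store.floor}; "
            "similarities under the floor were not computed"
        )
    g = nx.Graph()
    g.add_nodes_from(range(store.n_molecules))
    g.add_edges_from((i, j) for (i, j), s in store.entries.items() if s > t)
    return ThresholdNetwork(graph=g, threshold=t)


def sample_er(n: int, e: int, seed: int | np.random.Generator | None = None) -> ThresholdNetwork:
    """Uniform G(N, E): exactly ``e`` distinct edges among the n(n-1)/2 pairs."""
    e_max = n * (n - 1) // 2
    if not 0 <= e <= e_max:
        raise ValueError(f"edge count {e} outside [0, {e_max}] for n={n}")
    if isinstance(seed, np.random.Generator):
        seed = int(seed.integers(2**31))
    g = nx.gnm_random_graph(n, e, seed=seed)
    return ThresholdNetwork(graph=g, threshold=None)


def _eigenvector_centrality(
    g: nx.Graph,
    nodes: list,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> np.ndarray:
    """Principal adjacency eigenvector by power iteration on the largest component.

    Thresholded similarity networks are highly fragmented; the convention
    here is to compute the eigenvector on the largest connected component,
    set zeros elsewhere, and return a unit-L2-norm vector. An edgeless graph
    yields the uniform unit vector.
    """
    n = len(nodes)
    if n == 0:
        return np.zeros(0)
    if g.number_of_edges() == 0:
        return np.full(n, 1.0 / math.sqrt(n))
    comp = max(nx.connected_components(g), key=len)
    comp_nodes = sorted(comp)
    idx = {node: k for k, node in enumerate(comp_nodes)}
    a = nx.to_numpy_array(g.subgraph(comp_nodes), nodelist=comp_nodes)
    x = np.full(len(comp_nodes), 1.0 / math.sqrt(len(comp_nodes)))
    for _ in range(max_iter):
        y = a @ x
        norm = np.linalg.norm(y)
        if norm == 0.0:
            break
        y /= norm
        if np.linalg.norm(y - x) < tol:
            x = y
            break
        x = y
    full = np.zeros(n)
    pos = {node: i for i, node in enumerate(nodes)}
    for node in comp_nodes:
        full[pos[node]] = x[idx[node]]
    return full


def centrality_profile(net: ThresholdNetwork) -> CentralityProfile:
    """Degree, unnormalised betweenness and eigenvector centrality.

    Betweenness counts, for each node i, the fraction of shortest paths
    between every other pair (s, t) that pass through i, with each
    unordered pair counted once and no normalisation (downstream curves are
    min-max rescaled anyway).
    """
    g = net.graph
    nodes = sorted(g.nodes())
    degree = np.array([g.degree(v) for v in nodes], dtype=float)
    bet = nx.betweenness_centrality(g, normalized=False)
    betweenness = np.array([bet[v] for v in nodes])
    eigenvector = _eigenvector_centrality(g, nodes)
    return CentralityProfile(
        nodes=nodes, degree=degree, betweenness=betweenness, eigenvector=eigenvector
    )


def giant_component_fraction(net: ThresholdNetwork) -> float:
    """Size of the largest connected component divided by N."""
    if net.n_nodes == 0:
        raise ValueError("empty network")
    largest = max((len(c) for c in nx.connected_components(net.graph)), default=0)
    return largest / net.n_nodes


def assortativity(net: ThresholdNetwork) -> float | None:
    """Degree assortativity: Pearson correlation of end-point degrees.

    Computed over the directed edge list (each undirected edge contributes
    both orientations). Returns ``None`` — an explicit undefined marker,
    never zero — when the graph has no edges or all end-point degrees are
    equal (zero variance).
    """
    if net.e == 0:
        return None
    degrees = dict(net.graph.degree())
    x, y = [], []
    for u, v in net.graph.edges():
        x.extend((degrees[u], degrees[v]))
        y.extend((degrees[v], degrees[u]))
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.var(x) == 0.0 or np.var(y) == 0.0:
        return None
    r = float(np.corrcoef(x, y)[0, 1])
    return r
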