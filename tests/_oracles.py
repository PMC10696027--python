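"""Independent oracles used only by the tests.

These deliberately take different routes from the package implementation:
the MCS oracle enumerates connected node subsets and asks networkx's VF2
matcher for induced-subgraph isomorphism, instead of branch-and-bound.
"""

import itertools

import networkx as nx
from networkx.algorithms import isomorphism as iso

from csncrit.mcs import MolecularGraph


def graph_to_nx(g: MolecularGraph) -> nx.Graph:
    out = nx.Graph()
    for i, (el, _aromatic) in enumerate(g.atoms):
        out.add_node(i, el=el)
    for (i, j), order in g.bonds.items():
        out.add_edge(i, j, order=order)
    return out


def brute_force_mcs(a: MolecularGraph, b: MolecularGraph) -> int:
    """Largest connected induced common subgraph by exhaustive enumeration."""
    if a.size > b.size:
        a, b = b, a
    nx_a, nx_b = graph_to_nx(a), graph_to_nx(b)
    node_match = iso.categorical_node_match("el", None)
    edge_match = iso.categorical_edge_match("order", None)
    for k in range(min(a.size, b.size), 0, -1):
        for subset in itertools.combinations(range(a.size), k):
            sub = nx_a.subgraph(subset)
            if not nx.is_connected(sub):
                continue
            gm = iso.GraphMatcher(nx_b, sub, node_match=node_match, edge_match=edge_match)
            if gm.subgraph_is_isomorphic():
                return k
    return 0


def er_giant_fraction_theory(c: float, tol: float = 1e-12) -> float:
    """Solve S = 1 - exp(-c S) by fixed-point iteration (S > 0 branch)."""
    s = 0.5
    for _ in range(10_000):
        s_new = 1.0 - pow(2.718281828459045, -c * s)
        if abs(s_new - s) < tol:
            return s_new
        s = s_new
    return s
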