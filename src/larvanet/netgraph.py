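"""Graph-theoretic layer over dispersal-proportion matrices.

Regions become nodes of a directed graph; an edge o→s exists when the
dispersal proportion from o to s reaches a threshold (default 0.1%,
discarding connections carrying a negligible share of larvae).
Self-loops are never edges and exogenous-island columns are excluded
before the graph is built, so all metrics describe within-island
structure: edge density, unweighted shortest paths (infinite lengths
noted but excluded from the mean), weakly/strongly connected
components, cut nodes (weak sense), in-/out-degree, and betweenness
centrality.  For proportion-weighted betweenness the edge cost is
−log(proportion), which makes a path's cost the negative log of its
multiplicative dispersal probability — the "shortest" path is the most
probable multi-step dispersal route.  A reciprocal (1/proportion) cost
is available as an alternative convention.

networkx supplies the algorithms; the surrounding tests validate every
metric against brute-force enumeration on small random digraphs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "RegionGraph",
    "build_graph",
    "edge_density",
    "shortest_paths",
    "components",
    "cut_nodes",
    "degrees",
    "betweenness",
]


@dataclass
class RegionGraph:
    """A directed region graph with dispersal-proportion edge weights."""

    graph: nx.DiGraph
    threshold: float

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_graph(P: pd.DataFrame, threshold: float = 0.001) -> RegionGraph:
    """Directed graph from a square proportion matrix.

    An edge o→s exists iff P[o, s] ≥ threshold and o ≠ s; NaN entries
    (undefined proportions) never become edges.  All nodes of ``P``
    are kept, including isolated ones.
    """
    P = pd.DataFrame(P, dtype=float)
    if list(P.index) != list(P.columns):
        raise ValueError("proportion matrix must be square with identical labels")
    G = nx.DiGraph()
    G.add_nodes_from(P.index)
    for o in P.index:
        for s in P.columns:
            if o == s:
                continue
            w = P.at[o, s]
            if np.isfinite(w) and w >= threshold and w > 0:
                G.add_edge(o, s, weight=float(w))
    return RegionGraph(graph=G, threshold=threshold)


def _graph(G) -> nx.DiGraph:
    return G.graph if isinstance(G, RegionGraph) else G


def edge_density(G, nodes: Optional[Iterable] = None, mode: str = "directed") -> float:
    """Realized fraction of possible edges on a node subset.

    directed: |E| / n(n−1); undirected: edges regardless of direction
    over n(n−1)/2 (parallel opposite edges collapse to one).  A subset
    of fewer than two nodes is undefined (NaN).
    """
    g = _graph(G)
    sub = g.subgraph(list(nodes)) if nodes is not None else g
    n = sub.number_of_nodes()
    if n < 2:
        return float("nan")
    if mode == "directed":
        return sub.number_of_edges() / (n * (n - 1))
    if mode == "undirected":
        und = {frozenset(e) for e in sub.edges() if e[0] != e[1]}
        return len(und) / (n * (n - 1) / 2)
    raise ValueError(f"unknown mode {mode!r}")


def shortest_paths(G) -> tuple[pd.DataFrame, float]:
    """Unweighted directed shortest-path lengths between all node pairs.

    Returns (matrix, mean).  Unreachable pairs are recorded as inf and
    excluded from the mean, which averages finite off-diagonal lengths.
    """
    g = _graph(G)
    nodes = list(g.nodes)
    L = pd.DataFrame(np.inf, index=nodes, columns=nodes)
    for src, dists in nx.all_pairs_shortest_path_length(g):
        for dst, d in dists.items():
            L.at[src, dst] = float(d)
    off = L.to_numpy()[~np.eye(len(nodes), dtype=bool)] if nodes else np.array([])
    finite = off[np.isfinite(off)]
    mean = float(finite.mean()) if finite.size else float("nan")
    return L, mean


def components(G, mode: str = "weak") -> pd.Series:
    """Component label per node (weakly or strongly connected)."""
    g = _graph(G)
    if mode == "weak":
        comps = nx.weakly_connected_components(g)
    elif mode == "strong":
        comps = nx.strongly_connected_components(g)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    label = {}
    for k, comp in enumerate(sorted(comps, key=lambda c: sorted(map(str, c)))):
        for node in comp:
            label[node] = k
    return pd.Series(label, name=f"{mode}_component").reindex(list(g.nodes))


def cut_nodes(G) -> set:
    """Nodes whose removal strictly increases the number of weakly
    connected components among the remaining nodes."""
    g = _graph(G)
    base = nx.number_weakly_connected_components(g)
    out = set()
    for v in list(g.nodes):
        h = g.subgraph([n for n in g.nodes if n != v])
        if h.number_of_nodes() and nx.number_weakly_connected_components(h) > base:
            out.add(v)
    return out


def degrees(G) -> pd.DataFrame:
    """In-/out-degree per node plus min-max normalized (0–1) variants."""
    g = _graph(G)
    nodes = list(g.nodes)
    din = pd.Series({n: g.in_degree(n) for n in nodes}, dtype=float)
    dout = pd.Series({n: g.out_degree(n) for n in nodes}, dtype=float)

    def norm(s: pd.Series) -> pd.Series:
        span = s.max() - s.min()
        if span == 0 or not len(s):
            return s * 0.0
        return (s - s.min()) / span

    return pd.DataFrame(
        {"in_degree": din, "out_degree": dout, "in_degree_norm": norm(din), "out_degree_norm": norm(dout)}
    )


def betweenness(G, weighting: str = "proportion") -> pd.Series:
    """Shortest-path betweenness centrality per node (endpoints excluded,
    ties split fractionally, unnormalized counts).

    weighting="unweighted" counts hops; "proportion" uses edge cost
    −log(weight) so high-proportion dispersal edges are preferred;
    "reciprocal" uses cost 1/weight.  Nonpositive weights are invalid.
    """
    g = _graph(G)
    if weighting == "unweighted":
        bc = nx.betweenness_centrality(g, normalized=False)
        return pd.Series(bc, name="betweenness").reindex(list(g.nodes))
    if weighting not in ("proportion", "reciprocal"):
        raise ValueError(f"unknown weighting {weighting!r}")
    h = g.copy()
    for _, _, d in h.edges(data=True):
        w = d.get("weight")
        if w is None or w <= 0:
            raise ValueError("proportion weighting requires positive edge weights")
        d["cost"] = -math.log(w) if weighting == "proportion" else 1.0 / w
        # -log of proportions in (0, 1] is >= 0; shift-free costs are safe
        if d["cost"] < 0:
            raise ValueError("edge proportion above 1 produces a negative cost")
    bc = nx.betweenness_centrality(h, weight="cost", normalized=False)
    return pd.Series(bc, name="betweenness").reindex(list(g.nodes))
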