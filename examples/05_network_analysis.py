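"""Graph-theoretic analysis of a region-level dispersal network.

Builds the directed region graph from forward settlement proportions
(edges below 0.1% of dispersal are discarded), then computes edge
density, shortest paths, connected components, cut nodes, degrees, and
proportion-weighted betweenness centrality.
"""

from larvanet.connectivity import build_matrix, forward_proportion
from larvanet.netgraph import (
    betweenness,
    build_graph,
    components,
    cut_nodes,
    degrees,
    edge_density,
    shortest_paths,
)
from larvanet.scenarios import directional_ssi_run, reef_ring_setup

out = directional_ssi_run(seed=1)
_, _, sites = reef_ring_setup(habitat_mix={"intertidal": 1.0}, seed=1)
M = build_matrix(out["records"], sites, level="region")
P = forward_proportion(M.focal_square()).fillna(0.0)

G = build_graph(P, threshold=0.001)
print(f"graph: {len(G.nodes)} regions, {G.n_edges} edges at the 0.1% threshold")
print(f"edge density (directed): {edge_density(G):.2f}")

L, mean_path = shortest_paths(G)
print(f"mean shortest path (finite pairs only): {mean_path:.2f} generations")

scc = components(G, "strong")
print(f"strongly connected components: {scc.nunique()} "
      f"(largest holds {scc.value_counts().max()} regions)")
print(f"cut nodes (removal fragments the network): {sorted(cut_nodes(G)) or 'none'}")

table = degrees(G).join(betweenness(G))
print("\nper-region degrees and weighted betweenness:")
print(table.sort_values("betweenness", ascending=False).round(2).head(8))
# High out-degree regions seed many others (larval sources); high
# betweenness marks multi-generation dispersal pathways: under an
# eastward drift both concentrate on the upstream/mid flanks.
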