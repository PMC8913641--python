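"""Global network attributes and node/edge centralities.

Definitions follow Cytoscape NetworkAnalyzer conventions on the
unweighted topology: mean local clustering coefficient (degree < 2
contributes 0 by default), Freeman-style degree centralization
(n/(n-2)) * (k_max/(n-1) - density), count of ordered connected node
pairs ("shortest paths"), characteristic path length over finite
distances, mean neighbour count 2E/n, density 2E/(n(n-1)) and
heterogeneity = coefficient of variation of the degree sequence.

Centralities: NDC = degree; NCC = 1 / mean hop distance to reachable
nodes; NBC = Brandes betweenness normalised to [0,1] by (n-1)(n-2)/2;
EBC = unnormalised edge betweenness summed over unordered connected
pairs (endpoint pairs included).  Edge weights (|r|) are carried as
attributes only; an optional weighted-distance mode treats the distance
between nodes as the sum of edge weights along a path.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import islice

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "GlobalNetworkAttributes",
    "CentralityTable",
    "global_attributes",
    "node_centralities",
    "edge_betweenness",
    "communities",
]


@dataclass(frozen=True)
class GlobalNetworkAttributes:
    """The global statistics reported per turbidity-class network."""

    n_nodes: int
    n_edges: int
    clustering_coefficient: float
    network_centralization: float | None
    shortest_paths_count: int
    connected_pair_fraction: float
    characteristic_path_length: float | None
    mean_neighbors: float
    density: float
    heterogeneity: float

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "clustering_coefficient": self.clustering_coefficient,
            "network_centralization": self.network_centralization,
            "shortest_paths_count": self.shortest_paths_count,
            "connected_pair_fraction": self.connected_pair_fraction,
            "characteristic_path_length": self.characteristic_path_length,
            "mean_neighbors": self.mean_neighbors,
            "density": self.density,
            "heterogeneity": self.heterogeneity,
        }


@dataclass(frozen=True)
class CentralityTable:
    """Per-node NDC/NCC/NBC and per-edge EBC records.

    ``nodes``: columns taxon, ndc, ncc, nbc.
    ``edges``: columns source, target, r, sign, weight, ebc.
    """

    nodes: pd.DataFrame
    edges: pd.DataFrame


def _working_graph(net: nx.Graph, include_isolated: bool) -> nx.Graph:
    if include_isolated:
        return net
    keep = [n for n, d in net.degree() if d > 0]
    return net.subgraph(keep)


def global_attributes(
    net: nx.Graph,
    include_isolated: bool = True,
    clustering_degree_lt2: str = "zero",
) -> GlobalNetworkAttributes:
    """Compute the global attribute set for one network.

    ``include_isolated=False`` removes degree-0 nodes first (the two
    conventions differ in density and mean neighbours whenever isolated
    taxa exist).  ``clustering_degree_lt2`` chooses whether nodes of
    degree < 2 count as 0 in the clustering average ("zero") or are
    left out ("exclude").
    """
    g = _working_graph(net, include_isolated)
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError(f"need >= 2 nodes after the isolated-node policy, got {n}")
    e = g.number_of_edges()
    degrees = np.array([d for _, d in g.degree()], dtype=float)

    density = 2 * e / (n * (n - 1))
    mean_neighbors = 2 * e / n
    mean_deg = degrees.mean()
    heterogeneity = float(degrees.std(ddof=0) / mean_deg) if mean_deg > 0 else 0.0

    local = nx.clustering(g)  # 0 for degree < 2
    if clustering_degree_lt2 == "exclude":
        vals = [c for node, c in local.items() if g.degree(node) >= 2]
        clustering = float(np.mean(vals)) if vals else 0.0
    elif clustering_degree_lt2 == "zero":
        clustering = float(np.mean(list(local.values())))
    else:
        raise ValueError("clustering_degree_lt2 must be 'zero' or 'exclude'")

    if n < 3:
        centralization = None
    else:
        centralization = float((n / (n - 2)) * (degrees.max() / (n - 1) - density))

    total = 0
    dist_sum = 0.0
    for _, lengths in nx.all_pairs_shortest_path_length(g):
        for d in lengths.values():
            if d > 0:
                total += 1
                dist_sum += d
    cpl = dist_sum / total if total else None
    return GlobalNetworkAttributes(
        n_nodes=n,
        n_edges=e,
        clustering_coefficient=clustering,
        network_centralization=centralization,
        shortest_paths_count=total,
        connected_pair_fraction=total / (n * (n - 1)),
        characteristic_path_length=cpl,
        mean_neighbors=mean_neighbors,
        density=density,
        heterogeneity=heterogeneity,
    )


def node_centralities(net: nx.Graph, weighted: bool = False) -> CentralityTable:
    """NDC, NCC and NBC per node plus EBC per edge.

    With ``weighted=True`` distances are sums of the |r| edge weights
    instead of hop counts (non-default; the reported study statistics
    are topological).
    """
    weight = "weight" if weighted else None
    n = net.number_of_nodes()
    ndc = dict(net.degree())
    if weighted:
        ncc = nx.closeness_centrality(net, distance="weight", wf_improved=False)
    else:
        ncc = nx.closeness_centrality(net, wf_improved=False)
    nbc = nx.betweenness_centrality(net, normalized=n > 2, weight=weight)
    nodes = pd.DataFrame(
        {
            "taxon": sorted(net.nodes, key=str),
        }
    )
    nodes["ndc"] = [ndc[t] for t in nodes["taxon"]]
    nodes["ncc"] = [ncc[t] for t in nodes["taxon"]]
    nodes["nbc"] = [nbc[t] for t in nodes["taxon"]]
    return CentralityTable(nodes=nodes, edges=edge_betweenness(net, weighted=weighted).edges)


def edge_betweenness(net: nx.Graph, weighted: bool = False) -> CentralityTable:
    """Unnormalised edge betweenness per edge (node table left empty).

    For each edge, the sum over unordered connected node pairs of the
    fraction of that pair's shortest paths traversing the edge;
    endpoint pairs contribute.
    """
    weight = "weight" if weighted else None
    ebc = nx.edge_betweenness_centrality(net, normalized=False, weight=weight)
    rows = []
    for (u, v), val in ebc.items():
        a, b = sorted((u, v), key=str)
        d = net.edges[u, v]
        rows.append(
            {
                "source": a,
                "target": b,
                "r": d.get("r"),
                "sign": d.get("sign"),
                "weight": d.get("weight"),
                "ebc": val,
            }
        )
    rows.sort(key=lambda r: (str(r["source"]), str(r["target"])))
    edges = pd.DataFrame(rows, columns=["source", "target", "r", "sign", "weight", "ebc"])
    return CentralityTable(nodes=pd.DataFrame(columns=["taxon", "ndc", "ncc", "nbc"]), edges=edges)


# ---------------------------------------------------------------------------
# Divisive edge-betweenness clustering (Girvan-Newman)
# ---------------------------------------------------------------------------

def _max_ebc_edge(g: nx.Graph) -> tuple:
    """Edge of maximal betweenness; ties broken by lexicographic edge name."""
    ebc = nx.edge_betweenness_centrality(g, normalized=False)
    best = max(ebc.values())
    candidates = [tuple(sorted(e, key=str)) for e, v in ebc.items() if v >= best - 1e-12]
    return min(candidates)


def communities(net: nx.Graph, k: int | None = None) -> list[frozenset]:
    """Partition nodes by divisive removal of maximum-EBC edges.

    Removes the highest-edge-betweenness edge (lexicographic tie-break)
    until the graph splits into ``k`` connected components; with ``k``
    unset, returns the partition of maximal modularity along the
    divisive sequence (evaluated on the original unweighted topology).
    Deterministic.
    """
    if net.number_of_edges() < 1:
        raise ValueError("communities requires a network with at least one edge")
    n = net.number_of_nodes()
    if k is not None:
        if k > n:
            raise ValueError(f"k={k} exceeds the number of nodes ({n})")
        if k < 1:
            raise ValueError("k must be >= 1")

    def comps(g: nx.Graph) -> list[frozenset]:
        return sorted((frozenset(c) for c in nx.connected_components(g)), key=lambda c: sorted(map(str, c))[0])

    work = net.copy()
    current = comps(work)
    if k is not None and len(current) >= k:
        return current

    best_partition = current
    best_q = nx.community.modularity(net, current, weight=None)
    while work.number_of_edges():
        work.remove_edge(*_max_ebc_edge(work))
        parts = comps(work)
        if len(parts) > len(current):
            current = parts
            if k is not None and len(parts) >= k:
                return parts
            q = nx.community.modularity(net, parts, weight=None)
            if q > best_q + 1e-12:
                best_q, best_partition = q, parts
    if k is not None:
        return current  # k unreachable only if k > number of nodes, already guarded
    return best_partition


def fragmentation_after_removal(net: nx.Graph, node) -> int:
    """Ordered connected pair count after deleting one node.

    Used for keystone-taxon screening: removing a high-betweenness
    taxon never increases this count.
    """
    g = net.copy()
    g.remove_node(node)
    return sum(
        1
        for _, lengths in nx.all_pairs_shortest_path_length(g)
        for d in lengths.values()
        if d > 0
    )
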