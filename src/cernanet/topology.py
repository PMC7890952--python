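"""Node and edge topological properties of the constructed network.

Degree, betweenness (unnormalized and normalized), closeness and clustering
coefficient per node, plus shortest-path edge betweenness.  Definitions are
unweighted/undirected; closeness on disconnected graphs is computed within
each node's component (harmonic variant by flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd


@dataclass(frozen=True)
class TopologyTable:
    nodes: pd.DataFrame  # degree, betweenness, betweenness_norm, closeness, clustering
    edges: pd.DataFrame  # gene1, gene2, edge_betweenness


def compute_topology(network: nx.Graph, harmonic: bool = False) -> TopologyTable:
    """Compute the four node properties and edge betweenness.

    ``harmonic=True`` swaps within-component closeness for harmonic
    centrality (scaled by 1/(n-1)).  Degree-<2 nodes have clustering 0.
    """
    nodes = sorted(network.nodes)
    if not nodes:
        return TopologyTable(
            nodes=pd.DataFrame(
                columns=[
                    "node", "degree", "betweenness", "betweenness_norm",
                    "closeness", "clustering",
                ]
            ),
            edges=pd.DataFrame(columns=["gene1", "gene2", "edge_betweenness"]),
        )
    bet_raw = nx.betweenness_centrality(network, normalized=False)
    bet_norm = nx.betweenness_centrality(network, normalized=True)
    if harmonic:
        n = network.number_of_nodes()
        close = nx.harmonic_centrality(network)
        close = {k: v / (n - 1) if n > 1 else 0.0 for k, v in close.items()}
    else:
        # wf_improved=False gives plain within-component closeness
        close = nx.closeness_centrality(network, wf_improved=False)
    clust = nx.clustering(network)
    node_df = pd.DataFrame(
        {
            "node": nodes,
            "degree": [network.degree(n) for n in nodes],
            "betweenness": [bet_raw[n] for n in nodes],
            "betweenness_norm": [bet_norm[n] for n in nodes],
            "closeness": [close[n] for n in nodes],
            "clustering": [clust[n] for n in nodes],
        }
    )
    ebet = nx.edge_betweenness_centrality(network, normalized=False)
    edge_rows = [
        {"gene1": u, "gene2": v, "edge_betweenness": ebet[(u, v)]}
        for u, v in (tuple(sorted(e)) for e in network.edges)
    ]
    edge_df = pd.DataFrame(
        sorted(edge_rows, key=lambda r: (r["gene1"], r["gene2"])),
        columns=["gene1", "gene2", "edge_betweenness"],
    )
    return TopologyTable(nodes=node_df, edges=edge_df)


def topology_distribution(
    table: TopologyTable, prop: str, bins: int = 20
) -> pd.DataFrame:
    """Binned counts of a node property (or ``edge_betweenness``)."""
    if prop == "edge_betweenness":
        values = table.edges["edge_betweenness"].to_numpy(dtype=float)
    elif prop in table.nodes.columns and prop != "node":
        values = table.nodes[prop].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown topology property {prop!r}")
    if values.size == 0:
        return pd.DataFrame(columns=["bin_left", "bin_right", "count"])
    counts, edges = np.histogram(values, bins=bins)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
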