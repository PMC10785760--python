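"""Weighted association networks with multilevel community detection.

Both the exposure co-correlation network and the pathway–immune-marker
integration network are undirected weighted graphs partitioned by
multilevel (Louvain-style) modularity maximization. Communities are
relabeled deterministically (0, 1, ... ordered by smallest member node)
so a fixed seed yields byte-identical exports.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd


def detect_communities(graph: nx.Graph, seed: int = 0, weight: str = "weight") -> dict:
    """Louvain modularity maximization; returns node → contiguous label."""
    if graph.number_of_nodes() == 0:
        return {}
    if graph.number_of_edges() == 0:
        parts = [{n} for n in graph.nodes]
    else:
        parts = nx.community.louvain_communities(graph, weight=weight, seed=seed)
    parts = sorted((sorted(p, key=str) for p in parts), key=lambda p: str(p[0]))
    labels = {}
    for i, part in enumerate(parts):
        for node in part:
            labels[node] = i
    nx.set_node_attributes(graph, labels, "community")
    return labels


def modularity(graph: nx.Graph, labels: dict, weight: str = "weight") -> float:
    """Weighted modularity of a labeling (0.0 for an edgeless graph)."""
    if graph.number_of_edges() == 0:
        return 0.0
    groups: dict[int, set] = {}
    for node, lab in labels.items():
        groups.setdefault(lab, set()).add(node)
    return nx.community.modularity(graph, groups.values(), weight=weight)


def export_network(graph: nx.Graph, prefix: Path | str) -> None:
    """Write GraphML plus a Cytoscape-loadable edge TSV."""
    prefix = Path(prefix)
    nx.write_graphml(graph, f"{prefix}.graphml")
    rows = []
    for u, v, data in graph.edges(data=True):
        rows.append(
            {
                "source": u,
                "target": v,
                "weight": data.get("weight"),
                "community_source": graph.nodes[u].get("community"),
                "community_target": graph.nodes[v].get("community"),
            }
        )
    pd.DataFrame(
        rows, columns=["source", "target", "weight", "community_source", "community_target"]
    ).to_csv(f"{prefix}_edges.tsv", sep="\t", index=False)
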