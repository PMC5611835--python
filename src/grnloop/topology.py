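"""Topology analytics on aggregated and consensus networks.

Degree-based hub detection (strictly above an empirical degree quantile),
connected-component extraction around a gene of interest, the max-union
consensus merge of per-dataset aggregated networks, and the long-format
pathway-significance landscape used to compare enrichment levels between the
individual aggregated networks and the consensus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .enrichment import EnrichmentResult
from .network import WeightedNetwork


@dataclass
class HubReport:
    dataset_id: str
    hubs: List[Tuple[str, int]]  # (gene, degree), degree descending
    quantile_threshold: float


def degrees(net: WeightedNetwork) -> Dict[str, int]:
    """Incident-edge count per node; isolated nodes report 0."""
    out = {node: 0 for node in net.nodes}
    for u, v in net.edges:
        out[u] += 1
        out[v] += 1
    return out


def _to_networkx(net: WeightedNetwork) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    for (u, v), w in net.edges.items():
        g.add_edge(u, v, weight=w)
    return g


def hub_genes(net: WeightedNetwork, q: float = 0.95, dataset_id: str = "") -> HubReport:
    """Genes whose degree strictly exceeds the q-quantile of the degree
    distribution (linear-interpolation quantile of the full degree multiset,
    isolated nodes included)."""
    if not (0.0 < q < 1.0):
        raise ValueError("q must be in (0, 1)")
    deg = degrees(net)
    if not deg:
        raise ValueError("empty network")
    threshold = float(np.quantile(np.fromiter(deg.values(), dtype=float), q))
    hubs = sorted(
        ((g, d) for g, d in deg.items() if d > threshold),
        key=lambda item: (-item[1], item[0]),
    )
    return HubReport(dataset_id=dataset_id, hubs=hubs, quantile_threshold=threshold)


def subnetwork_around(net: WeightedNetwork, gene: str) -> WeightedNetwork:
    """The connected component containing `gene`, edges and weights preserved."""
    if gene not in net.nodes:
        raise KeyError(f"gene {gene!r} not in network")
    component = nx.node_connected_component(_to_networkx(net), gene)
    sub = WeightedNetwork(nodes=component)
    for (u, v), w in net.edges.items():
        if u in component:
            sub.add_edge(u, v, w, net.provenance.get((u, v)))
    return sub


def consensus_network(aggregated: Mapping[str, WeightedNetwork]) -> WeightedNetwork:
    """Max-union merge of per-dataset aggregated networks.

    Nodes and edges are unions across datasets; an edge's weight is its
    maximum over the datasets containing it and its provenance lists those
    datasets.  The merge is associative and commutative.
    """
    if len(aggregated) < 2:
        raise ValueError("need at least 2 networks")
    out = WeightedNetwork()
    contributors: Dict[Tuple[str, str], List[str]] = {}
    for ds_id in sorted(aggregated):
        net = aggregated[ds_id]
        out.nodes |= net.nodes
        for e, w in net.edges.items():
            contributors.setdefault(e, []).append(ds_id)
            if w > out.edges.get(e, 0.0):
                out.edges[e] = w
                out.nodes.update(e)
    for e, ds_ids in contributors.items():
        out.provenance[e] = "datasets=" + ",".join(ds_ids)
    return out


def pathway_landscape(
    enrichments: Mapping[str, Sequence[EnrichmentResult]],
    pathway_ids: Sequence[str],
) -> pd.DataFrame:
    """Long-format (pathway, network, p, 1-p) table.

    Plotting 1-p puts "more significant" on top, which makes the comparison
    between per-dataset aggregated networks and the consensus network easy to
    read as a line per network.
    """
    rows = []
    for net_id, results in enrichments.items():
        by_id = {r.pathway_id: r for r in results}
        for pid in pathway_ids:
            if pid not in by_id:
                raise KeyError(f"pathway {pid!r} missing from network {net_id!r}")
            p = by_id[pid].p_value
            rows.append((pid, net_id, p, 1.0 - p))
    return pd.DataFrame(rows, columns=["pathway_id", "network_id", "p_value", "one_minus_p"])
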