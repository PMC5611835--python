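"""Undirected weighted gene network container shared by all pipeline stages.

Every stage of the pipeline (single-run inference, bagged ensembles, the
repeat-averaged ensemble, thresholding, per-dataset aggregation and the final
consensus merge) speaks this one container.  Edges are undirected and keyed by
the canonical sorted endpoint pair, weights live in (0, 1] (an appearance
frequency or a mean of frequencies), and a free-text provenance string per edge
records where it came from (bootstrap counts, iteration indices, dataset tags).
"""

from __future__ import annotations

from typing import Dict, Iterable, Optional, Set, Tuple

Edge = Tuple[str, str]


def edge_key(u: str, v: str) -> Edge:
    """Canonical key for an undirected edge: endpoints sorted lexicographically."""
    if u == v:
        raise ValueError(f"self-loop not allowed: {u!r}")
    return (u, v) if u < v else (v, u)


class WeightedNetwork:
    """Undirected weighted graph over gene symbols.

    Invariants: one entry per unordered pair, no self-loops, weights in (0, 1],
    and the node set always covers every edge endpoint.  Nodes without edges
    are legal (an inference run keeps every input gene as a node even when it
    nominates no significant partner).
    """

    def __init__(
        self,
        nodes: Optional[Iterable[str]] = None,
        edges: Optional[Dict[Edge, float]] = None,
        provenance: Optional[Dict[Edge, str]] = None,
    ) -> None:
        self.nodes: Set[str] = set(nodes) if nodes is not None else set()
        self.edges: Dict[Edge, float] = {}
        self.provenance: Dict[Edge, str] = {}
        if edges:
            for (u, v), w in edges.items():
                self.add_edge(u, v, w)
        if provenance:
            for (u, v), tag in provenance.items():
                self.provenance[edge_key(u, v)] = tag

    def add_edge(self, u: str, v: str, weight: float, provenance: str | None = None) -> None:
        if not (0.0 < weight <= 1.0):
            raise ValueError(f"edge weight must be in (0, 1], got {weight}")
        key = edge_key(u, v)
        self.edges[key] = float(weight)
        self.nodes.update(key)
        if provenance is not None:
            self.provenance[key] = provenance

    def weight(self, u: str, v: str) -> Optional[float]:
        return self.edges.get(edge_key(u, v))

    def has_edge(self, u: str, v: str) -> bool:
        return edge_key(u, v) in self.edges

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_set(self) -> Set[Edge]:
        return set(self.edges)

    def sorted_edges(self):
        """Edges in canonical order (lexicographic on the sorted pair)."""
        for key in sorted(self.edges):
            yield key, self.edges[key]

    def copy(self) -> "WeightedNetwork":
        net = WeightedNetwork(nodes=self.nodes)
        net.edges = dict(self.edges)
        net.provenance = dict(self.provenance)
        return net

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WeightedNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __repr__(self) -> str:
        return f"WeightedNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"
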