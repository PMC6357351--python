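"""Merging feed-forward loops into regulatory networks.

Motif-restricted networks (A, B, C) and the combined network are all
deduplicated unions of their contributing FFL instances' nodes and
edges; each edge records which motif classes contributed it, which the
pathway-subnetwork stage reuses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .model import EdgeType, NodeKind, RegulatoryNetwork
from .motifs import MOTIF_TYPES, FFLInstance

__all__ = ["NetworkStats", "build_network", "network_stats"]


@dataclass(frozen=True)
class NetworkStats:
    """Node counts by role and edge counts by relationship type."""

    n_mirna: int = 0
    n_tf: int = 0
    n_gene: int = 0
    n_edges: int = 0
    edges_by_type: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.edges_by_type and self.n_edges != sum(self.edges_by_type.values()):
            raise ValueError("n_edges must equal the sum of edges_by_type")

    def as_dict(self) -> dict:
        return {
            "n_mirna": self.n_mirna,
            "n_tf": self.n_tf,
            "n_gene": self.n_gene,
            "n_edges": self.n_edges,
            "edges_by_type": dict(self.edges_by_type),
        }


def build_network(
    ffls: Sequence[FFLInstance],
    motif_filter: Iterable[str] | None = None,
) -> RegulatoryNetwork:
    """Union the nodes and edges of (a motif subset of) FFL instances.

    With ``motif_filter`` (a subset of {'A','B','C'}) only instances of
    those classes contribute — the motif-specific networks; without it,
    the combined network.  Shared edges collapse to one, accumulating
    motif provenance.
    """
    if motif_filter is None:
        wanted = set(MOTIF_TYPES)
    else:
        wanted = {str(m) for m in motif_filter}
        unknown = wanted - set(MOTIF_TYPES)
        if unknown:
            raise ValueError(f"unknown motif types in filter: {sorted(unknown)}")
    net = RegulatoryNetwork()
    for f in ffls:
        if f.motif_type not in wanted:
            continue
        for e in f.edges:
            net.add_edge(e, motifs=(f.motif_type,))
    return net


def network_stats(network: RegulatoryNetwork) -> NetworkStats:
    """Exact composition counts; independent of node/edge ordering."""
    by_type = {et.value: len(network.edges_of_type(et)) for et in EdgeType}
    return NetworkStats(
        n_mirna=len(network.nodes_of_kind(NodeKind.MIRNA)),
        n_tf=len(network.nodes_of_kind(NodeKind.TF)),
        n_gene=len(network.nodes_of_kind(NodeKind.GENE)),
        n_edges=len(network.edges),
        edges_by_type=by_type,
    )
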