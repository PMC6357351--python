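"""Pathway-seeded subnetwork extraction.

Given a seed gene list (e.g. the Wnt-pathway members recruited by the
combined network), keep every feed-forward loop whose jointly regulated
gene is a seed, merge the kept loops into a network, and split it into
connected components of the undirected projection.  The components are
the reported subnetworks, ordered deterministically by smallest node
id.  A flag relaxes seed matching to any slot (TF or miRNA seeds too).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .assembly import NetworkStats, build_network, network_stats
from .hubs import undirected_projection
from .model import RegulatoryNetwork
from .motifs import FFLInstance

__all__ = ["SubnetworkReport", "extract_subnetwork"]


@dataclass
class SubnetworkReport:
    seeds_found: tuple[str, ...]
    seeds_missing: tuple[str, ...]
    ffls: list[FFLInstance]
    components: list[RegulatoryNetwork]
    component_stats: list[NetworkStats] = field(default_factory=list)
    overall: RegulatoryNetwork | None = None
    overall_stats: NetworkStats | None = None

    @property
    def n_components(self) -> int:
        return len(self.components)


def extract_subnetwork(
    ffls: Sequence[FFLInstance],
    seeds: Iterable[str],
    match_slot: str = "gene",
) -> SubnetworkReport:
    """Build the subnetwork of all FFLs touching a seed list.

    ``match_slot='gene'`` (default) matches seeds against the loop's
    joint-target gene only; ``'any'`` also matches TF and miRNA slots.
    Seeds absent from every kept loop are reported as missing; if none
    match, an empty report is returned with a warning.
    """
    if match_slot not in ("gene", "any"):
        raise ValueError(f"match_slot must be 'gene' or 'any', got {match_slot!r}")
    seed_set = {s.strip() for s in seeds if s and s.strip()}
    if not seed_set:
        raise ValueError("seed list is empty")

    def touches(f: FFLInstance) -> bool:
        if match_slot == "gene":
            return f.gene in seed_set
        return bool({f.gene, f.tf, f.mirna} & seed_set)

    kept = [f for f in ffls if touches(f)]
    found = set()
    for f in kept:
        slots = {f.gene} if match_slot == "gene" else {f.gene, f.tf, f.mirna}
        found |= slots & seed_set
    missing = tuple(sorted(seed_set - found))
    if not kept:
        warnings.warn("no FFL contains any seed; empty subnetwork", stacklevel=2)
        return SubnetworkReport(
            seeds_found=(), seeds_missing=missing, ffls=[], components=[]
        )

    overall = build_network(kept)
    proj = undirected_projection(overall)
    comp_nodesets = sorted(
        (set(c) for c in nx.connected_components(proj)), key=lambda s: min(s)
    )
    components: list[RegulatoryNetwork] = []
    for nodes in comp_nodesets:
        sub = RegulatoryNetwork()
        for e in overall.sorted_edges():
            if e.source in nodes and e.target in nodes:
                sub.add_edge(e, motifs=overall.edge_motifs(e))
        components.append(sub)
    return SubnetworkReport(
        seeds_found=tuple(sorted(found)),
        seeds_missing=missing,
        ffls=kept,
        components=components,
        component_stats=[network_stats(c) for c in components],
        overall=overall,
        overall_stats=network_stats(overall),
    )
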