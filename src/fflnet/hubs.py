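"""Hub ranking by Maximal Clique Centrality (MCC).

MCC scores a node v as the sum over all maximal cliques C containing v
of (|C| - 1)!.  On a node whose neighborhood is edgeless this reduces to
the degree (every incident edge is a maximal 2-clique), while nodes
embedded in large cliques are boosted factorially — which is what makes
MCC effective at picking essential regulators out of locally dense
regions.  The score is computed on the simple undirected projection of
the typed directed network; edge types and directions do not matter for
centrality.  Isolated nodes score 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx

from .model import RegulatoryNetwork

__all__ = [
    "HubRecord",
    "HubRanking",
    "undirected_projection",
    "maximal_cliques",
    "mcc_scores",
    "top_k",
]


def undirected_projection(network: RegulatoryNetwork) -> nx.Graph:
    """Simple undirected graph: {u,v} iff any directed edge u->v or v->u."""
    g = nx.Graph()
    for sym, kind in network.nodes.items():
        g.add_node(sym, kind=kind.value)
    for e in network.edges:
        g.add_edge(e.source, e.target)
    return g


def maximal_cliques(graph: nx.Graph) -> list[tuple[str, ...]]:
    """All maximal cliques, each once, as sorted tuples in sorted order.

    Backed by networkx's Bron-Kerbosch with pivoting; singleton cliques
    (isolated nodes) are included here but ignored by the MCC score.
    """
    cliques = [tuple(sorted(c)) for c in nx.find_cliques(graph)]
    cliques.sort(key=lambda c: (len(c), c))
    return cliques


@dataclass(frozen=True)
class HubRecord:
    node: str
    kind: str
    score: int
    rank: int


@dataclass
class HubRanking:
    """MCC ranking, sorted by score descending then node id ascending."""

    records: list[HubRecord]
    warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def nodes(self) -> list[str]:
        return [r.node for r in self.records]

    def score_of(self, node: str) -> int:
        for r in self.records:
            if r.node == node:
                return r.score
        raise KeyError(node)


def mcc_scores(network: RegulatoryNetwork) -> HubRanking:
    """Full MCC ranking of a network.

    Factorials are exact integers; ties break lexicographically on node
    id so the ranking is deterministic.
    """
    g = undirected_projection(network)
    scores: dict[str, int] = {n: 0 for n in g.nodes}
    for clique in nx.find_cliques(g):
        if len(clique) < 2:
            continue  # isolated node: score stays 0
        w = math.factorial(len(clique) - 1)
        for node in clique:
            scores[node] += w
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    kinds = network.nodes
    records = [
        HubRecord(node=n, kind=kinds[n].value, score=s, rank=i + 1)
        for i, (n, s) in enumerate(ordered)
    ]
    return HubRanking(records=records)


def top_k(ranking: HubRanking, k: int = 10) -> HubRanking:
    """First k records after deterministic tie-breaking.

    Warns (and records the warning) when fewer than k nodes exist or
    when a score tie straddles the cut, since then the hub set is not
    uniquely defined by the score alone.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    msgs = list(ranking.warnings)
    recs = ranking.records
    if k >= len(recs):
        if k > len(recs):
            msgs.append(f"requested k={k} but ranking has only {len(recs)} nodes")
            warnings.warn(msgs[-1], stacklevel=2)
        return HubRanking(records=list(recs), warnings=msgs)
    if recs[k - 1].score == recs[k].score:
        tied = [r.node for r in recs if r.score == recs[k - 1].score]
        msgs.append(
            f"score tie at the k={k} cut (score {recs[k - 1].score}, "
            f"tied nodes: {', '.join(tied)}); broken lexicographically"
        )
        warnings.warn(msgs[-1], stacklevel=2)
    return HubRanking(records=list(recs[:k]), warnings=msgs)


def write_hub_table(ranking: HubRanking, path) -> None:
    """Hub TSV: ``node<TAB>kind<TAB>mcc<TAB>rank``."""
    lines = ["node\tkind\tmcc\trank"]
    lines += [f"{r.node}\t{r.kind}\t{r.score}\t{r.rank}" for r in ranking]
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def hub_sequence(ranking: Sequence[HubRecord]) -> list[tuple[str, int]]:
    """(node, score) pairs — convenience for tests and reports."""
    return [(r.node, r.score) for r in ranking]
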