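"""Core domain types for miRNA-TF co-regulatory network analysis.

The analysis operates on four kinds of typed, directed regulation pairs
(TF->gene, TF->miRNA, miRNA->gene, miRNA->TF) over three disjoint node
roles.  Role disjointness is load-bearing: the feed-forward-loop motif
definitions require that the jointly regulated target is a non-TF
protein-coding gene, so a symbol may not act as both TF and gene within
one analysis.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import pandas as pd

__all__ = [
    "NodeKind",
    "EdgeType",
    "RegulatoryEdge",
    "RegulatoryNetwork",
    "ExpressionMatrix",
    "GeneSet",
    "GeneSetCollection",
    "KindConflictError",
    "check_kind_consistency",
]


class NodeKind(str, enum.Enum):
    """Role of a node: transcription factor, microRNA, or non-TF gene."""

    TF = "TF"
    MIRNA = "miRNA"
    GENE = "gene"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class EdgeType(str, enum.Enum):
    """The four regulation-pair types, each fixing its endpoint roles."""

    TF_GENE = "TF_gene"
    TF_MIRNA = "TF_miRNA"
    MIRNA_GENE = "miRNA_gene"
    MIRNA_TF = "miRNA_TF"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @property
    def source_kind(self) -> NodeKind:
        return _EDGE_KINDS[self][0]

    @property
    def target_kind(self) -> NodeKind:
        return _EDGE_KINDS[self][1]


_EDGE_KINDS: dict[EdgeType, tuple[NodeKind, NodeKind]] = {
    EdgeType.TF_GENE: (NodeKind.TF, NodeKind.GENE),
    EdgeType.TF_MIRNA: (NodeKind.TF, NodeKind.MIRNA),
    EdgeType.MIRNA_GENE: (NodeKind.MIRNA, NodeKind.GENE),
    EdgeType.MIRNA_TF: (NodeKind.MIRNA, NodeKind.TF),
}


class KindConflictError(ValueError):
    """A symbol is implied to have two different roles.

    Carries the full offender table so callers can report every
    conflicting symbol at once rather than the first hit.
    """

    def __init__(self, conflicts: Mapping[str, set[NodeKind]]):
        self.conflicts = {k: set(v) for k, v in conflicts.items()}
        lines = ", ".join(
            f"{sym}: {{{', '.join(sorted(k.value for k in kinds))}}}"
            for sym, kinds in sorted(self.conflicts.items())
        )
        super().__init__(
            f"{len(self.conflicts)} node(s) appear with conflicting kinds: {lines}"
        )


@dataclass(frozen=True, order=True)
class RegulatoryEdge:
    """A directed, typed regulation pair.

    Identifiers are stored verbatim after whitespace trimming (miRNA
    casing such as ``hsa-mir-27b`` is preserved); comparison is
    case-sensitive.  Self-regulation is rejected: none of the four pair
    types includes it.
    """

    source: str
    target: str
    edge_type: EdgeType

    def __post_init__(self) -> None:
        object.__setattr__(self, "source", self.source.strip())
        object.__setattr__(self, "target", self.target.strip())
        object.__setattr__(self, "edge_type", EdgeType(self.edge_type))
        if not self.source or not self.target:
            raise ValueError("edge endpoints must be non-empty symbols")
        if self.source == self.target:
            raise ValueError(f"self-loop not allowed: {self.source!r}")

    @property
    def source_kind(self) -> NodeKind:
        return self.edge_type.source_kind

    @property
    def target_kind(self) -> NodeKind:
        return self.edge_type.target_kind


def check_kind_consistency(edges: Iterable[RegulatoryEdge]) -> dict[str, NodeKind]:
    """Infer each symbol's role from the typed edges it participates in.

    Returns ``{symbol: kind}``; raises :class:`KindConflictError` listing
    *all* symbols whose implied roles disagree across edges (e.g. a
    symbol that is a TF-gene target but a TF-miRNA source).
    """
    seen: dict[str, set[NodeKind]] = {}
    for e in edges:
        seen.setdefault(e.source, set()).add(e.source_kind)
        seen.setdefault(e.target, set()).add(e.target_kind)
    conflicts = {s: k for s, k in seen.items() if len(k) > 1}
    if conflicts:
        raise KindConflictError(conflicts)
    return {s: next(iter(k)) for s, k in seen.items()}


class RegulatoryNetwork:
    """A deduplicated, typed, directed regulatory graph.

    Node kinds are inferred from edge types at insertion and may never
    conflict; duplicate edges (same source, target and type) collapse.
    Edges may carry a motif-provenance annotation (the set of motif
    classes whose instances contributed the edge).
    """

    def __init__(self, edges: Iterable[RegulatoryEdge] = ()) -> None:
        self._kinds: dict[str, NodeKind] = {}
        self._edges: set[RegulatoryEdge] = set()
        self._provenance: dict[RegulatoryEdge, set[str]] = {}
        for e in edges:
            self.add_edge(e)

    # -- construction -------------------------------------------------
    def add_edge(
        self, edge: RegulatoryEdge, motifs: Iterable[str] = ()
    ) -> None:
        for sym, kind in ((edge.source, edge.source_kind), (edge.target, edge.target_kind)):
            prev = self._kinds.get(sym)
            if prev is not None and prev is not kind:
                raise KindConflictError({sym: {prev, kind}})
            self._kinds[sym] = kind
        self._edges.add(edge)
        if motifs:
            self._provenance.setdefault(edge, set()).update(motifs)

    # -- access -------------------------------------------------------
    @property
    def nodes(self) -> dict[str, NodeKind]:
        return dict(self._kinds)

    @property
    def edges(self) -> frozenset[RegulatoryEdge]:
        return frozenset(self._edges)

    def edge_motifs(self, edge: RegulatoryEdge) -> frozenset[str]:
        return frozenset(self._provenance.get(edge, ()))

    def nodes_of_kind(self, kind: NodeKind) -> set[str]:
        kind = NodeKind(kind)
        return {s for s, k in self._kinds.items() if k is kind}

    def edges_of_type(self, edge_type: EdgeType) -> set[RegulatoryEdge]:
        edge_type = EdgeType(edge_type)
        return {e for e in self._edges if e.edge_type is edge_type}

    def kind_of(self, symbol: str) -> NodeKind:
        return self._kinds[symbol]

    def targets_of(self, symbol: str) -> set[str]:
        """Direct regulatory targets (any edge type) of a node."""
        return {e.target for e in self._edges if e.source == symbol}

    def sorted_edges(self) -> list[RegulatoryEdge]:
        return sorted(self._edges, key=lambda e: (e.source, e.target, e.edge_type.value))

    def __len__(self) -> int:
        return len(self._kinds)

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self._kinds))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegulatoryNetwork):
            return NotImplemented
        return self._kinds == other._kinds and self._edges == other._edges

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"RegulatoryNetwork({len(self._kinds)} nodes, {len(self._edges)} edges)"
        )

    # -- conversion ---------------------------------------------------
    def to_networkx(self):
        """Directed networkx graph with kind/edge_type attributes."""
        import networkx as nx

        g = nx.DiGraph()
        for sym, kind in self._kinds.items():
            g.add_node(sym, kind=kind.value)
        for e in self._edges:
            g.add_edge(e.source, e.target, edge_type=e.edge_type.value)
        return g


@dataclass
class ExpressionMatrix:
    """A normalized expression matrix (rows = probes/genes, cols = samples).

    ``values`` is a float DataFrame; missing entries stay NaN and are
    handled pairwise-complete downstream.  ``metadata`` retains any
    Series-Matrix header lines as a side table.
    """

    values: pd.DataFrame
    metadata: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cols = list(self.values.columns)
        if len(cols) != len(set(cols)):
            dupes = sorted({c for c in cols if cols.count(c) > 1})
            raise ValueError(f"duplicate sample ids: {dupes}")
        if len(cols) == 0:
            raise ValueError("expression matrix has zero samples")
        self.values = self.values.astype(float)

    @property
    def row_ids(self) -> list[str]:
        return [str(i) for i in self.values.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().sum().sum())


@dataclass(frozen=True)
class GeneSet:
    term: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.term!r} is empty")


@dataclass
class GeneSetCollection:
    """Named gene sets plus an optional background universe.

    When no explicit background is supplied the union of all members is
    used — this stands in for the tool-internal universes of web
    enrichment services and is deliberately overridable.
    """

    sets: dict[str, GeneSet]
    background: frozenset[str] | None = None

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets.values())

    def effective_background(self) -> frozenset[str]:
        if self.background is not None:
            return self.background
        out: set[str] = set()
        for gs in self.sets.values():
            out |= gs.members
        return frozenset(out)
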