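"""Readers and writers for pair tables, networks, expression matrices and GMT.

File dialects:

* pair table — TSV ``source<TAB>target[<TAB>edge_type]``, ``#`` comments.
* network    — edge TSV (same columns, always typed, with header), SIF
  (``source<TAB>edge_type<TAB>target``), or GraphML with a ``kind`` node
  attribute and an ``edge_type`` edge attribute.
* expression — plain TSV (first column row ids, remaining columns
  samples) or the GEO Series-Matrix dialect, in which the numeric block
  is fenced by ``!series_matrix_table_begin``/``!series_matrix_table_end``
  and ``!``-prefixed header lines carry metadata.
* gene sets  — GMT (term, description, tab-separated members).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .model import (
    EdgeType,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    RegulatoryEdge,
    RegulatoryNetwork,
)

__all__ = [
    "ParseReport",
    "parse_pair_table",
    "read_expression_matrix",
    "read_gmt",
    "write_network",
    "read_network",
]


@dataclass
class ParseReport:
    """Accounting of what a pair-table parse kept and dropped."""

    n_rows: int = 0
    n_edges: int = 0
    n_duplicates: int = 0
    dropped_self_loops: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_self_loops(self) -> int:
        return len(self.dropped_self_loops)


def parse_pair_table(
    path: str | Path,
    edge_type: EdgeType | str | None = None,
) -> tuple[list[RegulatoryEdge], ParseReport]:
    """Parse a two- or three-column TSV of regulation pairs.

    ``edge_type`` types every row when the file has two columns; a
    three-column file carries its own type per row and must agree with
    ``edge_type`` if both are given.  Exact duplicate pairs are
    collapsed and counted; self-loop rows are dropped and recorded.
    Malformed rows raise :class:`ValueError` naming the line number.
    """
    declared = EdgeType(edge_type) if edge_type is not None else None
    report = ParseReport()
    edges: list[RegulatoryEdge] = []
    seen: set[RegulatoryEdge] = set()
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=2 tab-separated fields, "
                    f"got {len(fields)}"
                )
            source, target = fields[0].strip(), fields[1].strip()
            if len(fields) >= 3 and fields[2].strip():
                try:
                    row_type = EdgeType(fields[2].strip())
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: line {lineno}: unknown edge type {fields[2].strip()!r}"
                    ) from exc
                if declared is not None and row_type is not declared:
                    raise ValueError(
                        f"{path}: line {lineno}: edge type column {row_type.value!r} "
                        f"conflicts with declared type {declared.value!r}"
                    )
            elif declared is not None:
                row_type = declared
            else:
                raise ValueError(
                    f"{path}: line {lineno}: no edge type given (neither argument "
                    "nor third column)"
                )
            if not source or not target:
                raise ValueError(f"{path}: line {lineno}: empty symbol")
            report.n_rows += 1
            if source == target:
                report.dropped_self_loops.append((lineno, source))
                continue
            edge = RegulatoryEdge(source, target, row_type)
            if edge in seen:
                report.n_duplicates += 1
                continue
            seen.add(edge)
            edges.append(edge)
    report.n_edges = len(edges)
    return edges, report


# ---------------------------------------------------------------------------
# expression matrices


def read_expression_matrix(
    path: str | Path, format: str = "tsv"
) -> ExpressionMatrix:
    """Read a normalized expression matrix.

    ``format='tsv'``: header row of sample names, first column row ids.
    ``format='series_matrix'``: GEO Series-Matrix; only the fenced table
    is parsed and ``!``-header lines are retained as metadata.
    """
    if format == "tsv":
        with open(path, "rt", encoding="utf-8") as fh:
            for line in fh:
                if line.strip() and not line.startswith("#"):
                    _check_dup_samples(path, line)
                    break
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        _check_ragged(path, df)
        return ExpressionMatrix(values=df)
    if format == "series_matrix":
        return _read_series_matrix(path)
    raise ValueError(f"unknown expression format {format!r}")


def _check_dup_samples(path: str | Path, header_line: str) -> None:
    # pandas mangles duplicate column names silently; catch them here
    cols = [c.strip().strip('"') for c in header_line.rstrip("\n").split("\t")[1:]]
    if len(cols) != len(set(cols)):
        dupes = sorted({c for c in cols if cols.count(c) > 1})
        raise ValueError(f"{path}: duplicate sample column names: {dupes}")


def _check_ragged(path: str | Path, df: pd.DataFrame) -> None:
    if df.shape[1] == 0:
        raise ValueError(f"{path}: zero sample columns")
    # pandas pads ragged short rows with NaN; an all-NaN trailing column is
    # the fingerprint of a ragged header/body mismatch
    if any(str(c).startswith("Unnamed:") for c in df.columns):
        raise ValueError(f"{path}: ragged rows (header/body column mismatch)")


def _read_series_matrix(path: str | Path) -> ExpressionMatrix:
    metadata: dict[str, list[str]] = {}
    table_lines: list[str] = []
    in_table = False
    saw_fence = False
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            stripped = line.rstrip("\n")
            if stripped.startswith("!series_matrix_table_begin"):
                in_table = True
                saw_fence = True
                continue
            if stripped.startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if in_table:
                if stripped.strip():
                    table_lines.append(stripped)
            elif stripped.startswith("!"):
                key, _, rest = stripped[1:].partition("\t")
                metadata.setdefault(key, []).append(rest.strip('"'))
    if not saw_fence:
        raise ValueError(f"{path}: no series_matrix_table_begin fence found")
    if not table_lines:
        raise ValueError(f"{path}: empty series-matrix table")
    _check_dup_samples(path, table_lines[0])
    df = pd.read_csv(_io.StringIO("\n".join(table_lines)), sep="\t", index_col=0)
    df.index = [str(i).strip('"') for i in df.index]
    df.columns = [str(c).strip('"') for c in df.columns]
    _check_ragged(path, df)
    return ExpressionMatrix(values=df, metadata=metadata)


# ---------------------------------------------------------------------------
# gene sets


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file; duplicate members within one set collapse."""
    sets: dict[str, GeneSet] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT requires >=3 fields "
                    f"(term, description, members), got {len(fields)}"
                )
            term, desc = fields[0].strip(), fields[1].strip()
            members = frozenset(m.strip() for m in fields[2:] if m.strip())
            if not members:
                raise ValueError(f"{path}: line {lineno}: set {term!r} has no members")
            sets[term] = GeneSet(term=term, description=desc, members=members)
    if not sets:
        import warnings

        warnings.warn(f"{path}: empty GMT file", stacklevel=2)
    return GeneSetCollection(sets=sets)


# ---------------------------------------------------------------------------
# network serialization

_EDGE_TSV_HEADER = "source\ttarget\tedge_type"


def write_network(
    network: RegulatoryNetwork, path: str | Path, format: str = "edge_tsv"
) -> None:
    """Serialize a network; ``edge_tsv`` round-trips via :func:`read_network`."""
    path = Path(path)
    if format == "edge_tsv":
        lines = [_EDGE_TSV_HEADER]
        lines += [
            f"{e.source}\t{e.target}\t{e.edge_type.value}"
            for e in network.sorted_edges()
        ]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif format == "sif":
        lines = [
            f"{e.source}\t{e.edge_type.value}\t{e.target}"
            for e in network.sorted_edges()
        ]
        path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
    elif format == "graphml":
        import networkx as nx

        nx.write_graphml(network.to_networkx(), path)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path: str | Path, format: str = "edge_tsv") -> RegulatoryNetwork:
    """Read a network written by :func:`write_network`."""
    path = Path(path)
    net = RegulatoryNetwork()
    if format == "edge_tsv":
        with open(path, "rt", encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line.strip() or line == _EDGE_TSV_HEADER:
                    continue
                fields = line.split("\t")
                if len(fields) != 3:
                    raise ValueError(f"{path}: line {lineno}: expected 3 fields")
                net.add_edge(RegulatoryEdge(fields[0], fields[1], EdgeType(fields[2])))
        return net
    if format == "sif":
        with open(path, "rt", encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line.strip():
                    continue
                fields = line.split("\t")
                if len(fields) != 3:
                    raise ValueError(f"{path}: line {lineno}: expected 3 fields")
                net.add_edge(RegulatoryEdge(fields[0], fields[2], EdgeType(fields[1])))
        return net
    raise ValueError(f"unknown network format {format!r}")


def edges_from_tables(
    tables: Iterable[tuple[str | Path, EdgeType | str | None]],
) -> tuple[list[RegulatoryEdge], dict[str, ParseReport]]:
    """Parse several pair tables and pool their deduplicated edges.

    Returns the pooled edge list (deduplicated across tables) and a
    per-file report keyed by file name.
    """
    pooled: list[RegulatoryEdge] = []
    seen: set[RegulatoryEdge] = set()
    reports: dict[str, ParseReport] = {}
    for path, etype in tables:
        edges, rep = parse_pair_table(path, etype)
        reports[str(path)] = rep
        for e in edges:
            if e not in seen:
                seen.add(e)
                pooled.append(e)
    return pooled, reports
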