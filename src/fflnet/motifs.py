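"""Enumeration of 3-node TF-miRNA-gene feed-forward loops.

A feed-forward loop (FFL) here is a triple (TF, miRNA, gene) in which
both regulators target the same non-TF protein-coding gene — the TF
transcriptionally (TF->gene), the miRNA post-transcriptionally
(miRNA->gene) — and the regulators are themselves linked.  The link
direction classifies the loop exclusively:

* motif A — the TF also drives the miRNA (TF->miRNA only);
* motif B — the miRNA represses the TF (miRNA->TF only);
* motif C — both directions are present (a TF/miRNA feedback pair),
  realized by four edges instead of three.

Classification is exclusive: a mutually regulating pair yields a C
instance only, never an additional A or B, so per-type counts always
sum to the total.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .model import EdgeType, RegulatoryEdge, check_kind_consistency

__all__ = ["FFLInstance", "enumerate_ffls", "motif_summary"]

MOTIF_TYPES = ("A", "B", "C")


@dataclass(frozen=True, order=True)
class FFLInstance:
    """One classified feed-forward loop.

    ``edges`` holds the 3 (A, B) or 4 (C) regulatory edges realizing
    the loop, in a fixed order: TF->gene, miRNA->gene, then the
    regulator-pair edge(s) (TF->miRNA before miRNA->TF).
    """

    tf: str
    mirna: str
    gene: str
    motif_type: str
    edges: tuple[RegulatoryEdge, ...]

    def __post_init__(self) -> None:
        if self.motif_type not in MOTIF_TYPES:
            raise ValueError(f"motif_type must be one of {MOTIF_TYPES}")
        expected = 4 if self.motif_type == "C" else 3
        if len(self.edges) != expected:
            raise ValueError(
                f"motif {self.motif_type} requires {expected} edges, "
                f"got {len(self.edges)}"
            )


def enumerate_ffls(edges: Iterable[RegulatoryEdge]) -> list[FFLInstance]:
    """Find every feed-forward loop in a typed edge list.

    Requires kind-consistent edges (checked).  Each qualifying
    (TF, miRNA, gene) triple appears exactly once with its exclusive
    motif label; output is sorted by (tf, mirna, gene) so downstream
    results are byte-reproducible.
    """
    edges = list(edges)
    check_kind_consistency(edges)

    tf_genes: dict[str, dict[str, RegulatoryEdge]] = defaultdict(dict)
    mirna_genes: dict[str, dict[str, RegulatoryEdge]] = defaultdict(dict)
    tf_mirna: dict[tuple[str, str], RegulatoryEdge] = {}
    mirna_tf: dict[tuple[str, str], RegulatoryEdge] = {}
    for e in edges:
        if e.edge_type is EdgeType.TF_GENE:
            tf_genes[e.source][e.target] = e
        elif e.edge_type is EdgeType.MIRNA_GENE:
            mirna_genes[e.source][e.target] = e
        elif e.edge_type is EdgeType.TF_MIRNA:
            tf_mirna[(e.source, e.target)] = e
        elif e.edge_type is EdgeType.MIRNA_TF:
            mirna_tf[(e.source, e.target)] = e

    pairs = {(t, m) for (t, m) in tf_mirna} | {(t, m) for (m, t) in mirna_tf}
    out: list[FFLInstance] = []
    for tf, mirna in pairs:
        down = tf_mirna.get((tf, mirna))
        up = mirna_tf.get((mirna, tf))
        shared = tf_genes[tf].keys() & mirna_genes[mirna].keys()
        for gene in shared:
            base = (tf_genes[tf][gene], mirna_genes[mirna][gene])
            if down is not None and up is not None:
                inst = FFLInstance(tf, mirna, gene, "C", base + (down, up))
            elif down is not None:
                inst = FFLInstance(tf, mirna, gene, "A", base + (down,))
            else:
                inst = FFLInstance(tf, mirna, gene, "B", base + (up,))
            out.append(inst)
    out.sort(key=lambda f: (f.tf, f.mirna, f.gene))
    return out


def motif_summary(ffls: Sequence[FFLInstance]) -> pd.DataFrame:
    """Per-motif-type composition table.

    Rows A, B, C and Total; columns: FFL count, distinct TFs, miRNAs,
    genes, and distinct edge counts per relationship type (computed over
    the union of the instances of that type).
    """
    rows = []
    groups = {t: [f for f in ffls if f.motif_type == t] for t in MOTIF_TYPES}
    groups["Total"] = list(ffls)
    for name, group in groups.items():
        edge_union: set[RegulatoryEdge] = set()
        for f in group:
            edge_union.update(f.edges)
        by_type = {
            et: sum(1 for e in edge_union if e.edge_type is et) for et in EdgeType
        }
        rows.append(
            {
                "motif": name,
                "n_ffls": len(group),
                "n_tfs": len({f.tf for f in group}),
                "n_mirnas": len({f.mirna for f in group}),
                "n_genes": len({f.gene for f in group}),
                "n_mirna_gene": by_type[EdgeType.MIRNA_GENE],
                "n_mirna_tf": by_type[EdgeType.MIRNA_TF],
                "n_tf_gene": by_type[EdgeType.TF_GENE],
                "n_tf_mirna": by_type[EdgeType.TF_MIRNA],
            }
        )
    return pd.DataFrame(rows).set_index("motif")


def write_ffl_table(ffls: Sequence[FFLInstance], path) -> None:
    """FFL TSV: ``tf<TAB>mirna<TAB>gene<TAB>motif_type``."""
    lines = ["tf\tmirna\tgene\tmotif_type"]
    lines += [f"{f.tf}\t{f.mirna}\t{f.gene}\t{f.motif_type}" for f in ffls]
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def ffl_from_triple(tf: str, mirna: str, gene: str, motif_type: str) -> FFLInstance:
    """Rebuild an FFL instance from its triple — the motif class fully
    determines the realizing edges."""
    base = (
        RegulatoryEdge(tf, gene, EdgeType.TF_GENE),
        RegulatoryEdge(mirna, gene, EdgeType.MIRNA_GENE),
    )
    down = RegulatoryEdge(tf, mirna, EdgeType.TF_MIRNA)
    up = RegulatoryEdge(mirna, tf, EdgeType.MIRNA_TF)
    if motif_type == "A":
        return FFLInstance(tf, mirna, gene, "A", base + (down,))
    if motif_type == "B":
        return FFLInstance(tf, mirna, gene, "B", base + (up,))
    if motif_type == "C":
        return FFLInstance(tf, mirna, gene, "C", base + (down, up))
    raise ValueError(f"unknown motif type {motif_type!r}")


def read_ffl_table(path) -> list[FFLInstance]:
    """Read a TSV written by :func:`write_ffl_table`."""
    out: list[FFLInstance] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("tf\t") or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 fields")
            out.append(ffl_from_triple(*fields))
    out.sort(key=lambda f: (f.tf, f.mirna, f.gene))
    return out
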