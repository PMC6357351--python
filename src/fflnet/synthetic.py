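"""Synthetic regulatory tables and expression matrices with known truth.

The generator emulates the structure of the study inputs: four typed
pair tables over disjoint TF/miRNA/gene universes containing *planted*
feed-forward loops of each motif class on top of background regulation
sampled uniformly over kind-consistent pairs, and a normalized
expression matrix in which a configurable fraction of TF->gene edges
carries a planted Pearson correlation at a given sample count.

Defaults mirror the reference study's scale: 27 TFs, 18 miRNAs and 127
genes; 71/50/7 planted A/B/C loops; background rates equal to the
published pair counts divided by the number of possible pairs of each
type; 35 expression samples with rho = 0.9 on 64.8% of TF->gene edges.

Two guarantees make every downstream stage testable:

* with background rates 0, motif enumeration recovers the planted
  triples exactly, per class;
* with background on, it recovers at least the planted count per class
  — background TF<->miRNA edges are never drawn on a regulator pair
  used by a planted loop (in either direction), since such an edge
  would silently reclassify the planted loop.

One integer seed drives a named pseudo-random stream per artifact
(tables vs expression), so regenerating one artifact never perturbs
the other.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import EdgeType, ExpressionMatrix, RegulatoryEdge, RegulatoryNetwork

__all__ = ["SimulationConfig", "GroundTruth", "generate_pair_tables",
           "generate_expression", "write_tables"]

_STREAMS = {"tables": 1, "expression": 2}


def _stream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[name]])


@dataclass
class SimulationConfig:
    """Study conditions for the generator (defaults = reference scale)."""

    n_tf: int = 27
    n_mirna: int = 18
    n_gene: int = 127
    planted_ffls: dict[str, int] = field(
        default_factory=lambda: {"A": 71, "B": 50, "C": 7}
    )
    background_edge_rates: dict[str, float] = field(
        default_factory=lambda: {
            # published pair counts / possible kind-consistent pairs
            "TF_gene": 671 / (27 * 127),
            "TF_miRNA": 76 / (27 * 18),
            "miRNA_gene": 77 / (18 * 127),
            "miRNA_TF": 21 / (18 * 27),
        }
    )
    n_samples: int = 35
    rho: float = 0.9
    frac_correlated: float = 57 / 88
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_tf, self.n_mirna, self.n_gene) < 1:
            raise ValueError("universe sizes must be positive")
        if any(c < 0 for c in self.planted_ffls.values()):
            raise ValueError("planted FFL counts must be >= 0")
        if set(self.planted_ffls) - {"A", "B", "C"}:
            raise ValueError("planted_ffls keys must be in {A, B, C}")
        for et, rate in self.background_edge_rates.items():
            EdgeType(et)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"background rate for {et} outside [0,1]")
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3 (Pearson p needs df >= 1)")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (-1, 1)")
        if not 0.0 <= self.frac_correlated <= 1.0:
            raise ValueError("frac_correlated must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """What was planted: FFL triples with labels, correlated edges."""

    ffls: list[tuple[str, str, str, str]] = field(default_factory=list)
    correlated_edges: list[tuple[str, str]] = field(default_factory=list)

    def counts_by_motif(self) -> dict[str, int]:
        out = {"A": 0, "B": 0, "C": 0}
        for (_, _, _, t) in self.ffls:
            out[t] += 1
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "ffls": [list(f) for f in self.ffls],
            "correlated_edges": [list(e) for e in self.correlated_edges],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def _symbols(config: SimulationConfig) -> tuple[list[str], list[str], list[str]]:
    tfs = [f"TF{i:03d}" for i in range(1, config.n_tf + 1)]
    mirnas = [f"hsa-mir-s{i:03d}" for i in range(1, config.n_mirna + 1)]
    genes = [f"GENE{i:03d}" for i in range(1, config.n_gene + 1)]
    return tfs, mirnas, genes


def generate_pair_tables(
    config: SimulationConfig,
) -> tuple[dict[EdgeType, list[RegulatoryEdge]], GroundTruth]:
    """Emit the four typed pair tables with planted FFLs plus background.

    Deterministic given ``config.seed``.  Raises when the planted counts
    exceed the combinatorial capacity of the universes (each planted
    loop consumes a (TF, miRNA) regulator pair exclusive to its motif
    class; a pair may host several loops of one class via different
    genes).
    """
    rng = _stream(config.seed, "tables")
    tfs, mirnas, genes = _symbols(config)
    counts = {t: int(config.planted_ffls.get(t, 0)) for t in ("A", "B", "C")}

    all_pairs = [(t, m) for t in tfs for m in mirnas]
    pairs_needed = sum(math.ceil(c / config.n_gene) for c in counts.values() if c)
    if pairs_needed > len(all_pairs):
        raise ValueError(
            f"planted counts {counts} exceed capacity: need {pairs_needed} "
            f"regulator pairs, only {len(all_pairs)} exist"
        )
    order = rng.permutation(len(all_pairs))
    shuffled = [all_pairs[i] for i in order]

    edges: dict[EdgeType, set[RegulatoryEdge]] = {et: set() for et in EdgeType}
    truth = GroundTruth()
    used_pairs: set[tuple[str, str]] = set()
    cursor = 0
    for motif in ("A", "B", "C"):
        c = counts[motif]
        if c == 0:
            continue
        n_pairs = math.ceil(c / config.n_gene)
        pool = shuffled[cursor : cursor + n_pairs]
        cursor += n_pairs
        used_pairs.update(pool)
        base, extra = divmod(c, n_pairs)
        for j, (tf, mi) in enumerate(pool):
            share = base + (1 if j < extra else 0)
            gene_idx = rng.choice(config.n_gene, size=share, replace=False)
            if motif in ("A", "C"):
                edges[EdgeType.TF_MIRNA].add(RegulatoryEdge(tf, mi, EdgeType.TF_MIRNA))
            if motif in ("B", "C"):
                edges[EdgeType.MIRNA_TF].add(RegulatoryEdge(mi, tf, EdgeType.MIRNA_TF))
            for gi in sorted(int(g) for g in gene_idx):
                gene = genes[gi]
                edges[EdgeType.TF_GENE].add(RegulatoryEdge(tf, gene, EdgeType.TF_GENE))
                edges[EdgeType.MIRNA_GENE].add(
                    RegulatoryEdge(mi, gene, EdgeType.MIRNA_GENE)
                )
                truth.ffls.append((tf, mi, gene, motif))

    # background edges: uniform over allowed pairs, excluding planted edges
    # and (for the regulator-pair types) any planted (TF, miRNA) pair
    candidates: dict[EdgeType, list[tuple[str, str]]] = {
        EdgeType.TF_GENE: [(t, g) for t in tfs for g in genes],
        EdgeType.TF_MIRNA: [
            (t, m) for t in tfs for m in mirnas if (t, m) not in used_pairs
        ],
        EdgeType.MIRNA_GENE: [(m, g) for m in mirnas for g in genes],
        EdgeType.MIRNA_TF: [
            (m, t) for t in tfs for m in mirnas if (t, m) not in used_pairs
        ],
    }
    for et in EdgeType:
        rate = float(config.background_edge_rates.get(et.value, 0.0))
        if rate <= 0.0:
            continue
        existing = {(e.source, e.target) for e in edges[et]}
        cand = [p for p in candidates[et] if p not in existing]
        keep = rng.random(len(cand)) < rate
        for (s, t), k in zip(cand, keep):
            if k:
                edges[et].add(RegulatoryEdge(s, t, et))

    tables = {et: sorted(es, key=lambda e: (e.source, e.target)) for et, es in edges.items()}
    truth.ffls.sort()
    return tables, truth


def generate_expression(
    network: RegulatoryNetwork,
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Expression matrix with planted co-expression on TF->gene edges.

    Rows cover every TF and gene node of the network (miRNAs have no
    array signal).  A fraction ``frac_correlated`` of TF->gene edges is
    planted: the gene's profile is drawn so that its latent correlation
    with the TF equals ``rho`` exactly (bivariate-normal construction);
    all other rows are independent noise.  When a gene carries several
    selected edges only the first (in deterministic edge order) is
    planted, so planted correlations never interfere.  Values are on a
    log-like scale: 8 + noise_sd * latent.
    """
    tf_gene = sorted(
        network.edges_of_type(EdgeType.TF_GENE), key=lambda e: (e.source, e.target)
    )
    if not tf_gene:
        raise ValueError("network has no TF_gene edges")
    if config.n_samples < 3:
        raise ValueError("n_samples must be >= 3")
    rng = _stream(config.seed, "expression")
    n = config.n_samples

    from .model import NodeKind

    tf_rows = sorted(network.nodes_of_kind(NodeKind.TF))
    gene_rows = sorted(network.nodes_of_kind(NodeKind.GENE))

    latents: dict[str, np.ndarray] = {t: rng.standard_normal(n) for t in tf_rows}

    k = int(round(config.frac_correlated * len(tf_gene)))
    chosen_idx = sorted(rng.choice(len(tf_gene), size=k, replace=False).tolist())
    planted: dict[str, str] = {}  # gene -> tf
    truth = GroundTruth()
    for i in chosen_idx:
        e = tf_gene[i]
        if e.target in planted:
            continue
        planted[e.target] = e.source
        truth.correlated_edges.append((e.source, e.target))

    c = math.sqrt(1.0 - config.rho**2)
    for g in gene_rows:
        eps = rng.standard_normal(n)
        if g in planted:
            latents[g] = config.rho * latents[planted[g]] + c * eps
        else:
            latents[g] = eps

    rows = tf_rows + gene_rows
    values = pd.DataFrame(
        {f"S{j + 1:03d}": [8.0 + config.noise_sd * latents[r][j] for r in rows]
         for j in range(n)},
        index=rows,
    )
    truth.correlated_edges.sort()
    return ExpressionMatrix(values=values), truth


def write_tables(
    tables: dict[EdgeType, Sequence[RegulatoryEdge]], outdir: str | Path
) -> dict[str, Path]:
    """Write the four pair TSVs (sorted rows, byte-reproducible)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for et, edge_list in tables.items():
        et = EdgeType(et)
        path = outdir / f"pairs_{et.value}.tsv"
        lines = ["# source\ttarget\tedge_type"]
        lines += [f"{e.source}\t{e.target}\t{e.edge_type.value}" for e in edge_list]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        paths[et.value] = path
    return paths
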