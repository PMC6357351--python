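"""Validation of TF->gene edges against an independent expression matrix.

An edge is *verified* when the TF and its target are co-expressed in an
independent dataset: sample Pearson correlation |r| > 0.3, two-sided
P < 0.05, and Benjamini-Hochberg FDR < 0.1, the FDR family being the
testable TF-gene edges of the queried network.  Edges whose endpoints
cannot be found in the matrix (after probe collapsing and ortholog
mapping), or with fewer than 3 pairwise-complete samples, or with a
constant vector, are *untestable*; they still count in the denominator
of the headline verified fraction so that fraction stays well-defined.

The expression data may come from another species (the reference use
case validates human edges against mouse maxillary-process arrays);
symbols are matched case-insensitively by default, or through an
explicit one-to-one ortholog map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import EdgeType, ExpressionMatrix, RegulatoryEdge, RegulatoryNetwork

__all__ = [
    "UntestableEdgeError",
    "ValidationResult",
    "ValidationSummary",
    "collapse_probes",
    "pearson_edge",
    "validate_edges",
]


class UntestableEdgeError(ValueError):
    """Raised when a correlation is undefined (n < 3 or zero variance)."""


@dataclass(frozen=True)
class ValidationResult:
    edge: RegulatoryEdge
    r: float | None
    n_used: int
    p: float | None
    q: float | None
    status: str  # verified | not_verified | untestable
    reason: str = ""


@dataclass(frozen=True)
class ValidationSummary:
    n_edges: int
    n_testable: int
    n_verified: int

    @property
    def fraction(self) -> float:
        """n_verified / n_edges — untestable edges count as unverified."""
        return self.n_verified / self.n_edges if self.n_edges else float("nan")


def collapse_probes(
    matrix: ExpressionMatrix,
    probe2gene: Mapping[str, str],
    method: str = "max_mean",
) -> ExpressionMatrix:
    """Collapse a probe-level matrix to one row per gene symbol.

    ``max_mean`` (default) keeps, per gene, the probe with the highest
    mean expression — the usual choice for picking the best-responding
    probe on expression arrays; ``mean``/``median`` aggregate across a
    gene's probes elementwise.  Unmapped probes are dropped (their count
    is retained in the result's metadata).
    """
    if method not in ("max_mean", "mean", "median"):
        raise ValueError(f"unknown collapse method {method!r}")
    df = matrix.values
    mapped = [p for p in df.index if p in probe2gene]
    if not mapped:
        raise ValueError("probe2gene maps none of the matrix rows")
    n_unmapped = len(df.index) - len(mapped)
    sub = df.loc[mapped]
    genes = pd.Series([probe2gene[p] for p in mapped], index=sub.index)
    if method == "max_mean":
        means = sub.mean(axis=1, skipna=True)
        best = (
            pd.DataFrame({"gene": genes, "mean": means})
            .sort_values(["gene", "mean"], ascending=[True, False], kind="mergesort")
            .drop_duplicates("gene")
        )
        out = sub.loc[best.index]
        out.index = best["gene"].tolist()
        out = out.sort_index()
    else:
        agg = "mean" if method == "mean" else "median"
        out = sub.groupby(genes.values).agg(agg)
        out = out.sort_index()
    meta = dict(matrix.metadata)
    meta["collapse"] = [f"method={method}", f"unmapped_probes={n_unmapped}"]
    return ExpressionMatrix(values=out, metadata=meta)


def pearson_edge(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, int]:
    """Pearson r and two-sided p over pairwise-complete observations.

    p comes from t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of
    freedom; a perfect |r| = 1 yields p = 0 by convention.  Raises
    :class:`UntestableEdgeError` when fewer than 3 complete pairs remain
    or either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    mask = ~(np.isnan(x) | np.isnan(y))
    n_used = int(mask.sum())
    if n_used < 3:
        raise UntestableEdgeError(f"only {n_used} pairwise-complete samples (< 3)")
    xv, yv = x[mask], y[mask]
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise UntestableEdgeError("zero variance in one of the vectors")
    r = float(np.corrcoef(xv, yv)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0 - 1e-14:
        return (math.copysign(1.0, r), 0.0, n_used)
    df = n_used - 2
    t = r * math.sqrt(df / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return (r, min(p, 1.0), n_used)


def _build_lookup(
    row_ids: Sequence[str], ortholog_map: Mapping[str, str] | None
) -> dict[str, str]:
    """symbol -> matrix row resolver.

    With an explicit ortholog map, the network symbol is first mapped
    and then matched case-insensitively; without one, case-insensitive
    symbol identity is the mapping (human SHH vs mouse Shh).  First
    occurrence wins on case-duplicated rows, deterministically.
    """
    upper: dict[str, str] = {}
    for rid in row_ids:
        upper.setdefault(str(rid).upper(), str(rid))

    def resolve(symbol: str) -> str | None:
        if ortholog_map is not None:
            mapped = ortholog_map.get(symbol)
            if mapped is None:
                return None
            return upper.get(mapped.upper())
        return upper.get(symbol.upper())

    return {"resolve": resolve}  # type: ignore[return-value]


def validate_edges(
    network: RegulatoryNetwork,
    matrix: ExpressionMatrix,
    ortholog_map: Mapping[str, str] | None = None,
    r_min: float = 0.3,
    p_max: float = 0.05,
    q_max: float = 0.1,
) -> tuple[list[ValidationResult], ValidationSummary]:
    """Test every TF->gene edge of a network for co-expression support.

    BH q-values are computed across the testable edges of this network
    (per-network adjustment).  Returns one result per edge, sorted by
    (source, target), plus the summary counts.
    """
    tf_gene = sorted(
        network.edges_of_type(EdgeType.TF_GENE), key=lambda e: (e.source, e.target)
    )
    if not tf_gene:
        raise ValueError("network has no TF_gene edges to validate")
    lookup = _build_lookup(matrix.row_ids, ortholog_map)
    resolve = lookup["resolve"]

    df = matrix.values
    testable: list[tuple[RegulatoryEdge, float, float, int]] = []
    untestable: list[ValidationResult] = []
    for e in tf_gene:
        row_tf, row_g = resolve(e.source), resolve(e.target)
        if row_tf is None or row_g is None:
            missing = [s for s, r in ((e.source, row_tf), (e.target, row_g)) if r is None]
            untestable.append(
                ValidationResult(
                    edge=e, r=None, n_used=0, p=None, q=None,
                    status="untestable",
                    reason=f"not in matrix: {', '.join(missing)}",
                )
            )
            continue
        try:
            r, p, n_used = pearson_edge(df.loc[row_tf].values, df.loc[row_g].values)
        except UntestableEdgeError as exc:
            untestable.append(
                ValidationResult(
                    edge=e, r=None, n_used=0, p=None, q=None,
                    status="untestable", reason=str(exc),
                )
            )
            continue
        testable.append((e, r, p, n_used))

    results: list[ValidationResult] = list(untestable)
    n_verified = 0
    if testable:
        pvals = np.array([p for (_, _, p, _) in testable])
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
        for (e, r, p, n_used), q in zip(testable, qvals):
            verified = (abs(r) > r_min) and (p < p_max) and (q < q_max)
            n_verified += int(verified)
            results.append(
                ValidationResult(
                    edge=e, r=r, n_used=n_used, p=p, q=float(q),
                    status="verified" if verified else "not_verified",
                )
            )
    if not testable:
        raise ValueError("no testable TF_gene edges (all endpoints unmatched)")
    results.sort(key=lambda v: (v.edge.source, v.edge.target))
    summary = ValidationSummary(
        n_edges=len(tf_gene), n_testable=len(testable), n_verified=n_verified
    )
    return results, summary


def write_validation_table(results: Sequence[ValidationResult], path) -> None:
    lines = ["tf\tgene\tr\tn_used\tp\tq\tstatus\treason"]
    for v in results:
        fmt = lambda x: "" if x is None else f"{x:.6g}"
        lines.append(
            f"{v.edge.source}\t{v.edge.target}\t{fmt(v.r)}\t{v.n_used}"
            f"\t{fmt(v.p)}\t{fmt(v.q)}\t{v.status}\t{v.reason}"
        )
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
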