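"""Hypergeometric over-representation analysis with BH correction.

Given a query gene list and a collection of gene sets, each set is
scored by the upper-tail hypergeometric probability of drawing at least
the observed overlap when sampling the query size from the background
universe, followed by Benjamini-Hochberg adjustment across all tested
sets.  This is the plain hypergeometric test (no EASE-style shrinkage);
the background defaults to the union of all set members and should be
overridden when a better universe (e.g. all assayed genes) is known.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .hubs import HubRanking
from .model import GeneSetCollection, NodeKind, RegulatoryNetwork

__all__ = [
    "EnrichmentResult",
    "hypergeom_pvalue",
    "enrich",
    "hub_target_enrichment",
]


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    description: str
    k: int  # query hits in the set
    K: int  # set size within background
    n: int  # query size within background
    N: int  # background size
    p: float
    q: float
    significant: bool
    hits: tuple[str, ...] = ()


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n).

    Equals sum_{i=k}^{min(K,n)} C(K,i) C(N-K, n-i) / C(N,n); k = 0
    gives exactly 1.  Computed through scipy's log-space survival
    function for numerical stability.
    """
    if min(k, K, n, N) < 0:
        raise ValueError("arguments must be non-negative")
    if K > N or n > N:
        raise ValueError("set and query sizes cannot exceed the background size")
    if k > min(K, n):
        raise ValueError(f"overlap k={k} exceeds min(K={K}, n={n})")
    if k == 0:
        return 1.0
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 0.0), 1.0)


def enrich(
    query: Iterable[str],
    sets: GeneSetCollection,
    background: Iterable[str] | None = None,
    q_threshold: float = 0.05,
) -> list[EnrichmentResult]:
    """Score every gene set against a query; BH across all tested sets.

    Query genes outside the background are dropped (a warning reports
    how many); sets are intersected with the background and skipped if
    the intersection is empty.  Results are sorted by (q, p, term).
    """
    bg = frozenset(background) if background is not None else sets.effective_background()
    if not bg:
        raise ValueError("background universe is empty")
    query_set = set(query)
    query_bg = query_set & bg
    dropped = len(query_set) - len(query_bg)
    if dropped:
        warnings.warn(
            f"{dropped} query gene(s) absent from the background were dropped",
            stacklevel=2,
        )
    if not query_bg:
        raise ValueError("query and background do not overlap")

    N, n = len(bg), len(query_bg)
    tested: list[tuple[str, str, int, int, tuple[str, ...]]] = []
    for gs in sets:
        members_bg = gs.members & bg
        if not members_bg:
            continue
        hits = tuple(sorted(query_bg & members_bg))
        tested.append((gs.term, gs.description, len(hits), len(members_bg), hits))
    if not tested:
        raise ValueError("no gene set overlaps the background")

    pvals = np.array([hypergeom_pvalue(k, K, n, N) for (_, _, k, K, _) in tested])
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    results = [
        EnrichmentResult(
            term=term, description=desc, k=k, K=K, n=n, N=N,
            p=float(p), q=float(q), significant=bool(q < q_threshold), hits=hits,
        )
        for (term, desc, k, K, hits), p, q in zip(tested, pvals, qvals)
    ]
    results.sort(key=lambda r: (r.q, r.p, r.term))
    return results


def hub_target_enrichment(
    network: RegulatoryNetwork,
    hubs: HubRanking,
    sets: GeneSetCollection,
    background: Iterable[str] | None = None,
    q_threshold: float = 0.05,
) -> dict[str, list[EnrichmentResult]]:
    """Enrichment of each hub regulator's direct target set.

    Only TF and miRNA hubs are queried (a gene hub has no outgoing
    regulation); hubs without targets are skipped with a warning.
    """
    out: dict[str, list[EnrichmentResult]] = {}
    for rec in hubs:
        if rec.kind == NodeKind.GENE.value:
            continue
        targets = network.targets_of(rec.node)
        if not targets:
            warnings.warn(f"hub {rec.node} has no targets; skipped", stacklevel=2)
            continue
        try:
            out[rec.node] = enrich(targets, sets, background, q_threshold)
        except ValueError as exc:
            warnings.warn(f"hub {rec.node}: {exc}; skipped", stacklevel=2)
    return out


def write_enrichment_table(results: Sequence[EnrichmentResult], path) -> None:
    lines = ["term\tdescription\tk\tK\tn\tN\tp\tq\tsignificant\thits"]
    for r in results:
        lines.append(
            f"{r.term}\t{r.description}\t{r.k}\t{r.K}\t{r.n}\t{r.N}"
            f"\t{r.p:.6g}\t{r.q:.6g}\t{str(r.significant).lower()}"
            f"\t{','.join(r.hits)}"
        )
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
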