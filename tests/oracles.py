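"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (triple loops, exhaustive subset
enumeration, direct combinatorial sums) and shares no code with the
package's own algorithms.
"""

from __future__ import annotations

import math
from itertools import combinations

from fflnet.model import EdgeType, RegulatoryEdge


def brute_force_ffls(edges) -> list[tuple[str, str, str, str]]:
    """O(|TF| * |miRNA| * |gene|) scan for classified FFL triples."""
    tf_gene, mirna_gene, tf_mirna, mirna_tf = set(), set(), set(), set()
    tfs, mirnas, genes = set(), set(), set()
    for e in edges:
        pair = (e.source, e.target)
        if e.edge_type is EdgeType.TF_GENE:
            tf_gene.add(pair); tfs.add(e.source); genes.add(e.target)
        elif e.edge_type is EdgeType.MIRNA_GENE:
            mirna_gene.add(pair); mirnas.add(e.source); genes.add(e.target)
        elif e.edge_type is EdgeType.TF_MIRNA:
            tf_mirna.add(pair); tfs.add(e.source); mirnas.add(e.target)
        elif e.edge_type is EdgeType.MIRNA_TF:
            mirna_tf.add(pair); mirnas.add(e.source); tfs.add(e.target)
    out = []
    for t in sorted(tfs):
        for m in sorted(mirnas):
            down = (t, m) in tf_mirna
            up = (m, t) in mirna_tf
            if not (down or up):
                continue
            label = "C" if (down and up) else ("A" if down else "B")
            for g in sorted(genes):
                if (t, g) in tf_gene and (m, g) in mirna_gene:
                    out.append((t, m, g, label))
    out.sort()
    return out


def random_kind_consistent_edges(rng, n_tf=10, n_mirna=8, n_gene=20, density=0.1):
    """Random typed edge list over disjoint universes."""
    tfs = [f"T{i}" for i in range(n_tf)]
    mirnas = [f"m{i}" for i in range(n_mirna)]
    genes = [f"G{i}" for i in range(n_gene)]
    edges = []
    for src_pool, dst_pool, et in (
        (tfs, genes, EdgeType.TF_GENE),
        (tfs, mirnas, EdgeType.TF_MIRNA),
        (mirnas, genes, EdgeType.MIRNA_GENE),
        (mirnas, tfs, EdgeType.MIRNA_TF),
    ):
        for s in src_pool:
            for d in dst_pool:
                if rng.random() < density:
                    edges.append(RegulatoryEdge(s, d, et))
    return edges


def exhaustive_maximal_cliques(nodes, adj) -> list[frozenset]:
    """All maximal cliques by checking every subset (graphs <= ~15 nodes).

    ``adj`` is a symmetric {node: set(neighbors)} mapping.
    """
    nodes = list(nodes)
    cliques = []
    for size in range(1, len(nodes) + 1):
        for sub in combinations(nodes, size):
            if all(v in adj[u] for u, v in combinations(sub, 2)):
                cliques.append(frozenset(sub))
    maximal = [
        c for c in cliques
        if not any(c < other for other in cliques)
    ]
    return maximal


def exhaustive_mcc(nodes, adj) -> dict[str, int]:
    """MCC from the exhaustive clique list; isolated nodes score 0."""
    scores = {n: 0 for n in nodes}
    for clique in exhaustive_maximal_cliques(nodes, adj):
        if len(clique) < 2:
            continue
        w = math.factorial(len(clique) - 1)
        for n in clique:
            scores[n] += w
    return scores


def bh_stepup(pvals) -> list[float]:
    """Textbook Benjamini-Hochberg step-up adjusted p-values."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvals[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj


def hypergeom_upper_tail(k, K, n, N) -> float:
    """Direct combinatorial sum P(X >= k), exact rational arithmetic."""
    total = math.comb(N, n)
    num = sum(
        math.comb(K, i) * math.comb(N - K, n - i)
        for i in range(k, min(K, n) + 1)
        if n - i <= N - K
    )
    return num / total


def fisher_z_power(rho, n, r_crit) -> float:
    """P(r > r_crit) for sample correlation at true rho, via Fisher's z.

    z = atanh(r) is approximately N(atanh(rho), 1/(n-3)).
    """
    from math import atanh, erf, sqrt

    z_crit = atanh(r_crit)
    z_mu = atanh(rho)
    se = 1.0 / sqrt(n - 3)
    x = (z_crit - z_mu) / se
    return 0.5 * (1.0 - erf(x / sqrt(2.0)))
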