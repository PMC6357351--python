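"""Markov clustering (MCL) of regulatory networks.

MCL simulates flow on a graph: random walks tend to stay inside
clusters, so alternately *expanding* (taking a power of the
column-stochastic transition matrix, letting flow spread) and
*inflating* (raising entries to a power r > 1 and renormalizing
columns, sharpening strong flows and starving weak ones) drives the
matrix to a limit whose attractor rows spell out the clustering.

Conventions here are the canonical ones: unit edge weights on the
undirected projection, a self-loop of weight 1 added to every node
before normalization, expansion e = 2 and inflation r = 2.0 by default.
Entries below ``prune_threshold`` are zeroed (with column
renormalization) each iteration, and convergence is declared when the
largest absolute entry change drops below ``tol``.

Clusters are read off the converged matrix: every node i with positive
return flow (M[i, i] > threshold) is an attractor and claims the nodes
whose columns feed it; attractors with identical support belong to one
attractor system and yield one cluster.  In the rare case of
overlapping attractor supports, a node goes to the first cluster in
deterministic (sorted smallest-member) order and the overlap is
recorded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import RegulatoryNetwork
from .hubs import undirected_projection

__all__ = ["ModulePartition", "mcl", "filter_modules"]


@dataclass
class ModulePartition:
    """Disjoint node modules plus the nodes left unassigned.

    Invariant: modules are pairwise disjoint and modules + unassigned
    cover the network's node set.
    """

    modules: list[tuple[str, ...]]
    unassigned: tuple[str, ...]
    params: dict
    converged: bool = True
    n_iter: int = 0
    overlaps: list[str] = field(default_factory=list)

    def sizes(self) -> list[int]:
        return [len(m) for m in self.modules]

    def all_nodes(self) -> set[str]:
        out = set(self.unassigned)
        for m in self.modules:
            out.update(m)
        return out

    def module_of(self, node: str) -> int | None:
        for i, m in enumerate(self.modules):
            if node in m:
                return i
        return None


def _column_normalize(m: np.ndarray) -> np.ndarray:
    col = m.sum(axis=0, keepdims=True)
    col[col == 0.0] = 1.0
    return m / col


def mcl(
    network: RegulatoryNetwork,
    inflation: float = 2.0,
    expansion: int = 2,
    max_iter: int = 100,
    tol: float = 1e-6,
    prune_threshold: float = 1e-5,
    trace: list | None = None,
) -> ModulePartition:
    """Run MCL on the undirected projection of a network.

    Returns the raw (pre-size-filter) partition.  ``inflation`` must
    exceed 1 (at r = 1 inflation is the identity and flow never
    sharpens).  Non-convergence within ``max_iter`` returns the current
    clustering with ``converged=False`` and a warning.  Passing a list
    as ``trace`` collects a copy of the transition matrix after every
    inflation step (diagnostics; the matrix must stay column-stochastic
    throughout).
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    if expansion < 2:
        raise ValueError("expansion must be >= 2")
    if len(network) == 0:
        raise ValueError("cannot cluster an empty network")

    g = undirected_projection(network)
    nodes = sorted(g.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    a = np.zeros((n, n), dtype=float)
    for u, v in g.edges:
        a[index[u], index[v]] = 1.0
        a[index[v], index[u]] = 1.0
    np.fill_diagonal(a, 1.0)  # self-loops dampen odd-cycle oscillation
    m = _column_normalize(a)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        expanded = np.linalg.matrix_power(m, expansion)
        inflated = _column_normalize(expanded**inflation)
        inflated[inflated < prune_threshold] = 0.0
        inflated = _column_normalize(inflated)
        change = float(np.max(np.abs(inflated - m)))
        m = inflated
        if trace is not None:
            trace.append(m.copy())
        if change < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"MCL did not converge within {max_iter} iterations", stacklevel=2
        )

    modules, overlaps = _read_clusters(m, nodes, prune_threshold)
    return ModulePartition(
        modules=modules,
        unassigned=(),
        params={
            "expansion": expansion,
            "inflation": inflation,
            "prune_threshold": prune_threshold,
            "max_iter": max_iter,
            "tol": tol,
        },
        converged=converged,
        n_iter=it,
        overlaps=overlaps,
    )


def _read_clusters(
    m: np.ndarray, nodes: list[str], threshold: float
) -> tuple[list[tuple[str, ...]], list[str]]:
    n = len(nodes)
    attractors = [i for i in range(n) if m[i, i] > threshold]
    raw: list[frozenset[int]] = []
    for i in attractors:
        support = frozenset(np.flatnonzero(m[i, :] > threshold).tolist()) | {i}
        if support not in raw:
            raw.append(support)
    # nodes claimed by no attractor row (numerically starved columns) each
    # join the attractor their column feeds most strongly
    claimed = set().union(*raw) if raw else set()
    for j in range(n):
        if j not in claimed:
            i = int(np.argmax(m[:, j]))
            for k, sup in enumerate(raw):
                if i in sup:
                    raw[k] = sup | {j}
                    break
            else:
                raw.append(frozenset({j}))

    clusters = sorted(
        ({nodes[i] for i in sup} for sup in raw),
        key=lambda s: min(s),
    )
    seen: set[str] = set()
    out: list[tuple[str, ...]] = []
    overlaps: list[str] = []
    for cluster in clusters:
        dupes = cluster & seen
        if dupes:
            overlaps.extend(sorted(dupes))
            cluster = cluster - seen
        if cluster:
            out.append(tuple(sorted(cluster)))
            seen |= cluster
    if overlaps:
        warnings.warn(
            f"overlapping attractor supports; nodes {sorted(set(overlaps))} "
            "assigned to their first cluster in sorted order",
            stacklevel=2,
        )
    return out, overlaps


def filter_modules(partition: ModulePartition, min_size: int = 3) -> ModulePartition:
    """Move modules smaller than ``min_size`` to the unassigned set.

    Small clusters carry little biological signal at this network scale,
    hence the default minimum of three nodes.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    kept = [m for m in partition.modules if len(m) >= min_size]
    dropped: list[str] = list(partition.unassigned)
    for m in partition.modules:
        if len(m) < min_size:
            dropped.extend(m)
    return ModulePartition(
        modules=kept,
        unassigned=tuple(sorted(dropped)),
        params={**partition.params, "min_size": min_size},
        converged=partition.converged,
        n_iter=partition.n_iter,
        overlaps=list(partition.overlaps),
    )


def write_partition(partition: ModulePartition, path) -> None:
    """Module TSV: ``node<TAB>module`` (1-based id or 'unassigned')."""
    lines = ["node\tmodule"]
    for i, module in enumerate(partition.modules, start=1):
        lines += [f"{node}\t{i}" for node in module]
    lines += [f"{node}\tunassigned" for node in partition.unassigned]
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
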