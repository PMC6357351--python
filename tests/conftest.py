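from __future__ import annotations

import pytest

from fflnet.model import EdgeType, RegulatoryEdge


def edge(source: str, target: str, et: EdgeType | str) -> RegulatoryEdge:
    return RegulatoryEdge(source, target, EdgeType(et))


@pytest.fixture
def motif_a_edges():
    """Minimal motif-A pattern: T1->G1, T1->m1, m1->G1."""
    return [
        edge("T1", "G1", EdgeType.TF_GENE),
        edge("T1", "m1", EdgeType.TF_MIRNA),
        edge("m1", "G1", EdgeType.MIRNA_GENE),
    ]


@pytest.fixture
def motif_c_edges(motif_a_edges):
    """Motif C: the A pattern plus the reciprocal m1->T1 edge."""
    return motif_a_edges + [edge("m1", "T1", EdgeType.MIRNA_TF)]
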