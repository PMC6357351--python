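"""Co-expression validation of TF->gene edges."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fflnet.model import EdgeType, ExpressionMatrix, RegulatoryNetwork
from fflnet.validation import (
    UntestableEdgeError,
    collapse_probes,
    pearson_edge,
    validate_edges,
)

from conftest import edge
from oracles import bh_stepup


def matrix_from(rows: dict[str, list[float]]) -> ExpressionMatrix:
    df = pd.DataFrame(rows).T
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    return ExpressionMatrix(values=df)


class TestPearsonEdge:
    def test_affine_dependence_gives_r_one_p_zero(self):
        x = list(range(10))
        y = [2 * v + 1 for v in x]
        r, p, n = pearson_edge(x, y)
        assert (r, p, n) == (1.0, 0.0, 10)

    def test_r_point_three_at_n35_fails_p_gate(self):
        # t = 0.3*sqrt(33/0.91) ~ 1.807 on 33 df -> two-sided p ~ 0.080
        rng = np.random.default_rng(0)
        # build vectors with exact sample correlation 0.3 via Gram-Schmidt
        x = rng.standard_normal(35)
        z = rng.standard_normal(35)
        x = (x - x.mean()) / x.std()
        z = z - z.mean()
        z -= (z @ x) / (x @ x) * x  # orthogonal to x
        z /= z.std()
        y = 0.3 * x + np.sqrt(1 - 0.09) * z
        r, p, n = pearson_edge(x, y)
        assert r == pytest.approx(0.3, abs=1e-12)
        assert p == pytest.approx(0.080, abs=0.0005)
        assert p > 0.05

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        x, y = rng.standard_normal(20), rng.standard_normal(20)
        assert pearson_edge(x, y) == pearson_edge(y, x)

    def test_constant_vector_untestable(self):
        with pytest.raises(UntestableEdgeError, match="variance"):
            pearson_edge([1.0] * 10, list(range(10)))

    def test_pairwise_complete_handling(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [1.1, 2.2, 3.0, np.nan, 5.1]
        r, p, n = pearson_edge(x, y)
        assert n == 3

    def test_too_few_complete_pairs_untestable(self):
        with pytest.raises(UntestableEdgeError, match="< 3"):
            pearson_edge([1.0, 2.0, np.nan], [1.0, np.nan, 3.0])


class TestCollapseProbes:
    def _matrix(self):
        return matrix_from({
            "p1": [1.0, 2.0, 3.0],
            "p2": [3.0, 4.0, 5.0],
            "p3": [9.0, 9.0, 9.0],
        })

    def test_max_mean_keeps_highest_mean_probe(self):
        out = collapse_probes(self._matrix(), {"p1": "GATA3", "p2": "GATA3"})
        assert out.row_ids == ["GATA3"]
        assert out.values.loc["GATA3"].tolist() == [3.0, 4.0, 5.0]

    def test_single_probe_identity(self):
        out = collapse_probes(self._matrix(), {"p3": "SHH"})
        assert out.values.loc["SHH"].tolist() == [9.0, 9.0, 9.0]

    def test_mean_method_averages_elementwise(self):
        out = collapse_probes(
            self._matrix(), {"p1": "GATA3", "p2": "GATA3"}, method="mean"
        )
        assert out.values.loc["GATA3"].tolist() == [2.0, 3.0, 4.0]

    def test_unmapped_probes_counted(self):
        out = collapse_probes(self._matrix(), {"p1": "GATA3"})
        assert "unmapped_probes=2" in out.metadata["collapse"][1]

    def test_empty_intersection_is_an_error(self):
        with pytest.raises(ValueError, match="none of the matrix rows"):
            collapse_probes(self._matrix(), {"zz": "SHH"})


class TestValidateEdges:
    def _single_edge_net(self):
        return RegulatoryNetwork([edge("TFX", "GY", EdgeType.TF_GENE)])

    def test_single_affine_edge_fraction_one_and_q_equals_p(self):
        net = self._single_edge_net()
        m = matrix_from({"TFX": [1, 2, 3, 4, 5, 6], "GY": [2, 4, 6, 8, 10, 12]})
        results, summary = validate_edges(net, m)
        assert summary.fraction == 1.0
        (res,) = results
        assert res.status == "verified" and res.q == res.p == 0.0

    def test_case_insensitive_symbol_matching(self):
        # human symbols vs mouse-style capitalization
        net = self._single_edge_net()
        m = matrix_from({"Tfx": [1, 2, 3, 4], "Gy": [2, 4, 6, 8]})
        _, summary = validate_edges(net, m)
        assert summary.n_testable == 1 and summary.n_verified == 1

    def test_explicit_ortholog_map_used(self):
        net = self._single_edge_net()
        m = matrix_from({"OrthoT": [1, 2, 3, 4], "OrthoG": [2, 4, 6, 8]})
        _, summary = validate_edges(
            net, m, ortholog_map={"TFX": "OrthoT", "GY": "OrthoG"}
        )
        assert summary.n_verified == 1

    def test_missing_symbol_is_untestable_but_counted(self):
        net = RegulatoryNetwork([
            edge("TFX", "GY", EdgeType.TF_GENE),
            edge("TFX", "GZ", EdgeType.TF_GENE),
        ])
        m = matrix_from({"TFX": [1, 2, 3, 4], "GY": [2, 4, 6, 8]})
        results, summary = validate_edges(net, m)
        assert summary.n_edges == 2 and summary.n_testable == 1
        assert summary.fraction == 0.5
        status = {r.edge.target: r.status for r in results}
        assert status == {"GY": "verified", "GZ": "untestable"}

    def test_no_tf_gene_edges_is_an_error(self):
        net = RegulatoryNetwork([edge("m1", "GY", EdgeType.MIRNA_GENE)])
        with pytest.raises(ValueError, match="no TF_gene"):
            validate_edges(net, matrix_from({"GY": [1, 2, 3]}))

    def test_bh_family_is_the_testable_edges(self):
        rng = np.random.default_rng(42)
        n_edges, n = 20, 30
        edges = [edge(f"TF{i}", f"G{i}", EdgeType.TF_GENE) for i in range(n_edges)]
        rows = {}
        for i in range(n_edges):
            rows[f"TF{i}"] = rng.standard_normal(n)
            rows[f"G{i}"] = rng.standard_normal(n)
        results, _ = validate_edges(RegulatoryNetwork(edges), matrix_from(rows))
        pvals = [r.p for r in results]
        qvals = [r.q for r in results]
        np.testing.assert_allclose(qvals, bh_stepup(pvals), atol=1e-12)

    def test_decision_rule_equals_brute_force_thresholds(self):
        rng = np.random.default_rng(7)
        n_edges, n = 30, 35
        edges = [edge(f"TF{i}", f"G{i}", EdgeType.TF_GENE) for i in range(n_edges)]
        rows = {}
        for i in range(n_edges):
            t = rng.standard_normal(n)
            rows[f"TF{i}"] = t
            mix = 0.5 if i % 2 else 0.0
            rows[f"G{i}"] = mix * t + rng.standard_normal(n)
        results, summary = validate_edges(RegulatoryNetwork(edges), matrix_from(rows))
        expected = sum(
            1 for r in results
            if r.status != "untestable"
            and abs(r.r) > 0.3 and r.p < 0.05 and r.q < 0.1
        )
        assert summary.n_verified == expected
        for r in results:
            if r.status == "verified":
                assert abs(r.r) > 0.3 and r.p < 0.05 and r.q < 0.1
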