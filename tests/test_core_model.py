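"""Core domain types and file readers/writers."""

from __future__ import annotations

import pytest

from fflnet.io import (
    parse_pair_table,
    read_expression_matrix,
    read_gmt,
    read_network,
    write_network,
)
from fflnet.model import (
    EdgeType,
    KindConflictError,
    RegulatoryEdge,
    RegulatoryNetwork,
    check_kind_consistency,
)

from conftest import edge


class TestRegulatoryEdge:
    def test_self_loop_is_unconstructible(self):
        with pytest.raises(ValueError, match="self-loop"):
            RegulatoryEdge("SHH", "SHH", EdgeType.TF_GENE)

    def test_whitespace_trimmed_and_case_preserved(self):
        e = RegulatoryEdge(" DLX1 ", "hsa-mir-27b\t", EdgeType.TF_MIRNA)
        assert (e.source, e.target) == ("DLX1", "hsa-mir-27b")

    def test_kind_follows_edge_type(self):
        e = edge("m1", "T1", EdgeType.MIRNA_TF)
        assert e.source_kind.value == "miRNA"
        assert e.target_kind.value == "TF"


class TestKindConsistency:
    def test_conflicting_roles_raise_listing_all_offenders(self):
        edges = [
            edge("A", "X", EdgeType.TF_GENE),     # X is a gene
            edge("X", "m1", EdgeType.TF_MIRNA),   # ...and a TF: conflict
            edge("m1", "A", EdgeType.MIRNA_TF),   # A consistent (TF)
            edge("B", "Y", EdgeType.TF_GENE),     # Y gene
            edge("m1", "Y", EdgeType.MIRNA_TF),   # ...and TF: second conflict
        ]
        with pytest.raises(KindConflictError) as exc:
            check_kind_consistency(edges)
        assert set(exc.value.conflicts) == {"X", "Y"}

    def test_consistent_edges_infer_kinds(self, motif_c_edges):
        kinds = check_kind_consistency(motif_c_edges)
        assert kinds["T1"].value == "TF"
        assert kinds["m1"].value == "miRNA"
        assert kinds["G1"].value == "gene"

    def test_network_rejects_conflict_at_insertion(self):
        net = RegulatoryNetwork([edge("A", "X", EdgeType.TF_GENE)])
        with pytest.raises(KindConflictError):
            net.add_edge(edge("X", "m1", EdgeType.TF_MIRNA))


class TestParsePairTable:
    def _write(self, tmp_path, text):
        p = tmp_path / "pairs.tsv"
        p.write_text(text, encoding="utf-8")
        return p

    def test_distinct_rows_yield_all_edges(self, tmp_path):
        p = self._write(tmp_path, "T1\tG1\nT1\tG2\nT2\tG1\n")
        edges, rep = parse_pair_table(p, EdgeType.TF_GENE)
        assert len(edges) == 3
        assert rep.n_duplicates == 0 and rep.n_self_loops == 0

    def test_exact_duplicate_collapsed_and_counted(self, tmp_path):
        p = self._write(tmp_path, "T1\tG1\nT1\tG2\nT1\tG1\n")
        edges, rep = parse_pair_table(p, EdgeType.TF_GENE)
        assert len(edges) == 2
        assert rep.n_duplicates == 1

    def test_self_loop_row_dropped_and_recorded(self, tmp_path):
        p = self._write(tmp_path, "T1\tT1\nT1\tG1\n")
        edges, rep = parse_pair_table(p, EdgeType.TF_GENE)
        assert [e.target for e in edges] == ["G1"]
        assert rep.dropped_self_loops == [(1, "T1")]

    def test_malformed_row_names_line(self, tmp_path):
        p = self._write(tmp_path, "T1\tG1\nonly_one_field\n")
        with pytest.raises(ValueError, match="line 2"):
            parse_pair_table(p, EdgeType.TF_GENE)

    def test_type_column_conflict_is_an_error(self, tmp_path):
        p = self._write(tmp_path, "T1\tG1\tTF_gene\nT1\tm1\tTF_miRNA\n")
        with pytest.raises(ValueError, match="conflicts with declared"):
            parse_pair_table(p, EdgeType.TF_GENE)

    def test_typed_column_without_declared_type(self, tmp_path):
        p = self._write(tmp_path, "# comment\nT1\tG1\tTF_gene\nm1\tG1\tmiRNA_gene\n")
        edges, _ = parse_pair_table(p)
        assert {e.edge_type for e in edges} == {EdgeType.TF_GENE, EdgeType.MIRNA_GENE}


class TestExpressionReaders:
    def test_plain_tsv(self, tmp_path):
        p = tmp_path / "expr.tsv"
        p.write_text(
            "probe\ts1\ts2\ts3\nA\t1\t2\t3\nB\t4\t5\t6\nC\t7\t8\t9\nD\t0\t0\t1\n"
        )
        m = read_expression_matrix(p, "tsv")
        assert m.shape == (4, 3)
        assert m.sample_ids == ["s1", "s2", "s3"]

    def test_series_matrix_parses_only_fenced_block(self, tmp_path):
        p = tmp_path / "gse.txt"
        p.write_text(
            '!Series_title\t"maxillary development"\n'
            '!Sample_geo_accession\t"GSM1"\t"GSM2"\n'
            "!series_matrix_table_begin\n"
            '"ID_REF"\t"GSM1"\t"GSM2"\n'
            '"1001_at"\t5.1\t5.3\n'
            '"1002_at"\t8.2\t8.0\n'
            "!series_matrix_table_end\n"
        )
        m = read_expression_matrix(p, "series_matrix")
        assert m.shape == (2, 2)
        assert m.row_ids == ["1001_at", "1002_at"]
        assert "Series_title" in m.metadata

    def test_missing_fence_is_an_error(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("!Series_title\tx\n")
        with pytest.raises(ValueError, match="fence"):
            read_expression_matrix(p, "series_matrix")

    def test_duplicate_sample_names_rejected(self, tmp_path):
        p = tmp_path / "expr.tsv"
        p.write_text("probe\ts1\ts1\nA\t1\t2\n")
        with pytest.raises(ValueError, match="duplicate sample"):
            read_expression_matrix(p, "tsv")


class TestGmt:
    def test_sets_parsed_and_members_deduplicated(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("wnt\tWnt signaling\tWNT3A\tDVL2\tWNT3A\nhippo\t-\tYAP1\tTEAD1\n")
        coll = read_gmt(p)
        assert len(coll) == 2
        assert coll.sets["wnt"].members == frozenset({"WNT3A", "DVL2"})

    def test_short_line_error_names_line(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("ok\tdesc\tG1\nbroken\tdesc\n")
        with pytest.raises(ValueError, match="line 2"):
            read_gmt(p)

    def test_empty_file_warns(self, tmp_path):
        p = tmp_path / "empty.gmt"
        p.write_text("")
        with pytest.warns(UserWarning, match="empty"):
            coll = read_gmt(p)
        assert len(coll) == 0


class TestNetworkRoundTrip:
    @pytest.mark.parametrize("fmt", ["edge_tsv", "sif"])
    def test_write_then_read_is_identity(self, tmp_path, motif_c_edges, fmt):
        net = RegulatoryNetwork(motif_c_edges)
        path = tmp_path / f"net.{fmt}"
        write_network(net, path, fmt)
        assert read_network(path, fmt) == net

    def test_empty_network_writes_header_only(self, tmp_path):
        path = tmp_path / "net.tsv"
        write_network(RegulatoryNetwork(), path, "edge_tsv")
        assert path.read_text().strip() == "source\ttarget\tedge_type"

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="unknown network format"):
            write_network(RegulatoryNetwork(), tmp_path / "x", "xlsx")

    def test_graphml_has_kind_and_type_attributes(self, tmp_path, motif_a_edges):
        import networkx as nx

        net = RegulatoryNetwork(motif_a_edges)
        path = tmp_path / "net.graphml"
        write_network(net, path, "graphml")
        g = nx.read_graphml(path)
        assert g.nodes["T1"]["kind"] == "TF"
        assert g.edges["T1", "G1"]["edge_type"] == "TF_gene"
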