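"""Ground-truth recovery and statistical calibration of the generator."""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest

from fflnet.assembly import build_network
from fflnet.model import EdgeType, RegulatoryNetwork
from fflnet.motifs import enumerate_ffls
from fflnet.synthetic import (
    SimulationConfig,
    generate_expression,
    generate_pair_tables,
    write_tables,
)
from fflnet.validation import validate_edges

from conftest import edge
from oracles import fisher_z_power


def quiet_config(**kw) -> SimulationConfig:
    base = dict(
        n_tf=10, n_mirna=8, n_gene=20,
        planted_ffls={"A": 5, "B": 0, "C": 0},
        background_edge_rates={},
        seed=0,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestPlantedTables:
    def test_planted_a_motifs_recovered_exactly(self):
        tables, truth = generate_pair_tables(quiet_config())
        ffls = enumerate_ffls([e for es in tables.values() for e in es])
        assert Counter(f.motif_type for f in ffls) == {"A": 5}
        assert sorted((f.tf, f.mirna, f.gene, f.motif_type) for f in ffls) == truth.ffls

    def test_planted_c_motifs_stay_c_under_exclusive_rule(self):
        cfg = quiet_config(planted_ffls={"A": 0, "B": 0, "C": 2})
        tables, _ = generate_pair_tables(cfg)
        ffls = enumerate_ffls([e for es in tables.values() for e in es])
        assert Counter(f.motif_type for f in ffls) == {"C": 2}

    def test_mixed_planting_recovered_per_type(self):
        cfg = quiet_config(planted_ffls={"A": 7, "B": 4, "C": 3}, seed=3)
        tables, truth = generate_pair_tables(cfg)
        ffls = enumerate_ffls([e for es in tables.values() for e in es])
        assert Counter(f.motif_type for f in ffls) == {"A": 7, "B": 4, "C": 3}
        assert truth.counts_by_motif() == {"A": 7, "B": 4, "C": 3}

    @pytest.mark.parametrize("seed", range(5))
    def test_background_only_adds_ffls(self, seed):
        cfg = quiet_config(
            planted_ffls={"A": 6, "B": 3, "C": 2},
            background_edge_rates={
                "TF_gene": 0.1, "TF_miRNA": 0.05,
                "miRNA_gene": 0.05, "miRNA_TF": 0.03,
            },
            seed=seed,
        )
        tables, truth = generate_pair_tables(cfg)
        ffls = enumerate_ffls([e for es in tables.values() for e in es])
        found = Counter(f.motif_type for f in ffls)
        planted = truth.counts_by_motif()
        for t in "ABC":
            assert found[t] >= planted[t]
        planted_set = {(f[0], f[1], f[2]) for f in truth.ffls}
        found_set = {(f.tf, f.mirna, f.gene) for f in ffls}
        assert planted_set <= found_set

    def test_same_seed_byte_identical_tables(self, tmp_path):
        cfg = quiet_config(background_edge_rates={"TF_gene": 0.1})
        t1, _ = generate_pair_tables(cfg)
        t2, _ = generate_pair_tables(cfg)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_tables(t1, d1)
        write_tables(t2, d2)
        for et in EdgeType:
            f = f"pairs_{et.value}.tsv"
            assert (d1 / f).read_bytes() == (d2 / f).read_bytes()

    def test_capacity_error(self):
        cfg = quiet_config(n_tf=2, n_mirna=2, n_gene=1,
                           planted_ffls={"A": 3, "B": 2, "C": 1})
        with pytest.raises(ValueError, match="capacity"):
            generate_pair_tables(cfg)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="n_samples"):
            quiet_config(n_samples=2)
        with pytest.raises(ValueError, match="rho"):
            quiet_config(rho=1.0)
        with pytest.raises(ValueError, match="rate"):
            quiet_config(background_edge_rates={"TF_gene": 1.5})


class TestPlantedExpression:
    def _one_edge_network(self):
        return RegulatoryNetwork([edge("TF1", "G1", EdgeType.TF_GENE)])

    def test_high_rho_sample_r_concentrates(self):
        # rho=0.95, n=200: Fisher-z says |r - rho| < 0.05 with prob ~1
        net = self._one_edge_network()
        hits = 0
        for seed in range(100):
            cfg = quiet_config(rho=0.95, n_samples=200, frac_correlated=1.0,
                               seed=seed)
            matrix, truth = generate_expression(net, cfg)
            assert truth.correlated_edges == [("TF1", "G1")]
            r = np.corrcoef(matrix.values.loc["TF1"], matrix.values.loc["G1"])[0, 1]
            hits += abs(r - 0.95) <= 0.05
        assert hits >= 95

    def test_null_edges_rarely_verified(self):
        # rho irrelevant at frac_correlated=0: verification rate ~ 0
        edges = [edge(f"TF{i}", f"G{i}", EdgeType.TF_GENE) for i in range(50)]
        net = RegulatoryNetwork(edges)
        cfg = quiet_config(n_samples=100, frac_correlated=0.0, seed=1)
        matrix, truth = generate_expression(net, cfg)
        assert truth.correlated_edges == []
        _, summary = validate_edges(net, matrix)
        assert summary.n_verified <= 2

    def test_power_matches_fisher_z_at_reference_design(self):
        # rho=0.9, n=35, 1000 planted edges: verified fraction within
        # +/- 5 points of the analytic Pearson power
        edges = [edge(f"TF{i:04d}", f"G{i:04d}", EdgeType.TF_GENE)
                 for i in range(1000)]
        net = RegulatoryNetwork(edges)
        cfg = quiet_config(rho=0.9, n_samples=35, frac_correlated=1.0, seed=11)
        matrix, truth = generate_expression(net, cfg)
        assert len(truth.correlated_edges) == 1000
        _, summary = validate_edges(net, matrix)
        # critical r for the p < 0.05 gate at df = 33 (|r| > 0.3 is weaker)
        from scipy import stats

        t_crit = stats.t.ppf(0.975, 33)
        r_crit = float(t_crit / np.sqrt(33 + t_crit**2))
        power = fisher_z_power(0.9, 35, max(r_crit, 0.3))
        assert summary.fraction == pytest.approx(power, abs=0.05)

    def test_deterministic_and_stream_isolated(self):
        net = self._one_edge_network()
        cfg = quiet_config(rho=0.5, n_samples=20, frac_correlated=1.0, seed=9)
        m1, _ = generate_expression(net, cfg)
        m2, _ = generate_expression(net, cfg)
        assert m1.values.equals(m2.values)
        # regenerating tables does not consume the expression stream
        generate_pair_tables(cfg)
        m3, _ = generate_expression(net, cfg)
        assert m1.values.equals(m3.values)

    def test_requires_tf_gene_edges(self):
        net = RegulatoryNetwork([edge("m1", "G1", EdgeType.MIRNA_GENE)])
        with pytest.raises(ValueError, match="TF_gene"):
            generate_expression(net, quiet_config())
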