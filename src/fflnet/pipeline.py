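"""End-to-end pipeline orchestration.

``run_all`` chains every stage — simulate or ingest the pair tables,
enumerate feed-forward loops, assemble motif and combined networks,
rank hubs by MCC, partition modules with MCL, validate TF->gene edges
against expression, run enrichment, extract the pathway-seeded
subnetwork — writing per-stage artifacts to the output directory plus
one JSON manifest with every headline number.  Stages whose inputs are
not configured (no expression matrix, no GMT, no seeds) are recorded as
``skipped`` and the rest of the pipeline completes.  The manifest is a
pure function of (inputs, config): it records input checksums and all
parameters, and contains no timestamps, so identical runs produce
byte-identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import assembly, enrichment, hubs, io, motifs, subnetwork, validation
from .mcl import filter_modules as _filter_modules, mcl as _run_mcl, write_partition as _write_partition
from .model import EdgeType
from .synthetic import SimulationConfig, generate_expression, generate_pair_tables, write_tables

__all__ = ["PipelineConfig", "StageError", "run_all"]

log = logging.getLogger("fflnet")

_TABLE_KEYS = {
    "tf_gene": EdgeType.TF_GENE,
    "tf_mirna": EdgeType.TF_MIRNA,
    "mirna_gene": EdgeType.MIRNA_GENE,
    "mirna_tf": EdgeType.MIRNA_TF,
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    """All inputs and stage parameters for ``run_all``.

    Either ``pair_tables`` (mapping table key -> TSV path) or
    ``simulate`` (SimulationConfig fields) must be given; everything
    else is optional and its stage degrades to ``skipped``.
    """

    outdir: str = "fflnet_out"
    seed: int = 0
    pair_tables: dict[str, str] | None = None
    simulate: dict | None = None
    expression: str | None = None
    expression_format: str = "tsv"
    probe_map: str | None = None
    ortholog_map: str | None = None
    gmt: str | None = None
    background: str | None = None
    subnet_seeds: list[str] = field(default_factory=list)
    match_slot: str = "gene"
    k_hubs: int = 10
    inflation: float = 2.0
    min_module_size: int = 3
    r_min: float = 0.3
    p_max: float = 0.05
    q_max: float = 0.1
    enrich_fdr: float = 0.05

    def __post_init__(self) -> None:
        if self.pair_tables is None and self.simulate is None:
            raise ValueError("config needs either pair_tables or simulate")
        if not 0 < self.enrich_fdr < 1 or not 0 < self.p_max < 1 or not 0 < self.q_max < 1:
            raise ValueError("significance thresholds must lie in (0, 1)")
        if not 0 <= self.r_min < 1:
            raise ValueError("r_min must lie in [0, 1)")
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if self.k_hubs < 1 or self.min_module_size < 1:
            raise ValueError("k_hubs and min_module_size must be >= 1")
        if self.pair_tables is not None:
            unknown = set(self.pair_tables) - set(_TABLE_KEYS)
            if unknown:
                raise ValueError(f"unknown pair table keys: {sorted(unknown)}")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text(encoding="utf-8")
        if str(path).endswith((".yml", ".yaml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _two_col_map(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            a, b = line.split("\t")[:2]
            out[a.strip()] = b.strip()
    return out


def run_all(config: PipelineConfig) -> dict:
    """Run every configured stage; return (and write) the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": config.to_dict(),
        "inputs": {},
        "stages": {},
    }

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except StageError:
                raise
            except Exception as exc:
                _dump_manifest(manifest, outdir)  # retain partial outputs
                raise StageError(name, exc) from exc
            log.info("stage %-10s done in %.2fs", name, time.perf_counter() - t0)

        return deco

    state: dict = {}

    @stage("ingest")
    def _ingest():
        if config.simulate is not None:
            sim = SimulationConfig(**{**config.simulate, "seed": config.seed})
            tables, truth = generate_pair_tables(sim)
            paths = write_tables(tables, outdir / "simulated")
            truth.to_json(outdir / "simulated" / "ground_truth.json")
            state["edges"] = [e for es in tables.values() for e in es]
            state["sim"] = sim
            state["truth"] = truth
            manifest["stages"]["ingest"] = {
                "status": "simulated",
                "n_edges": len(state["edges"]),
                "tables": {k: str(v) for k, v in paths.items()},
            }
        else:
            specs = [(Path(p), _TABLE_KEYS[k]) for k, p in sorted(config.pair_tables.items())]
            edges, reports = io.edges_from_tables(specs)
            for p, _ in specs:
                manifest["inputs"][str(p)] = _sha256(p)
            state["edges"] = edges
            manifest["stages"]["ingest"] = {
                "status": "ok",
                "n_edges": len(edges),
                "dropped_duplicates": sum(r.n_duplicates for r in reports.values()),
                "dropped_self_loops": sum(r.n_self_loops for r in reports.values()),
            }

    @stage("enumerate")
    def _enumerate():
        ffls = motifs.enumerate_ffls(state["edges"])
        state["ffls"] = ffls
        motifs.write_ffl_table(ffls, outdir / "ffls.tsv")
        summary = motifs.motif_summary(ffls)
        summary.to_csv(outdir / "motif_summary.tsv", sep="\t")
        manifest["stages"]["enumerate"] = {
            "status": "ok",
            "n_ffls": len(ffls),
            "by_motif": {
                t: int(summary.loc[t, "n_ffls"]) for t in motifs.MOTIF_TYPES
            },
        }

    @stage("build")
    def _build():
        nets = {}
        for t in motifs.MOTIF_TYPES:
            nets[t] = assembly.build_network(state["ffls"], motif_filter={t})
        combined = assembly.build_network(state["ffls"])
        state["combined"] = combined
        io.write_network(combined, outdir / "combined_network.tsv", "edge_tsv")
        stats = {t: assembly.network_stats(n).as_dict() for t, n in nets.items()}
        stats["combined"] = assembly.network_stats(combined).as_dict()
        (outdir / "network_stats.json").write_text(
            json.dumps(stats, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        manifest["stages"]["build"] = {"status": "ok", "stats": stats}

    @stage("hubs")
    def _hubs():
        ranking = hubs.mcc_scores(state["combined"])
        top = hubs.top_k(ranking, config.k_hubs)
        state["hubs"] = top
        hubs.write_hub_table(ranking, outdir / "hubs.tsv")
        manifest["stages"]["hubs"] = {
            "status": "ok",
            "k": config.k_hubs,
            "top": [
                {"node": r.node, "kind": r.kind, "mcc": r.score, "rank": r.rank}
                for r in top
            ],
            "warnings": top.warnings,
        }

    @stage("cluster")
    def _cluster():
        part = _run_mcl(state["combined"], inflation=config.inflation)
        part = _filter_modules(part, config.min_module_size)
        state["modules"] = part
        _write_partition(part, outdir / "modules.tsv")
        manifest["stages"]["cluster"] = {
            "status": "ok",
            "n_modules": len(part.modules),
            "module_sizes": part.sizes(),
            "n_unassigned": len(part.unassigned),
            "converged": part.converged,
        }

    @stage("validate")
    def _validate():
        if config.expression is None and "sim" not in state:
            manifest["stages"]["validate"] = {"status": "skipped",
                                              "reason": "no expression matrix configured"}
            return
        if config.expression is not None:
            matrix = io.read_expression_matrix(config.expression, config.expression_format)
            manifest["inputs"][str(config.expression)] = _sha256(Path(config.expression))
            if config.probe_map:
                matrix = validation.collapse_probes(matrix, _two_col_map(config.probe_map))
                manifest["inputs"][str(config.probe_map)] = _sha256(Path(config.probe_map))
        else:
            matrix, expr_truth = generate_expression(state["combined"], state["sim"])
            matrix.values.to_csv(outdir / "simulated" / "expression.tsv", sep="\t")
            state["expr_truth"] = expr_truth
        omap = _two_col_map(config.ortholog_map) if config.ortholog_map else None
        results, summary = validation.validate_edges(
            state["combined"], matrix, ortholog_map=omap,
            r_min=config.r_min, p_max=config.p_max, q_max=config.q_max,
        )
        state["validation"] = (results, summary)
        validation.write_validation_table(results, outdir / "edge_validation.tsv")
        manifest["stages"]["validate"] = {
            "status": "ok",
            "n_edges": summary.n_edges,
            "n_testable": summary.n_testable,
            "n_verified": summary.n_verified,
            "verified_fraction": round(summary.fraction, 6),
        }

    @stage("enrich")
    def _enrich():
        if config.gmt is None:
            manifest["stages"]["enrich"] = {"status": "skipped",
                                            "reason": "no GMT configured"}
            return
        sets = io.read_gmt(config.gmt)
        manifest["inputs"][str(config.gmt)] = _sha256(Path(config.gmt))
        background = None
        if config.background:
            background = [
                line.strip()
                for line in Path(config.background).read_text(encoding="utf-8").splitlines()
                if line.strip() and not line.startswith("#")
            ]
            manifest["inputs"][str(config.background)] = _sha256(Path(config.background))
        combined = state["combined"]
        from .model import NodeKind

        query = sorted(
            combined.nodes_of_kind(NodeKind.GENE) | combined.nodes_of_kind(NodeKind.TF)
        )
        results = enrichment.enrich(query, sets, background, config.enrich_fdr)
        enrichment.write_enrichment_table(results, outdir / "enrichment_combined.tsv")
        per_module = {}
        for i, module in enumerate(state["modules"].modules, start=1):
            mod_query = [n for n in module if combined.kind_of(n) is not NodeKind.MIRNA]
            try:
                mod_res = enrichment.enrich(mod_query, sets, background, config.enrich_fdr)
            except ValueError:
                per_module[str(i)] = []
                continue
            enrichment.write_enrichment_table(mod_res, outdir / f"enrichment_module{i}.tsv")
            per_module[str(i)] = [r.term for r in mod_res if r.significant]
        manifest["stages"]["enrich"] = {
            "status": "ok",
            "n_sets_tested": len(results),
            "significant_terms": [r.term for r in results if r.significant],
            "significant_by_module": per_module,
        }

    @stage("subnet")
    def _subnet():
        if not config.subnet_seeds:
            manifest["stages"]["subnet"] = {"status": "skipped",
                                            "reason": "no seed genes configured"}
            return
        report = subnetwork.extract_subnetwork(
            state["ffls"], config.subnet_seeds, config.match_slot
        )
        for i, comp in enumerate(report.components, start=1):
            io.write_network(comp, outdir / f"subnetwork_component{i}.tsv", "edge_tsv")
        manifest["stages"]["subnet"] = {
            "status": "ok",
            "seeds_found": list(report.seeds_found),
            "seeds_missing": list(report.seeds_missing),
            "n_components": report.n_components,
            "overall": report.overall_stats.as_dict() if report.overall_stats else None,
        }

    if "sim" in state and "truth" in state:
        manifest["ground_truth"] = {
            "planted_ffls": state["truth"].counts_by_motif(),
        }
    if "expr_truth" in state:
        manifest["ground_truth"]["planted_correlated_edges"] = len(
            state["expr_truth"].correlated_edges
        )

    _dump_manifest(manifest, outdir)
    return manifest


def _dump_manifest(manifest: dict, outdir: Path) -> None:
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
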