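"""End-to-end orchestration: simulate/load -> DE -> meta -> network ->
enrichment (-> qPCR), with a machine-readable run manifest.

A :class:`PipelineConfig` either points at input files (per-study
expression + metadata TSVs, an edge list, GMT gene sets, optionally a qPCR
table) or carries a synthetic compendium spec. All thresholds the stages use
are collected here with the published defaults (per-study p < 0.05, combined
p < 0.001, votes >= 2, interaction score > 900, hub degree >= 10 / top 10%,
module size >= 5 at p < 0.05). Identical config + seed gives byte-identical
outputs and manifest checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import diffexpr, enrichment, io, meta, network, preprocess, synthetic, validation

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    # inputs: either file paths ...
    expression_paths: list[str] = field(default_factory=list)
    meta_paths: list[str] = field(default_factory=list)
    edge_list_path: str | None = None
    gmt_path: str | None = None
    aging_set_name: str | None = "AGING_REFERENCE"
    qpcr_path: str | None = None
    # ... or a synthetic spec
    synthetic_spec: dict | None = None
    synthetic_ppi: dict | None = None
    # preprocessing
    normalize: bool = False  # synthetic log2-scale data is already normalized
    collapse_rule: str = "mean"
    universe_mode: str = "intersection"
    # stage thresholds (published defaults)
    per_study_p: float = 0.05
    per_study_fdr: float | None = 0.05
    p_combined_threshold: float = 0.001
    vote_threshold: int = 2
    score_threshold: float = 900.0
    dc_min: int = 10
    top_fraction: float = 0.10
    min_module_size: int = 5
    module_alpha: float = 0.05
    n_perm: int = 999
    seed: int = 0
    output_dir: str = "results/pipeline"

    def validate(self) -> None:
        has_files = bool(self.expression_paths)
        has_synth = self.synthetic_spec is not None
        if not has_files and not has_synth:
            raise ValueError("config needs expression_paths or a synthetic_spec")
        for name, val, lo, hi in [
            ("per_study_p", self.per_study_p, 0, 1),
            ("p_combined_threshold", self.p_combined_threshold, 0, 1),
            ("module_alpha", self.module_alpha, 0, 1),
            ("top_fraction", self.top_fraction, 0, 1),
        ]:
            if not lo < val <= hi:
                raise ValueError(f"{name} out of range: {val}")
        if self.vote_threshold < 0 or self.dc_min < 0 or self.min_module_size < 1:
            raise ValueError("count thresholds must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write per-stage TSVs plus ``manifest.json``.

    Returns the manifest dict (seed, thresholds, per-stage gene counts, and
    a checksum per output file). Any stage failure propagates with the stage
    name in the exception message.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "thresholds": {
            "per_study_p": config.per_study_p,
            "per_study_fdr": config.per_study_fdr,
            "p_combined": config.p_combined_threshold,
            "vote_threshold": config.vote_threshold,
            "score_threshold": config.score_threshold,
            "dc_min": config.dc_min,
            "top_fraction": config.top_fraction,
            "min_module_size": config.min_module_size,
            "module_alpha": config.module_alpha,
            "n_perm": config.n_perm,
        },
        "counts": {},
        "outputs": {},
    }
    truth = None

    def stage(name):
        logger.info("pipeline stage: %s", name)
        return name

    try:
        name = stage("input")
        if config.synthetic_spec is not None:
            spec = synthetic.CompendiumSpec(**config.synthetic_spec, seed=config.seed)
            studies, truth = synthetic.generate_compendium(spec)
        else:
            studies = [
                io.read_study(e, m)
                for e, m in zip(config.expression_paths, config.meta_paths)
            ]

        name = stage("preprocess")
        if config.normalize:
            studies = [
                preprocess.StudyExpression(
                    s.study_id, preprocess.normalize_study(s.matrix), s.sample_meta
                )
                for s in studies
            ]
        for s in studies:
            s.validate()
        compendium = preprocess.build_compendium(studies, universe_mode=config.universe_mode)
        manifest["counts"]["studies"] = len(studies)
        manifest["counts"]["gene_universe"] = len(compendium.gene_universe)

        name = stage("diffexpr")
        de_results = {}
        for s in studies:
            de = diffexpr.moderated_t(
                s.matrix.loc[compendium.gene_universe], s.groups.loc[s.matrix.columns]
            )
            de_results[s.study_id] = de
            out = outdir / f"de_{s.study_id}.tsv"
            de.to_csv(out, sep="\t")
            manifest["outputs"][out.name] = _sha256(out)
        manifest["counts"]["de_significant"] = {
            sid: len(diffexpr.significant_genes(de, config.per_study_p, config.per_study_fdr))
            for sid, de in de_results.items()
        }

        name = stage("meta")
        meta_table = meta.meta_analyze(de_results, per_study_p=config.per_study_p)
        meta_table = meta.consensus(
            meta_table,
            p_combined_threshold=config.p_combined_threshold,
            vote_threshold=config.vote_threshold,
        )
        out = outdir / "meta.tsv"
        meta_table.to_csv(out, sep="\t")
        manifest["outputs"][out.name] = _sha256(out)
        consensus_genes = meta_table.index[meta_table["consensus"]].tolist()
        n_down = int((meta_table.loc[consensus_genes, "direction"] == "down").sum())
        n_up = int((meta_table.loc[consensus_genes, "direction"] == "up").sum())
        manifest["counts"]["per_method"] = {
            "fisher": int(meta_table["sig_fisher"].sum()),
            "fixed_effect": int(meta_table["sig_fe"].sum()),
            "votes": int(meta_table["sig_votes"].sum()),
        }
        manifest["counts"]["consensus"] = len(consensus_genes)
        manifest["consensus_genes"] = sorted(consensus_genes)
        if consensus_genes:
            manifest["counts"]["consensus_breakdown"] = meta.direction_breakdown(n_down, n_up)
        else:
            logger.warning("pipeline: empty consensus gene list")
            manifest["counts"]["consensus_breakdown"] = None

        name = stage("network")
        modules_list: list[network.ModuleResult] = []
        if config.edge_list_path is not None:
            edges = io.read_edge_list(config.edge_list_path)
        elif truth is not None:
            ppi_args = dict(config.synthetic_ppi or {})
            edges = synthetic.generate_ppi(truth, seed=config.seed, **ppi_args)
        else:
            edges = None
        if edges is not None and consensus_genes:
            graph, net_log = network.build_zero_order(
                edges, consensus_genes, score_threshold=config.score_threshold
            )
            manifest["counts"]["network"] = net_log
            if graph.number_of_nodes():
                directions = meta_table["direction"]
                hub_table = network.centralities(graph, directions=directions)
                hub_table = network.select_hubs(
                    hub_table, dc_min=config.dc_min,
                    top_fraction=config.top_fraction,
                    n_total_genes=len(consensus_genes),
                )
                out = outdir / "hubs.tsv"
                hub_table.to_csv(out, sep="\t", index=False)
                manifest["outputs"][out.name] = _sha256(out)
                manifest["counts"]["hubs"] = int(hub_table["hub"].sum())
                comps, modules_list = network.components_and_modules(
                    graph, min_size=config.min_module_size,
                    alpha=config.module_alpha, n_perm=config.n_perm,
                    seed=config.seed,
                )
                manifest["counts"]["components"] = len(comps)
                manifest["counts"]["continent_nodes"] = len(comps[0])
                manifest["counts"]["continent_edges"] = network._internal_edges(graph, comps[0])
                manifest["counts"]["modules"] = len(modules_list)
                rows = [
                    {"module": m.module_id, "kind": m.kind, "size": m.size,
                     "internal_edges": m.n_internal_edges, "p": m.p_value,
                     "members": ",".join(m.members)}
                    for m in modules_list
                ]
                out = outdir / "modules.tsv"
                pd.DataFrame(rows, columns=["module", "kind", "size", "internal_edges",
                                            "p", "members"]).to_csv(out, sep="\t", index=False)
                manifest["outputs"][out.name] = _sha256(out)
                network.export_graphml(graph, outdir / "network.graphml")

        name = stage("enrichment")
        gene_sets = None
        if config.gmt_path is not None:
            gene_sets = enrichment.read_gmt(config.gmt_path)
        elif truth is not None:
            gene_sets = synthetic.generate_gene_sets(truth, seed=config.seed)
        if gene_sets and consensus_genes:
            ora_table = enrichment.ora(
                consensus_genes, gene_sets, compendium.gene_universe
            )
            out = outdir / "ora.tsv"
            ora_table.to_csv(out, sep="\t", index=False)
            manifest["outputs"][out.name] = _sha256(out)
            manifest["counts"]["enriched_sets"] = int((ora_table["fdr"] < 0.05).sum())
            aging = (gene_sets or {}).get(config.aging_set_name or "", None)
            if aging and modules_list:
                rows = []
                for m in modules_list:
                    res = enrichment.odds_ratio_enrichment(
                        m.members, aging, compendium.gene_universe, name=m.module_id
                    )
                    rows.append({
                        "module": m.module_id, "a": res.a, "b": res.b, "c": res.c,
                        "d": res.d, "OR": res.odds_ratio, "ci_low": res.ci_low,
                        "ci_high": res.ci_high, "p": res.p_value,
                    })
                out = outdir / "aging_enrichment.tsv"
                pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
                manifest["outputs"][out.name] = _sha256(out)

        name = stage("qpcr")
        if config.qpcr_path is not None:
            table = io.read_qpcr(config.qpcr_path)
            rows = []
            for gene in sorted(table.loc[table["role"] == "target", "gene"].unique()):
                res = validation.ddct(table, target_gene=gene)
                treated = [g for g in res["summary"].index if g != "control"]
                rows.append({
                    "gene": gene,
                    "fold": res["summary"].loc[treated[0], "mean_fold"] if treated else 1.0,
                    "t": res["t"], "p": res["p"],
                })
            out = outdir / "qpcr.tsv"
            pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
            manifest["outputs"][out.name] = _sha256(out)
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        raise RuntimeError(f"pipeline failed at stage '{name}': {exc}") from exc

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def config_to_yaml(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config)))
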