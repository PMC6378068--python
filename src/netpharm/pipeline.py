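"""End-to-end pipeline orchestration.

Stages: merge per-herb tables → ADME screen (with whitelist rescue) →
confidence-filter edges → target map → disease-gene intersection and
compound pruning → GO / pathway over-representation → C-T and T-P
networks → integrated module-annotated pathway.  Every intermediate is
written as TSV/GraphML next to a machine-readable JSON run report whose
counts satisfy the pipeline identities (active = passed + rescued,
final = active − dropped, C-T nodes = final compounds + overlap genes
with edges).  Given identical config and inputs the run is fully
deterministic apart from the report timestamps.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import data_io, enrichment, network_analysis, pathway_integration, screening, target_mapping
from .data_io import Namespace, PipelineConfig

log = logging.getLogger("netpharm")

__all__ = ["PipelineInputs", "RunReport", "run_pipeline"]


@dataclass
class PipelineInputs:
    """File paths for one run: per-herb compound TSVs keyed by herb code,
    an edge list, a disease gene list and GMT collections (GO optional)."""

    compound_tables: dict
    edges: Path
    disease: Path
    pathway_gmt: Path
    go_gmt: Path | None = None
    disease_label: str = "disease"


@dataclass
class RunReport:
    """Machine twin of the run: per-stage counts, config hash and seed."""

    counts: dict
    config_hash: str
    seed: int
    started: str
    finished: str = ""

    def to_json(self, path) -> None:
        payload = {
            "counts": self.counts,
            "config_hash": self.config_hash,
            "seed": self.seed,
            "started": self.started,
            "finished": self.finished,
        }
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(payload, fh, indent=1)
            fh.write("\n")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def _write_screening_table(records, result, out_path):
    rows = []
    for rec in records:
        status = result.status(rec.mol_id)
        rows.append(
            {
                "mol_id": rec.mol_id,
                "name": rec.name,
                "herbs": ",".join(sorted(rec.herb_sources)),
                "ob": rec.ob,
                "dl": rec.dl,
                "caco2": rec.caco2,
                "status": status,
                "failed_criteria": ",".join(result.failures.get(rec.mol_id, ())),
            }
        )
    pd.DataFrame(rows).to_csv(out_path, sep="\t", index=False)


def _write_enrichment_table(results, out_path):
    rows = [
        {
            "set_id": r.set_id,
            "set_name": r.set_name,
            "k": r.k,
            "K": r.K,
            "n": r.n,
            "N": r.N,
            "p_value": r.p_value,
            "fdr": r.fdr,
            "retained": r.retained,
        }
        for r in results
    ]
    pd.DataFrame(
        rows,
        columns=["set_id", "set_name", "k", "K", "n", "N", "p_value", "fdr", "retained"],
    ).to_csv(out_path, sep="\t", index=False)


def run_pipeline(config: PipelineConfig, inputs: PipelineInputs, out_dir) -> RunReport:
    """Execute every stage, writing artifacts into ``out_dir``.

    Any stage failure raises :class:`StageError` naming the stage; partial
    artifacts written so far are retained alongside a ``FAILED`` marker.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    started = datetime.now(timezone.utc).isoformat()
    counts: dict = {}
    stage = "setup"
    try:
        # -- merge ----------------------------------------------------------
        stage = "merge"
        herb_lists = [
            data_io.read_compound_table(path, herb_code=herb)
            for herb, path in inputs.compound_tables.items()
        ]
        merged = screening.merge_herb_lists(herb_lists)
        counts["herb_tables"] = len(herb_lists)
        counts["compound_rows"] = sum(len(hl) for hl in herb_lists)
        counts["unique_compounds"] = len(merged)
        data_io.write_compound_table(merged, out_dir / "merged_compounds.tsv")

        # -- screen ---------------------------------------------------------
        stage = "screen"
        criteria = screening.ScreeningCriteria(
            ob_min=config.ob_min, dl_min=config.dl_min, caco2_min=config.caco2_min
        )
        screened = screening.screen_compounds(merged, criteria, set(config.whitelist))
        counts["passed"] = len(screened.passed)
        counts["rescued"] = len(screened.rescued)
        counts["rejected"] = len(screened.rejected)
        counts["active"] = len(screened.active)
        counts["pct_passed"] = (
            round(100.0 * len(screened.passed) / len(merged), 2) if merged else 0.0
        )
        _write_screening_table(merged, screened, out_dir / "screening.tsv")

        # -- target map -----------------------------------------------------
        stage = "map-targets"
        raw_edges = data_io.read_edge_list(inputs.edges)
        filtered = target_mapping.filter_predicted_edges(raw_edges, config.confidence_min)
        counts["edges_in"] = len(raw_edges)
        counts["edges_confident"] = len(filtered)
        target_map = target_mapping.build_target_map(screened.active, filtered)
        counts["targets"] = len(target_map.target_universe)
        data_io.write_edge_list(target_map.edges, out_dir / "target_map.tsv")

        # -- intersect / prune ----------------------------------------------
        stage = "intersect"
        disease = data_io.read_gene_list(inputs.disease, label=inputs.disease_label)
        counts["disease_genes"] = len(disease.genes)
        overlap = target_mapping.intersect_disease_genes(target_map, disease)
        retained_compounds, dropped_compounds = target_mapping.prune_compounds(
            overlap, screened
        )
        counts["overlap_genes"] = len(overlap.overlap_genes)
        counts["final_compounds"] = len(retained_compounds)
        counts["dropped_compounds"] = len(dropped_compounds)
        data_io.write_gene_list(
            data_io.DiseaseGeneList("overlap", overlap.overlap_genes),
            out_dir / "overlap_genes.txt",
        )

        # -- enrichment -----------------------------------------------------
        stage = "enrich"
        pathway_collection = data_io.read_gmt(inputs.pathway_gmt, namespace=Namespace.KEGG)
        pathway_results = enrichment.enrich(
            overlap.overlap_genes, pathway_collection, fdr_max=config.fdr_max
        )
        retained_pathways = [r for r in pathway_results if r.retained]
        counts["pathways_tested"] = len(pathway_results)
        counts["pathways_retained"] = len(retained_pathways)
        _write_enrichment_table(pathway_results, out_dir / "enrichment_pathways.tsv")
        if inputs.go_gmt is not None:
            go_collection = data_io.read_gmt(inputs.go_gmt, namespace=Namespace.GO_BP)
            go_results = enrichment.enrich(
                overlap.overlap_genes, go_collection, fdr_max=config.fdr_max
            )
            counts["go_tested"] = len(go_results)
            counts["go_retained"] = int(sum(r.retained for r in go_results))
            _write_enrichment_table(go_results, out_dir / "enrichment_go.tsv")

        # -- networks -------------------------------------------------------
        stage = "network"
        ct_net = network_analysis.build_ct_network(
            retained_compounds, overlap.overlap_genes, overlap.edges
        )
        ct_stats = network_analysis.degree_statistics(ct_net)
        counts["ct_nodes"] = ct_net.n_nodes
        counts["ct_edges"] = ct_net.n_edges
        counts["mean_edges_per_compound"] = round(ct_stats.mean_degree_side_a, 2)
        counts["mean_degree_per_target"] = round(ct_stats.mean_degree_side_b, 2)
        network_analysis.export_network(ct_net, out_dir / "ct_network.graphml", "graphml")
        tp_net = network_analysis.build_tp_network(
            overlap.overlap_genes, retained_pathways, pathway_collection
        )
        counts["tp_targets"] = len(tp_net.side_a)
        counts["tp_pathways"] = len(tp_net.side_b)
        counts["tp_edges"] = tp_net.n_edges
        network_analysis.export_network(tp_net, out_dir / "tp_network.graphml", "graphml")

        # -- integrate ------------------------------------------------------
        stage = "integrate"
        module_config = (
            pathway_integration.ModuleConfig(assignments=config.modules)
            if config.modules
            else pathway_integration.ModuleConfig.default()
        )
        skeleton = pathway_integration.assign_modules(retained_pathways, module_config)
        integrated = pathway_integration.build_integrated_pathway(tp_net, skeleton)
        counts["module_pathways"] = len(integrated.pathways)
        counts["unassigned_pathways"] = len(integrated.unassigned)
        counts["annotated_targets"] = sum(
            1 for labels in integrated.target_labels.values() if labels
        )
        integrated.to_annotation_table().to_csv(
            out_dir / "integrated_targets.tsv", sep="\t", index=False
        )
    except Exception as exc:
        (out_dir / "FAILED").write_text(f"stage={stage}\nerror={exc}\n", encoding="utf-8")
        raise StageError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report = RunReport(
        counts=counts,
        config_hash=config.config_hash,
        seed=config.seed,
        started=started,
        finished=datetime.now(timezone.utc).isoformat(),
    )
    report.to_json(out_dir / "report.json")
    return report
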