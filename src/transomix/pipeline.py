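"""End-to-end pipeline driver: respond -> cluster -> enrich -> assemble -> condense.

Every stage writes its tables under the output directory so each step is
auditable; a machine-readable ``summary.json`` collects the headline counts.
All outputs are deterministically ordered, so identical inputs and seed give
byte-identical artifacts.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import clustering, condense, network, responsiveness
from .config import PipelineConfig
from .datatypes import KnowledgeBase, OmicsTimeCourse
from .io import (
    read_knowledgebase,
    read_timecourse_table,
    write_network_gml,
)

logger = logging.getLogger(__name__)

LAYER_FILES = {"metabolite": "metabolite.tsv", "gene": "gene.tsv", "phospho": "phospho.tsv"}


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write(df: pd.DataFrame, path: Path, **kwargs) -> None:
    df.to_csv(path, sep="\t", **kwargs)


def run_pipeline(
    config: PipelineConfig,
    tcs: dict[str, OmicsTimeCourse],
    kb: KnowledgeBase,
    outdir,
    *,
    tf_gene_edges: set[tuple[str, str]] | None = None,
    until: str = "condense",
) -> dict:
    """Run stages up to ``until`` on in-memory inputs; artifacts land in ``outdir``.

    ``tf_gene_edges`` overrides the inferred TF->gene connections (used by
    recovery tests that supply the planted edges); by default they are
    inferred from gene clustering and motif enrichment.  ``until`` is one of
    respond/cluster/enrich/assemble/condense; earlier stages always run since
    later ones consume their in-memory results.
    """
    stages = ("respond", "cluster", "enrich", "assemble", "condense")
    if until not in stages:
        raise ValueError(f"until must be one of {stages}")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": {"q_threshold": config.q_threshold,
                                "fc_threshold_log2": config.fc_threshold_log2}}

    # ---- stage: respond ----------------------------------------------------
    calls_by_layer: dict[str, pd.DataFrame] = {}
    class_by_layer: dict[str, pd.Series] = {}
    try:
        for layer, tc in tcs.items():
            calls = responsiveness.respond(tc, config)
            calls_by_layer[layer] = calls
            class_by_layer[layer] = responsiveness.response_classes(calls)
            _write(calls.sort_index(), out / f"response_{layer}.tsv")
        class_rows = []
        for layer, classes in class_by_layer.items():
            for mol, cls in classes.sort_index().items():
                class_rows.append({"molecule_id": mol, "layer": layer, "response_class": cls})
        _write(pd.DataFrame(class_rows), out / "response_classes.tsv", index=False)
        summary["responsive_counts"] = {
            layer: {
                cls: int((class_by_layer[layer] == cls).sum())
                for cls in responsiveness.RESPONSE_CLASSES
            }
            for layer in tcs
        }
    except Exception as exc:  # noqa: BLE001 - abort with stage context
        raise PipelineStageError("respond", exc) from exc
    if until == "respond":
        return _finish(summary, out)

    # ---- stage: cluster (metabolites) ---------------------------------------
    try:
        met_calls = calls_by_layer.get("metabolite")
        met_cluster_df = pd.DataFrame(columns=["molecule_id", "cluster"])
        if met_calls is not None:
            responsive_mets = sorted(
                set(met_calls[met_calls["responsive"]].index.get_level_values(0))
            )
            if len(responsive_mets) >= 2:
                norm = clustering.normalize_metabolites(
                    tcs["metabolite"].subset(responsive_mets)
                )
                tree = clustering.ward_tree(norm)
                k = min(config.n_metabolite_clusters, tree.n_leaves)
                clusters = clustering.extract_clusters(tree, k)
                met_cluster_df = pd.DataFrame(
                    [(m, c) for c, ms in sorted(clusters.items()) for m in sorted(ms)],
                    columns=["molecule_id", "cluster"],
                )
        _write(met_cluster_df, out / "metabolite_clusters.tsv", index=False)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("cluster", exc) from exc
    if until == "cluster":
        return _finish(summary, out)

    # ---- stage: enrich (gene clustering + TF inference) ---------------------
    try:
        inferred_edges: set[tuple[str, str]] = set()
        enrichment = pd.DataFrame()
        assignments = pd.DataFrame()
        gene_calls = calls_by_layer.get("gene")
        if gene_calls is not None:
            baseline_q = responsiveness.baseline_difference_qvalues(
                tcs["gene"], method=config.count_test_method
            )
            wt = gene_calls.xs("WT", level="genotype")
            ob = gene_calls.xs("OB", level="genotype")
            selected = clustering.cluster_selection_filter(
                wt, ob, baseline_q, config.q_threshold
            )
            if len(selected) >= max(2, config.min_cluster_size_for_enrichment):
                matrix = clustering.normalize_genes_zscore(tcs["gene"].subset(selected))
                tree = clustering.ward_tree(matrix)
                background = set(matrix.index)
                enrichment = clustering.enrich_tree_nodes(
                    tree, kb.motif_targets, background,
                    min_cluster_size=config.min_cluster_size_for_enrichment,
                    enrichment_q=config.enrichment_q,
                )
                assignments = clustering.assign_tf_clusters(
                    tree, enrichment, comparator=config.enrichment_comparator
                )
                inferred_edges = clustering.infer_tf_gene_edges(assignments, tree)
        _write(enrichment, out / "gene_cluster_enrichment.tsv", index=False)
        _write(assignments, out / "tf_assignments.tsv", index=False)
        _write(
            pd.DataFrame(sorted(inferred_edges), columns=["tf_id", "gene_id"]),
            out / "tf_gene_edges.tsv", index=False,
        )
        summary["n_inferred_tf_gene_edges"] = len(inferred_edges)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("enrich", exc) from exc
    if until == "enrich":
        return _finish(summary, out)

    # ---- stage: assemble -----------------------------------------------------
    try:
        edges_for_assembly = tf_gene_edges if tf_gene_edges is not None else inferred_edges
        net = network.assemble_network(calls_by_layer, class_by_layer, kb, edges_for_assembly)
        _write(net.edge_records(), out / "network_edges.tsv", index=False)
        write_network_gml(net.graph, out / "network.gml")
        reg = network.regulation_summary(
            net, display_min=config.display_min_reactions_top_regulators
        )
        _write(reg["by_source"], out / "reactions_by_source.tsv")
        _write(reg["by_speed"], out / "reactions_by_speed.tsv")
        _write(reg["top_regulators"], out / "top_regulators.tsv", index=False)
        summary["network"] = {
            "n_nodes": net.graph.number_of_nodes(),
            "n_edges": net.graph.number_of_edges(),
            "nodes_per_layer": {
                layer: len(net.nodes_in_layer(layer)) for layer in network.NETWORK_LAYERS
            },
            "reactions_by_source": {
                g: {k: int(v) for k, v in row.items()}
                for g, row in reg["by_source"].iterrows()
            },
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("assemble", exc) from exc
    if until == "assemble":
        return _finish(summary, out)

    # ---- stage: condense ------------------------------------------------------
    try:
        assoc = condense.pathway_association_tests(net, kb, config)
        coverage = condense.pathway_coverage(net, kb)
        selected_pw = condense.select_pathway_nodes(assoc, coverage, config)
        condensed = condense.condense_network(net, kb, assoc, selected_pw, config)
        _write(assoc, out / "pathway_associations.tsv", index=False)
        cov_out = coverage.join(selected_pw, how="left")
        cov_out["selected_by"] = cov_out["selected_by"].fillna("")
        _write(cov_out, out / "pathway_coverage.tsv")
        cond_edges = pd.DataFrame(
            [
                {"regulator": u, "pathway": v, "weight": d["weight"],
                 "genotype_class": d["genotype_class"]}
                for u, v, d in sorted(condensed.edges(data=True))
            ],
            columns=["regulator", "pathway", "weight", "genotype_class"],
        )
        _write(cond_edges, out / "condensed_edges.tsv", index=False)
        write_network_gml(condensed, out / "condensed.gml")
        summary["condensed"] = {
            "n_pathways": len(selected_pw),
            "n_regulators": sum(
                1 for _n, d in condensed.nodes(data=True) if d["layer"] != "Pathway"
            ),
            "n_edges": condensed.number_of_edges(),
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("condense", exc) from exc

    return _finish(summary, out)


def _finish(summary: dict, out: Path) -> dict:
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    logger.info("pipeline complete: %s", out)
    return summary


def run_pipeline_from_paths(config: PipelineConfig, input_dir, outdir, *,
                            until: str = "condense") -> dict:
    """Load TSV inputs from ``input_dir`` (layer tables + ``kb/``) and run."""
    d = Path(input_dir)
    tcs = {}
    for layer, fname in LAYER_FILES.items():
        p = d / fname
        if p.exists():
            tcs[layer] = read_timecourse_table(p, layer)
    if not tcs:
        raise FileNotFoundError(f"no layer tables found under {d}")
    kb = read_knowledgebase(d / "kb")
    return run_pipeline(config, tcs, kb, outdir, until=until)
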