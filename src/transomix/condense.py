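"""Pathway-level condensation of the reaction layer.

Reactions are grouped into pathway nodes (a reaction may belong to several
pathways).  Pathways are kept when significantly associated with at least one
glucose-responsive regulator (one-tailed Fisher over the full reaction
universe, BH q <= 0.01) or when their regulated-reaction coverage is in the
top 10% by either metabolites or enzyme genes.  Metabolite->pathway edges
must cover at least five reactions; TFs must regulate at least five reactions
in total (an "enzymes" basis is available as a documented alternative).
"""

from __future__ import annotations

import logging
import math

import networkx as nx
import pandas as pd

from .config import PipelineConfig
from .datatypes import KnowledgeBase
from .network import TransomicNetwork
from .stats import bh_qvalues, fisher_enrichment

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Regulator -> reaction reach
# ---------------------------------------------------------------------------


def regulator_reactions(net: TransomicNetwork) -> dict[str, set[str]]:
    """Reactions regulated by each Metabolite, Enzyme and TF node.

    Metabolites and enzymes regulate the reactions they have direct edges to;
    a TF regulates the union of reactions of the enzyme genes it targets.
    """
    g = net.graph
    out: dict[str, set[str]] = {}
    for node in g.nodes:
        layer = g.nodes[node]["layer"]
        if layer in ("Metabolite", "Enzyme"):
            rxns = {v for _u, v, _d in g.out_edges(node, data=True)
                    if g.nodes[v]["layer"] == "Reaction"}
            if rxns:
                out[node] = rxns
        elif layer == "TF":
            rxns = set()
            n_enzymes = 0
            for _u, enz, _d in g.out_edges(node, data=True):
                if g.nodes[enz]["layer"] != "Enzyme":
                    continue
                n_enzymes += 1
                rxns |= {v for _e, v, dd in g.out_edges(enz, data=True)
                         if g.nodes[v]["layer"] == "Reaction"}
            if rxns:
                out[node] = rxns
    return out


def tf_enzyme_counts(net: TransomicNetwork) -> dict[str, int]:
    """Number of enzyme genes each TF node regulates (alternative TF basis)."""
    g = net.graph
    out: dict[str, int] = {}
    for tf in net.nodes_in_layer("TF"):
        enzymes = {v for _u, v, _d in g.out_edges(tf, data=True)
                   if g.nodes[v]["layer"] == "Enzyme"}
        if enzymes:
            out[tf] = len(enzymes)
    return out


# ---------------------------------------------------------------------------
# Association tests and pathway selection
# ---------------------------------------------------------------------------


def pathway_association_tests(
    net: TransomicNetwork,
    kb: KnowledgeBase,
    config: PipelineConfig,
) -> pd.DataFrame:
    """One-tailed Fisher association of regulated reactions with pathways.

    For every (regulator, pathway) pair the 2x2 table classifies the universe
    of all knowledge-base reactions by pathway membership and by regulation
    by that molecule; BH q-values run across all tested pairs and pairs with
    q <= ``pathway_assoc_q`` are significant.
    """
    universe = sorted(kb.all_reactions())
    n_universe = len(universe)
    pw_reactions = kb.pathway_reactions()
    reach = regulator_reactions(net)
    rows = []
    for pw, members in sorted(pw_reactions.items()):
        if not members:
            logger.warning("pathway %s has no reactions; skipped", pw)
            continue
        for reg, rxns in sorted(reach.items()):
            layer = net.graph.nodes[reg]["layer"]
            if layer == "Enzyme":
                continue  # pathway association is tested for metabolites and TFs
            k_in = len(rxns & members)
            odds, p = fisher_enrichment(k_in, len(members), len(rxns), n_universe)
            rows.append((reg, layer, pw, k_in, len(members), len(rxns), odds, p))
    out = pd.DataFrame(rows, columns=[
        "regulator", "regulator_layer", "pathway", "k_in", "pathway_size",
        "n_regulated", "odds_ratio", "p",
    ])
    if len(out):
        out["q"] = bh_qvalues(out["p"].to_numpy())
        out["significant"] = out["q"] <= config.pathway_assoc_q
    else:
        out["q"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    logger.info("pathway_association_tests: %d pairs, %d significant",
                len(out), int(out["significant"].sum()))
    return out


def pathway_coverage(net: TransomicNetwork, kb: KnowledgeBase) -> pd.DataFrame:
    """Per-pathway fraction of reactions regulated by metabolites and by genes.

    The gene route counts enzyme genes responsive at the transcript level
    (the condensed enzyme layer excludes phospho-only regulation).
    """
    g = net.graph
    pw_reactions = kb.pathway_reactions()
    met_regulated: set[str] = set()
    gene_regulated: set[str] = set()
    for u, v, d in g.edges(data=True):
        if g.nodes[v]["layer"] != "Reaction":
            continue
        if g.nodes[u]["layer"] == "Metabolite":
            met_regulated.add(v)
        elif g.nodes[u]["layer"] == "Enzyme" and g.nodes[u].get("direction_source") == "gene":
            gene_regulated.add(v)
    rows = []
    for pw, members in sorted(pw_reactions.items()):
        n = len(members)
        n_met = len(members & met_regulated)
        n_gene = len(members & gene_regulated)
        rows.append({
            "pathway": pw,
            "class": kb.pathway_class.get(pw, "other"),
            "n_total": n,
            "n_by_metabolites": n_met,
            "n_by_genes": n_gene,
            "frac_by_metabolites": n_met / n if n else 0.0,
            "frac_by_genes": n_gene / n if n else 0.0,
        })
    return pd.DataFrame(rows).set_index("pathway")


def select_pathway_nodes(
    associations: pd.DataFrame,
    coverage: pd.DataFrame,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Union of significantly associated pathways and top-coverage pathways.

    The top-10% rule ranks pathways with at least one regulated reaction by
    coverage fraction (metabolite and gene rankings separately); the cutoff
    count is ceil(fraction * n_ranked) and ties at the boundary are included.
    """
    sig_pathways = set(associations.loc[associations["significant"], "pathway"])
    selected = {}
    for pw in coverage.index:
        rules = []
        if pw in sig_pathways:
            rules.append("association")
        selected[pw] = rules
    for col, tag in (("frac_by_metabolites", "top_metabolite_coverage"),
                     ("frac_by_genes", "top_gene_coverage")):
        ranked = coverage[coverage[col] > 0][col].sort_values(ascending=False)
        if not len(ranked):
            continue
        n_top = math.ceil(config.top_fraction_pathways * len(ranked))
        cutoff = ranked.iloc[n_top - 1]
        for pw, frac in ranked.items():
            if frac >= cutoff:  # inclusive ties at the boundary
                selected[pw].append(tag)
    rows = [{"pathway": pw, "selected_by": ";".join(rules)}
            for pw, rules in selected.items() if rules]
    out = pd.DataFrame(rows, columns=["pathway", "selected_by"]).set_index("pathway")
    logger.info("select_pathway_nodes: %d of %d pathways selected", len(out), len(coverage))
    return out


# ---------------------------------------------------------------------------
# Condensed network
# ---------------------------------------------------------------------------


def condense_network(
    net: TransomicNetwork,
    kb: KnowledgeBase,
    associations: pd.DataFrame,
    selected_pathways: pd.DataFrame,
    config: PipelineConfig,
) -> nx.DiGraph:
    """Collapse the reaction layer into selected pathway nodes.

    Metabolite regulator nodes are kept when significantly associated with at
    least one selected pathway, and each metabolite->pathway edge must cover
    at least ``min_reactions_per_condensed_edge`` reactions.  TF nodes are
    kept when their total regulated reactions (or regulated enzymes, with
    ``tf_min_basis='enzymes'``) reach ``min_reactions_per_tf_node``; TF edges
    are not subject to the per-edge minimum.
    """
    g = net.graph
    pw_reactions = kb.pathway_reactions()
    reach = regulator_reactions(net)
    out = nx.DiGraph()

    for pw in selected_pathways.index:
        members = pw_reactions.get(pw, set())
        met_reg = {r for r in members
                   if any(g.nodes[u]["layer"] == "Metabolite"
                          for u, _v, _d in g.in_edges(r, data=True)) and r in g.nodes}
        gene_reg = {r for r in members
                    if r in g.nodes and any(
                        g.nodes[u]["layer"] == "Enzyme"
                        and g.nodes[u].get("direction_source") == "gene"
                        for u, _v, _d in g.in_edges(r, data=True))}
        out.add_node(
            pw, layer="Pathway",
            pathway_class=kb.pathway_class.get(pw, "other"),
            n_reactions_total=len(members),
            n_reactions_regulated_by_metabolites=len(met_reg),
            n_reactions_regulated_by_genes=len(gene_reg),
            selected_by=selected_pathways.loc[pw, "selected_by"],
        )

    sig = associations[associations["significant"]]
    selected_set = set(selected_pathways.index)

    # metabolite regulators: significant association with >= 1 selected pathway
    kept_mets = sorted(
        set(sig.loc[(sig["regulator_layer"] == "Metabolite")
                    & sig["pathway"].isin(selected_set), "regulator"])
    )
    # TF regulators: total regulated reactions (or enzymes) >= threshold
    if config.tf_min_basis == "reactions":
        tf_totals = {tf: len(rxns) for tf, rxns in reach.items()
                     if net.graph.nodes[tf]["layer"] == "TF"}
    else:
        tf_totals = tf_enzyme_counts(net)
    kept_tfs = sorted(tf for tf, n in tf_totals.items()
                      if n >= config.min_reactions_per_tf_node)

    for reg in kept_mets + kept_tfs:
        nd = g.nodes[reg]
        out.add_node(reg, layer=nd["layer"], response_class=nd["response_class"],
                     n_reactions_total=len(reach.get(reg, ())))

    for reg in kept_mets:
        for pw in sorted(selected_set):
            weight = len(reach.get(reg, set()) & pw_reactions.get(pw, set()))
            if weight >= config.min_reactions_per_condensed_edge:
                out.add_edge(reg, pw, weight=weight,
                             genotype_class=g.nodes[reg]["response_class"])
    for tf in kept_tfs:
        for pw in sorted(selected_set):
            weight = len(reach.get(tf, set()) & pw_reactions.get(pw, set()))
            if weight > 0:
                out.add_edge(tf, pw, weight=weight,
                             genotype_class=g.nodes[tf]["response_class"])
    logger.info("condense_network: %d pathway nodes, %d regulators, %d edges",
                len(selected_set), len(kept_mets) + len(kept_tfs), out.number_of_edges())
    return out


def pathway_edge_weights(net: TransomicNetwork, kb: KnowledgeBase) -> pd.DataFrame:
    """Unfiltered regulator->pathway weights (grouping-conservation view)."""
    pw_reactions = kb.pathway_reactions()
    reach = regulator_reactions(net)
    rows = []
    for reg, rxns in sorted(reach.items()):
        for pw, members in sorted(pw_reactions.items()):
            w = len(rxns & members)
            if w:
                rows.append({"regulator": reg, "pathway": pw, "weight": w})
    return pd.DataFrame(rows, columns=["regulator", "pathway", "weight"])
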