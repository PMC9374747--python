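"""Five-layer regulatory trans-omic network assembly.

Layers: InsulinSignal -> TF -> Enzyme -> Reaction <- Metabolite.  Nodes are
glucose-responsive molecules (reactions are included only when regulated by a
responsive enzyme or metabolite); edges are interlayer regulatory connections
typed by their database origin and, among the signal/TF/enzyme layers, signed
by direction concordance (same direction -> positive, opposite -> negative).
Every edge carries a genotype class: it exists for a genotype only when both
endpoints respond in that genotype.
"""

from __future__ import annotations

import logging

import networkx as nx
import pandas as pd

from .datatypes import KnowledgeBase

logger = logging.getLogger(__name__)

NETWORK_LAYERS = ("InsulinSignal", "TF", "Enzyme", "Reaction", "Metabolite")

ALLOWED_LAYER_PAIRS = {
    ("InsulinSignal", "TF"): "kinase_to_tf",
    ("InsulinSignal", "Enzyme"): "kinase_to_enzyme",
    ("TF", "Enzyme"): "tf_to_enzyme_gene",
    ("Enzyme", "Reaction"): "enzyme_to_reaction",
    ("Metabolite", "Reaction"): None,  # allosteric_* or substrate_or_product
}

REGULATION_TYPES = (
    "kinase_to_tf",
    "kinase_to_enzyme",
    "tf_to_enzyme_gene",
    "enzyme_to_reaction",
    "allosteric_activator",
    "allosteric_inhibitor",
    "substrate_or_product",
)


class TransomicNetwork:
    """Attributed multigraph over the five layers.

    Thin wrapper around :class:`networkx.MultiDiGraph`; node attributes are
    ``layer``, ``response_class``, ``direction_WT/OB``, ``t_half_WT/OB``,
    ``speed_WT/OB``; edge attributes are ``regulation_type``, ``sign``,
    ``sign_WT/OB`` and ``genotype_class``.
    """

    def __init__(self, graph: nx.MultiDiGraph | None = None):
        self.graph = graph if graph is not None else nx.MultiDiGraph()

    # -- construction -------------------------------------------------------

    def add_molecule_node(self, node_id: str, layer: str, call_info: dict) -> None:
        self.graph.add_node(node_id, layer=layer, **call_info)

    def add_reaction_node(self, reaction_id: str) -> None:
        # reactions carry no direction: reaction activity is not measured
        self.graph.add_node(reaction_id, layer="Reaction", response_class="none")

    # -- views ---------------------------------------------------------------

    def nodes_in_layer(self, layer: str) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["layer"] == layer)

    def edge_records(self) -> pd.DataFrame:
        rows = []
        for u, v, d in self.graph.edges(data=True):
            rows.append({
                "source": u,
                "target": v,
                "source_layer": self.graph.nodes[u]["layer"],
                "target_layer": self.graph.nodes[v]["layer"],
                "regulation_type": d["regulation_type"],
                "sign": d.get("sign", "not_applicable"),
                "genotype_class": d["genotype_class"],
            })
        cols = ["source", "target", "source_layer", "target_layer",
                "regulation_type", "sign", "genotype_class"]
        return pd.DataFrame(rows, columns=cols).sort_values(cols).reset_index(drop=True)

    def edge_set(self) -> set[tuple]:
        """Canonical hashable edge set (for exact recovery comparisons)."""
        return {
            (u, v, d["regulation_type"], d.get("sign", "not_applicable"), d["genotype_class"])
            for u, v, d in self.graph.edges(data=True)
        }

    # -- invariants -----------------------------------------------------------

    def validate(self) -> None:
        for u, v, d in self.graph.edges(data=True):
            lu = self.graph.nodes[u]["layer"]
            lv = self.graph.nodes[v]["layer"]
            if (lu, lv) not in ALLOWED_LAYER_PAIRS:
                raise ValueError(f"edge {u}->{v} connects disallowed layers {lu}->{lv}")
            if d["regulation_type"] not in REGULATION_TYPES:
                raise ValueError(f"unknown regulation_type {d['regulation_type']!r}")
            if lv == "Reaction":
                if d.get("sign", "not_applicable") != "not_applicable":
                    raise ValueError("reaction-target edges carry no sign")
            elif d.get("sign") not in ("positive", "negative"):
                raise ValueError(f"edge {u}->{v} among signed layers lacks a sign")
        for r in self.nodes_in_layer("Reaction"):
            if self.graph.in_degree(r) < 1:
                raise ValueError(f"reaction {r} has no incoming regulation")


# ---------------------------------------------------------------------------
# Direction / genotype helpers
# ---------------------------------------------------------------------------


def edge_sign(regulator_direction: str, target_direction: str) -> str:
    """Concordance sign: same direction -> positive, opposite -> negative."""
    for d in (regulator_direction, target_direction):
        if d not in ("increase", "decrease"):
            raise ValueError(f"direction must be increase/decrease, got {d!r}")
    return "positive" if regulator_direction == target_direction else "negative"


def _node_call_info(molecule: str, calls: pd.DataFrame, class_map: pd.Series) -> dict:
    info: dict = {"response_class": class_map.get(molecule, "none")}
    for g in ("WT", "OB"):
        if (molecule, g) in calls.index:
            row = calls.loc[(molecule, g)]
            info[f"direction_{g}"] = row["direction"]
            th = row.get("t_half")
            if pd.notna(th):
                info[f"t_half_{g}"] = float(th)
                info[f"speed_{g}"] = row.get("speed", "undefined")
        else:
            info[f"direction_{g}"] = "none"
    return info


def _genotype_class_from_signs(sign_wt: str | None, sign_ob: str | None) -> str | None:
    if sign_wt and sign_ob:
        return "common" if sign_wt == sign_ob else "opposite"
    if sign_wt:
        return "WT_specific"
    if sign_ob:
        return "OB_specific"
    return None


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def assign_layer_nodes(
    net: TransomicNetwork,
    calls_by_layer: dict[str, pd.DataFrame],
    class_by_layer: dict[str, pd.Series],
    kb: KnowledgeBase,
) -> None:
    """Place responsive molecules into their layers.

    Metabolite nodes are responsive metabolites.  Enzyme nodes are metabolic
    enzyme genes responsive at the transcript level, or enzymes with
    responsive phosphorylation (direction then comes from the phospho call,
    annotated ``direction_source='phospho'``).  TF nodes are TFs responsive
    at the gene level or with responsive phosphorylation.  InsulinSignal
    nodes are signaling molecules with responsive phosphorylation.
    """
    kb.validate()

    def _responsive_set(layer: str) -> set[str]:
        calls = calls_by_layer.get(layer)
        if calls is None:
            return set()
        resp = calls[calls["responsive"]]
        return set(resp.index.get_level_values(0))

    met_resp = _responsive_set("metabolite")
    gene_resp = _responsive_set("gene")
    phos_resp = _responsive_set("phospho")

    for m in sorted(met_resp):
        net.add_molecule_node(
            m, "Metabolite", _node_call_info(m, calls_by_layer["metabolite"],
                                             class_by_layer["metabolite"]))
    for gid in sorted(gene_resp & kb.enzyme_gene_ids):
        info = _node_call_info(gid, calls_by_layer["gene"], class_by_layer["gene"])
        info["direction_source"] = "gene"
        net.add_molecule_node(gid, "Enzyme", info)
    for gid in sorted(gene_resp & kb.tf_ids):
        info = _node_call_info(gid, calls_by_layer["gene"], class_by_layer["gene"])
        info["direction_source"] = "gene"
        net.add_molecule_node(gid, "TF", info)
    for pid in sorted(phos_resp):
        info = _node_call_info(pid, calls_by_layer["phospho"], class_by_layer["phospho"])
        info["direction_source"] = "phospho"
        if pid in kb.signal_ids:
            net.add_molecule_node(pid, "InsulinSignal", info)
        elif pid in kb.tf_ids and pid not in net.graph.nodes:
            net.add_molecule_node(pid, "TF", info)
        elif pid in kb.enzyme_gene_ids and pid not in net.graph.nodes:
            net.add_molecule_node(pid, "Enzyme", info)
    counts = {layer: len(net.nodes_in_layer(layer)) for layer in NETWORK_LAYERS}
    logger.info("assign_layer_nodes: %s", counts)


def derive_reaction_nodes(net: TransomicNetwork, kb: KnowledgeBase) -> None:
    """Create reaction nodes regulated by responsive enzymes or metabolites.

    A reaction enters the network iff a responsive enzyme catalyses it, a
    responsive metabolite is one of its allosteric effectors, or a responsive
    metabolite is a substrate or product (reversibility is unknown, so both
    substrate and product count as regulators).
    """
    enzymes = set(net.nodes_in_layer("Enzyme"))
    mets = set(net.nodes_in_layer("Metabolite"))
    edges: list[tuple[str, str, str]] = []
    for gid in sorted(enzymes & kb.enzyme_gene_ids):
        for rxn in sorted(kb.enzyme_reactions.get(gid, ())):
            edges.append((gid, rxn, "enzyme_to_reaction"))
    for met, rxn, mode in sorted(kb.allosteric):
        if met in mets:
            edges.append((met, rxn, f"allosteric_{mode}"))
    for rxn in sorted(kb.all_reactions()):
        partners = kb.reaction_substrates.get(rxn, set()) | kb.reaction_products.get(rxn, set())
        for met in sorted(partners & mets):
            edges.append((met, rxn, "substrate_or_product"))
    for src, rxn, rtype in edges:
        if rxn not in net.graph.nodes:
            net.add_reaction_node(rxn)
        net.graph.add_edge(
            src, rxn,
            regulation_type=rtype,
            sign="not_applicable",
            genotype_class=net.graph.nodes[src]["response_class"],
        )
    logger.info("derive_reaction_nodes: %d reactions, %d regulating edges",
                len(net.nodes_in_layer("Reaction")), len(edges))


def build_interlayer_edges(
    net: TransomicNetwork,
    kb: KnowledgeBase,
    tf_gene_edges: set[tuple[str, str]],
) -> None:
    """Signed edges among InsulinSignal, TF and Enzyme layers.

    Kinase->TF and kinase->enzyme edges come from the knowledge base;
    TF->Enzyme edges from inferred TF->gene connections restricted to
    metabolic enzyme genes.  An edge exists for a genotype only when both
    endpoints respond in it; the per-genotype sign is direction concordance,
    and the edge's genotype class summarises in which genotypes it holds.
    TF repressor status is carried as an annotation, never flips the sign.
    """
    nodes = net.graph.nodes
    tfs = set(net.nodes_in_layer("TF"))
    enzymes = set(net.nodes_in_layer("Enzyme"))
    signals = set(net.nodes_in_layer("InsulinSignal"))

    candidates: list[tuple[str, str, str]] = []
    for sig in sorted(signals):
        for target, kind in sorted(kb.kinase_targets.get(sig, ())):
            if kind == "tf" and target in tfs:
                candidates.append((sig, target, "kinase_to_tf"))
            elif kind == "enzyme" and target in enzymes:
                candidates.append((sig, target, "kinase_to_enzyme"))
    for tf, gene in sorted(tf_gene_edges):
        if tf in tfs and gene in enzymes:
            candidates.append((tf, gene, "tf_to_enzyme_gene"))

    n_added = 0
    for src, dst, rtype in candidates:
        signs = {}
        for g in ("WT", "OB"):
            ds = nodes[src].get(f"direction_{g}", "none")
            dt = nodes[dst].get(f"direction_{g}", "none")
            signs[g] = edge_sign(ds, dt) if "none" not in (ds, dt) else None
        gclass = _genotype_class_from_signs(signs["WT"], signs["OB"])
        if gclass is None:
            continue
        attrs = {
            "regulation_type": rtype,
            "sign": signs["WT"] or signs["OB"],
            "genotype_class": gclass,
        }
        for g in ("WT", "OB"):
            if signs[g]:
                attrs[f"sign_{g}"] = signs[g]
        if rtype == "tf_to_enzyme_gene" and src in kb.tf_mode:
            attrs["tf_mode"] = kb.tf_mode[src]
        net.graph.add_edge(src, dst, **attrs)
        n_added += 1
    logger.info("build_interlayer_edges: %d signed edges", n_added)


def assemble_network(
    calls_by_layer: dict[str, pd.DataFrame],
    class_by_layer: dict[str, pd.Series],
    kb: KnowledgeBase,
    tf_gene_edges: set[tuple[str, str]],
) -> TransomicNetwork:
    """End-to-end assembly: nodes, reaction layer, signed interlayer edges."""
    net = TransomicNetwork()
    assign_layer_nodes(net, calls_by_layer, class_by_layer, kb)
    derive_reaction_nodes(net, kb)
    build_interlayer_edges(net, kb, tf_gene_edges)
    net.validate()
    return net


# ---------------------------------------------------------------------------
# Regulation summaries
# ---------------------------------------------------------------------------


def _responsive_in(node_data: dict, genotype: str) -> bool:
    return node_data.get(f"direction_{genotype}", "none") != "none"


def regulation_summary(net: TransomicNetwork, *, display_min: int = 15) -> dict:
    """Counts behind the reaction-regulation summaries.

    Returns a dict with
    ``by_source``: per genotype, reactions regulated by Enzyme only /
    Metabolite only / both;
    ``by_speed``: per genotype, reactions reached by metabolite or enzyme
    regulators in each T1/2 bin;
    ``top_regulators``: regulators (metabolites directly, TFs through their
    enzyme targets) regulating strictly more than ``display_min`` reactions.
    """
    g = net.graph
    reactions = net.nodes_in_layer("Reaction")

    by_source_rows = []
    for geno in ("WT", "OB"):
        counts = {"enzyme_only": 0, "metabolite_only": 0, "both": 0}
        for r in reactions:
            layers = set()
            for u, _v, _d in g.in_edges(r, data=True):
                if _responsive_in(g.nodes[u], geno):
                    layers.add(g.nodes[u]["layer"])
            if layers == {"Enzyme"}:
                counts["enzyme_only"] += 1
            elif layers == {"Metabolite"}:
                counts["metabolite_only"] += 1
            elif layers == {"Enzyme", "Metabolite"}:
                counts["both"] += 1
        counts["total_regulated"] = sum(counts.values())
        by_source_rows.append({"genotype": geno, **counts})
    by_source = pd.DataFrame(by_source_rows).set_index("genotype")

    by_speed_rows = []
    for geno in ("WT", "OB"):
        bins = {"rapid": set(), "intermediate": set(), "slow": set()}
        for r in reactions:
            for u, _v, _d in g.in_edges(r, data=True):
                nd = g.nodes[u]
                if not _responsive_in(nd, geno):
                    continue
                speed = nd.get(f"speed_{geno}")
                if speed in bins:
                    bins[speed].add(r)
        by_speed_rows.append(
            {"genotype": geno, **{s: len(v) for s, v in bins.items()}}
        )
    by_speed = pd.DataFrame(by_speed_rows).set_index("genotype")

    top_rows = []
    for geno in ("WT", "OB"):
        reach: dict[str, set[str]] = {}
        for m in net.nodes_in_layer("Metabolite"):
            if _responsive_in(g.nodes[m], geno):
                hit = {v for _u, v, _d in g.out_edges(m, data=True)
                       if g.nodes[v]["layer"] == "Reaction"}
                if hit:
                    reach[m] = hit
        for tf in net.nodes_in_layer("TF"):
            if not _responsive_in(g.nodes[tf], geno):
                continue
            rxns: set[str] = set()
            for _u, enz, d in g.out_edges(tf, data=True):
                if d.get(f"sign_{geno}") is None:
                    continue
                rxns |= {v for _e, v, dd in g.out_edges(enz, data=True)
                         if g.nodes[v]["layer"] == "Reaction"
                         and _responsive_in(g.nodes[enz], geno)}
            if rxns:
                reach[tf] = rxns
        for reg, rxns in sorted(reach.items()):
            if len(rxns) > display_min:
                top_rows.append({
                    "genotype": geno, "regulator": reg,
                    "layer": g.nodes[reg]["layer"], "n_reactions": len(rxns),
                })
    top = pd.DataFrame(top_rows, columns=["genotype", "regulator", "layer", "n_reactions"])

    return {"by_source": by_source, "by_speed": by_speed, "top_regulators": top}
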