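import itertools

import pandas as pd
import pytest

from transomix.datatypes import KnowledgeBase
from transomix.network import (
    TransomicNetwork,
    assemble_network,
    assign_layer_nodes,
    derive_reaction_nodes,
    edge_sign,
    regulation_summary,
)


def calls_frame(spec: dict[str, dict[str, tuple]]) -> pd.DataFrame:
    """{molecule: {genotype: (responsive, direction, t_half, speed)}} -> call table."""
    rows = []
    for mol, per_g in spec.items():
        for g in ("WT", "OB"):
            responsive, direction, t_half, speed = per_g.get(
                g, (False, "none", float("nan"), "undefined")
            )
            rows.append((mol, g, responsive, direction, t_half, speed))
    df = pd.DataFrame(
        rows, columns=["molecule_id", "genotype", "responsive", "direction",
                       "t_half", "speed"],
    )
    return df.set_index(["molecule_id", "genotype"])


def classes_of(calls: pd.DataFrame) -> pd.Series:
    from transomix.responsiveness import response_classes

    return response_classes(calls)


UP = (True, "increase", 10.0, "rapid")
DOWN = (True, "decrease", 40.0, "intermediate")
FLAT = (False, "none", float("nan"), "undefined")


def small_kb() -> KnowledgeBase:
    kb = KnowledgeBase()
    kb.enzyme_reactions = {"enzA": {"r1", "r2"}, "enzB": {"r3"}, "enzC": {"r4"}}
    kb.reaction_substrates = {"r1": {"metS"}, "r3": {"metX"}}
    kb.reaction_products = {"r2": {"metP"}}
    kb.allosteric = {("metA", "r1", "inhibitor")}
    kb.background_genes = {"enzA", "enzB", "enzC", "tf1", "tf2"}
    kb.tf_genes = {"tf1", "tf2"}
    kb.motif_targets = {"tf1": {"enzA", "enzB"}, "tf2": {"enzC"}}
    kb.kinase_targets = {"sig1": {("tf1", "tf"), ("enzA", "enzyme")}}
    kb.tf_mode = {"tf1": "activator", "tf2": "repressor"}
    kb.reaction_pathways = {r: {"pw1"} for r in ("r1", "r2", "r3", "r4")}
    kb.pathway_class = {"pw1": "carbohydrate"}
    return kb


class TestEdgeSign:
    @pytest.mark.parametrize("a,b,expected", [
        ("increase", "increase", "positive"),
        ("decrease", "decrease", "positive"),
        ("increase", "decrease", "negative"),
        ("decrease", "increase", "negative"),
    ])
    def test_truth_table(self, a, b, expected):
        assert edge_sign(a, b) == expected

    def test_flip_symmetry(self):
        flip = {"increase": "decrease", "decrease": "increase"}
        for a, b in itertools.product(("increase", "decrease"), repeat=2):
            assert edge_sign(a, b) == edge_sign(flip[a], flip[b])

    def test_undefined_direction_rejected(self):
        with pytest.raises(ValueError):
            edge_sign("none", "increase")


class TestLayerAssignment:
    def test_partition_and_phospho_route(self):
        kb = small_kb()
        calls = {
            "metabolite": calls_frame({"metA": {"WT": DOWN}}),
            "gene": calls_frame({"enzA": {"WT": UP}, "tf1": {"WT": UP},
                                 "enzB": {}, "flatgene": {}}),
            "phospho": calls_frame({"enzC": {"OB": UP}, "tf2": {"WT": DOWN},
                                    "sig1": {"WT": UP}}),
        }
        classes = {layer: classes_of(c) for layer, c in calls.items()}
        net = TransomicNetwork()
        assign_layer_nodes(net, calls, classes, kb)
        assert net.nodes_in_layer("Metabolite") == ["metA"]
        assert net.nodes_in_layer("Enzyme") == ["enzA", "enzC"]  # gene + phospho routes
        assert net.nodes_in_layer("TF") == ["tf1", "tf2"]
        assert net.nodes_in_layer("InsulinSignal") == ["sig1"]
        assert net.graph.nodes["enzC"]["direction_source"] == "phospho"
        assert net.graph.nodes["enzA"]["direction_source"] == "gene"
        assert "flatgene" not in net.graph.nodes  # non-responsive: no node


class TestReactionDerivation:
    def build(self, met_spec, gene_spec):
        kb = small_kb()
        calls = {
            "metabolite": calls_frame(met_spec),
            "gene": calls_frame(gene_spec),
            "phospho": calls_frame({}),
        }
        classes = {layer: classes_of(c) for layer, c in calls.items()}
        net = TransomicNetwork()
        assign_layer_nodes(net, calls, classes, kb)
        derive_reaction_nodes(net, kb)
        return net

    def test_enzyme_route_creates_reactions(self):
        net = self.build({}, {"enzA": {"WT": UP}})
        assert net.nodes_in_layer("Reaction") == ["r1", "r2"]
        types = {d["regulation_type"] for _u, _v, d in net.graph.edges(data=True)}
        assert types == {"enzyme_to_reaction"}

    def test_product_metabolite_counts_as_regulator(self):
        net = self.build({"metP": {"WT": UP}}, {})
        assert net.nodes_in_layer("Reaction") == ["r2"]
        (_u, _v, d), = net.graph.edges(data=True)
        assert d["regulation_type"] == "substrate_or_product"
        assert d["genotype_class"] == "WT_specific"

    def test_allosteric_mode_typed(self):
        net = self.build({"metA": {"OB": DOWN}}, {})
        (_u, _v, d), = net.graph.edges(data=True)
        assert d["regulation_type"] == "allosteric_inhibitor"

    def test_unregulated_reactions_absent(self):
        net = self.build({}, {"enzB": {"WT": UP}})
        assert net.nodes_in_layer("Reaction") == ["r3"]  # r1, r2, r4 absent


class TestInterlayerEdges:
    def assemble(self, gene_spec, phospho_spec=None):
        kb = small_kb()
        calls = {
            "metabolite": calls_frame({}),
            "gene": calls_frame(gene_spec),
            "phospho": calls_frame(phospho_spec or {}),
        }
        classes = {layer: classes_of(c) for layer, c in calls.items()}
        return assemble_network(calls, classes, kb, {("tf1", "enzA"), ("tf1", "enzB")})

    def test_wt_specific_positive_edge(self):
        net = self.assemble({"tf1": {"WT": UP}, "enzA": {"WT": UP}})
        edges = [d for u, v, d in net.graph.edges(data=True)
                 if d["regulation_type"] == "tf_to_enzyme_gene"]
        assert len(edges) == 1
        assert edges[0]["sign"] == "positive"
        assert edges[0]["genotype_class"] == "WT_specific"
        assert edges[0]["tf_mode"] == "activator"

    def test_opposite_target_gives_opposite_edge(self):
        net = self.assemble({"tf1": {"WT": UP, "OB": UP},
                             "enzA": {"WT": UP, "OB": DOWN}})
        edges = [d for _u, _v, d in net.graph.edges(data=True)
                 if d["regulation_type"] == "tf_to_enzyme_gene"]
        assert edges[0]["sign_WT"] == "positive"
        assert edges[0]["sign_OB"] == "negative"
        assert edges[0]["genotype_class"] == "opposite"

    def test_nonresponsive_endpoint_blocks_edge(self):
        net = self.assemble({"tf1": {"WT": UP}, "enzA": {}, "enzB": {"OB": UP}})
        # tf1 responds only in WT, enzB only in OB: no genotype has both
        assert not [1 for _u, _v, d in net.graph.edges(data=True)
                    if d["regulation_type"] == "tf_to_enzyme_gene"]

    def test_kinase_edges(self):
        net = self.assemble(
            {"tf1": {"WT": UP}, "enzA": {"WT": DOWN}},
            {"sig1": {"WT": UP}},
        )
        by_type = {}
        for _u, _v, d in net.graph.edges(data=True):
            by_type.setdefault(d["regulation_type"], []).append(d)
        assert by_type["kinase_to_tf"][0]["sign"] == "positive"
        assert by_type["kinase_to_enzyme"][0]["sign"] == "negative"

    def test_assembled_network_validates(self):
        net = self.assemble({"tf1": {"WT": UP}, "enzA": {"WT": UP}})
        net.validate()  # layer pairs, signs, reaction in-degree

    def test_layer_pair_violation_caught(self):
        net = TransomicNetwork()
        net.add_molecule_node("m1", "Metabolite", {"response_class": "common"})
        net.add_molecule_node("tf1", "TF", {"response_class": "common"})
        net.graph.add_edge("m1", "tf1", regulation_type="substrate_or_product",
                           sign="not_applicable", genotype_class="common")
        with pytest.raises(ValueError, match="disallowed layers"):
            net.validate()


class TestRegulationSummary:
    def build_three_reaction_network(self):
        kb = small_kb()
        calls = {
            "metabolite": calls_frame({"metX": {"WT": UP}, "metS": {"WT": DOWN}}),
            "gene": calls_frame({"enzA": {"WT": UP}}),
            "phospho": calls_frame({}),
        }
        classes = {layer: classes_of(c) for layer, c in calls.items()}
        return assemble_network(calls, classes, kb, set())

    def test_source_counts_and_conservation(self):
        net = self.build_three_reaction_network()
        # r2: enzyme only; r3: metabolite only (metX); r1: enzA + metS -> both
        summary = regulation_summary(net)
        wt = summary["by_source"].loc["WT"]
        assert (wt["enzyme_only"], wt["metabolite_only"], wt["both"]) == (1, 1, 1)
        assert wt["total_regulated"] == len(net.nodes_in_layer("Reaction"))
        ob = summary["by_source"].loc["OB"]
        assert ob["total_regulated"] == 0

    def test_speed_bins(self):
        net = self.build_three_reaction_network()
        by_speed = regulation_summary(net)["by_speed"].loc["WT"]
        # rapid regulators: enzA (r1, r2) and metX (r3); intermediate: metS (r1)
        assert by_speed["rapid"] == 3
        assert by_speed["intermediate"] == 1
        assert by_speed["slow"] == 0

    def test_top_regulator_threshold_is_strict(self):
        kb = KnowledgeBase()
        kb.enzyme_reactions = {"enz": {f"r{i}" for i in range(40)}}
        kb.reaction_substrates = {f"r{i}": {"met16"} for i in range(16)}
        kb.reaction_products = {f"r{i}": {"met15"} for i in range(16, 31)}
        kb.background_genes = {"enz"}
        calls = {
            "metabolite": calls_frame({"met16": {"WT": UP}, "met15": {"WT": UP}}),
            "gene": calls_frame({"enz": {"WT": UP}}),
            "phospho": calls_frame({}),
        }
        classes = {layer: classes_of(c) for layer, c in calls.items()}
        net = assemble_network(calls, classes, kb, set())
        top = regulation_summary(net, display_min=15)["top_regulators"]
        by_geno = top[top["genotype"] == "WT"]
        assert set(by_geno["regulator"]) == {"met16"}  # 16 > 15 in, 15 out
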