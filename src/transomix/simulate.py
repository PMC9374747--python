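"""Synthetic multi-omic study generator with planted ground truth.

Emulates the statistical shape of a two-genotype oral-glucose time course:
5 time points (0/20/60/120/240 min), 5 replicates per genotype and time,
~100 metabolites, a configurable gene panel, and a small phosphoprotein
panel.  Planted responders follow a saturating-exponential deviation on the
log2 scale, d(t) = A * (1 - 2**(-t / t_half)), so the half-amplitude time of
the log2 trace equals ``t_half`` exactly by construction.  Replicate noise is
lognormal (metabolites, phospho) or negative-binomial (gene counts).  The
generator also wires a knowledge base around the planted responders and
derives the exact network an assembler must produce under perfect calls.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import KnowledgeBase, OmicsTimeCourse

TIME_POINTS = (0, 20, 60, 120, 240)
N_REPLICATES = 5
#: planted T1/2 ranges per speed class (minutes)
SPEED_RANGES = {"rapid": (5.0, 15.0), "intermediate": (30.0, 50.0), "slow": (90.0, 200.0)}
PATTERNS = ("WT_specific", "OB_specific", "common", "opposite")

#: ketone-body-like planted decrease: with t_half = 6 min the expected
#: 20-min fold change is 2**(A * (1 - 2**(-20/6))) = 0.13
KETONE_T_HALF = 6.0
KETONE_AMPLITUDE = np.log2(0.13) / (1.0 - 2.0 ** (-20.0 / KETONE_T_HALF))


def _directions(pattern: str, direction: str) -> tuple[str, str]:
    """Per-genotype directions implied by a cross-genotype pattern."""
    other = "decrease" if direction == "increase" else "increase"
    return {
        "WT_specific": (direction, "none"),
        "OB_specific": ("none", direction),
        "common": (direction, direction),
        "opposite": (direction, other),
    }[pattern]


@dataclass
class SyntheticTruth:
    """Planted responders, TF structure and the expected network."""

    #: molecule_id, layer, pattern, direction_WT/OB, amplitude_log2,
    #: t_half_true, speed_true
    responders: pd.DataFrame
    #: layer -> all molecule ids in that layer
    layer_molecules: dict[str, list[str]]
    #: tf_id -> planted cluster gene set
    tf_clusters: dict[str, set[str]] = field(default_factory=dict)
    in_cluster_motif_rate: float = 0.4
    background_motif_rate: float = 0.05
    #: the TF->gene edges inference should recover
    tf_gene_edges: set[tuple[str, str]] = field(default_factory=set)
    #: exact edge set the assembler must output under perfect calls
    planted_network: pd.DataFrame | None = None

    def responder_ids(self, layer: str | None = None) -> set[str]:
        df = self.responders
        if layer is not None:
            df = df[df["layer"] == layer]
        return set(df["molecule_id"])

    def perfect_calls(self, layer: str) -> pd.DataFrame:
        """Noise-free call table for one layer, derived from the truth."""
        rows = []
        resp = self.responders[self.responders["layer"] == layer].set_index("molecule_id")
        for mol in self.layer_molecules[layer]:
            for g in ("WT", "OB"):
                if mol in resp.index:
                    r = resp.loc[mol]
                    d = r[f"direction_{g}"]
                    responsive = d != "none"
                    rows.append((mol, g, responsive, d,
                                 r["t_half_true"] if responsive else np.nan,
                                 r["speed_true"] if responsive else "undefined"))
                else:
                    rows.append((mol, g, False, "none", np.nan, "undefined"))
        out = pd.DataFrame(
            rows,
            columns=["molecule_id", "genotype", "responsive", "direction", "t_half", "speed"],
        )
        return out.set_index(["molecule_id", "genotype"])

    def perfect_classes(self, layer: str) -> pd.Series:
        resp = self.responders[self.responders["layer"] == layer].set_index("molecule_id")
        out = {}
        for mol in self.layer_molecules[layer]:
            out[mol] = resp.loc[mol, "pattern"] if mol in resp.index else "none"
        return pd.Series(out, name="response_class")

    def planted_edge_set(self) -> set[tuple]:
        df = self.planted_network
        return {
            (r.source, r.target, r.regulation_type, r.sign, r.genotype_class)
            for r in df.itertuples()
        }

    def to_json(self, path) -> None:
        payload = {
            "responders": self.responders.to_dict(orient="records"),
            "layer_molecules": self.layer_molecules,
            "tf_clusters": {tf: sorted(gs) for tf, gs in self.tf_clusters.items()},
            "in_cluster_motif_rate": self.in_cluster_motif_rate,
            "background_motif_rate": self.background_motif_rate,
            "tf_gene_edges": sorted(map(list, self.tf_gene_edges)),
            "planted_network": (
                self.planted_network.to_dict(orient="records")
                if self.planted_network is not None else None
            ),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Layer synthesis
# ---------------------------------------------------------------------------


def _log2_deviation(amplitude: float, t_half: float, times: np.ndarray) -> np.ndarray:
    return amplitude * (1.0 - 2.0 ** (-times / t_half))


def synthesize_layer(
    layer: str,
    molecule_ids: list[str],
    responders: pd.DataFrame,
    rng: np.random.Generator,
    *,
    cv: float = 0.2,
    nb_dispersion: float = 0.05,
    missing_rate: float = 0.0,
    baseline_log_mean: float = np.log(200.0),
    baseline_log_sd: float = 1.0,
    time_points=TIME_POINTS,
    n_replicates: int = N_REPLICATES,
) -> OmicsTimeCourse:
    """Draw replicate-level abundances for one layer.

    Non-responders are flat around a lognormal baseline; responders deviate
    on the log2 scale by A * (1 - 2**(-t/t_half)) in each genotype where they
    respond.  Gene counts use a negative binomial with the given dispersion;
    other layers use lognormal noise with the given coefficient of variation.
    """
    times = np.asarray(time_points, dtype=float)
    resp = responders.set_index("molecule_id") if len(responders) else pd.DataFrame()
    baselines = np.exp(rng.normal(baseline_log_mean, baseline_log_sd, len(molecule_ids)))
    sigma = np.sqrt(np.log1p(cv**2))
    columns = pd.MultiIndex.from_tuples(
        [(g, int(t), r + 1) for g in ("WT", "OB") for t in time_points
         for r in range(n_replicates)],
        names=["genotype", "time", "replicate"],
    )
    values = np.empty((len(molecule_ids), len(columns)))
    for i, mol in enumerate(molecule_ids):
        means = {}
        for g in ("WT", "OB"):
            dev = np.zeros_like(times)
            if len(resp) and mol in resp.index:
                r = resp.loc[mol]
                d = r[f"direction_{g}"]
                if d != "none":
                    amp = abs(r["amplitude_log2"]) * (1.0 if d == "increase" else -1.0)
                    dev = _log2_deviation(amp, float(r["t_half_true"]), times)
            means[g] = baselines[i] * 2.0**dev
        row = []
        for g in ("WT", "OB"):
            for j in range(len(time_points)):
                mu = means[g][j]
                if layer == "gene":
                    n_param = 1.0 / nb_dispersion
                    draw = rng.negative_binomial(
                        n_param, n_param / (n_param + mu), n_replicates
                    ).astype(float)
                else:
                    draw = mu * np.exp(rng.normal(0.0, sigma, n_replicates))
                row.append(draw)
        values[i] = np.concatenate(row)
    if missing_rate > 0:
        mask = rng.random(values.shape) < missing_rate
        values = np.where(mask, np.nan, values)
    data = pd.DataFrame(values, index=pd.Index(molecule_ids, name="molecule_id"),
                        columns=columns)
    return OmicsTimeCourse(layer, data)


def draw_responders(
    molecule_ids: list[str],
    layer: str,
    n_responsive: int,
    rng: np.random.Generator,
    *,
    amplitude_log2: float = 1.5,
    patterns=PATTERNS,
    speed_classes=("rapid", "intermediate", "slow"),
) -> pd.DataFrame:
    """Randomly pick responders with patterns, directions and T1/2 classes."""
    chosen = list(rng.choice(molecule_ids, size=n_responsive, replace=False))
    rows = []
    for i, mol in enumerate(chosen):
        pattern = patterns[i % len(patterns)]
        direction = "increase" if rng.random() < 0.5 else "decrease"
        speed = speed_classes[i % len(speed_classes)]
        lo, hi = SPEED_RANGES[speed]
        t_half = float(rng.uniform(lo, hi))
        dw, do = _directions(pattern, direction)
        rows.append((mol, layer, pattern, dw, do, amplitude_log2, t_half, speed))
    return pd.DataFrame(rows, columns=[
        "molecule_id", "layer", "pattern", "direction_WT", "direction_OB",
        "amplitude_log2", "t_half_true", "speed_true",
    ])


def generate_timecourses(
    n_metabolites: int = 104,
    n_genes: int = 840,
    n_phospho: int = 10,
    frac_responsive: float = 0.25,
    *,
    cv: float = 0.2,
    nb_dispersion: float = 0.05,
    missing_rate: float = 0.02,
    seed: int = 0,
) -> tuple[dict[str, OmicsTimeCourse], SyntheticTruth]:
    """Independent random responders per layer (no TF/network wiring).

    Suited to calibration and recovery tests of the responsiveness module;
    :func:`generate_study_bundle` builds the fully wired study instead.
    """
    layers = {
        "metabolite": [f"met{i:03d}" for i in range(1, n_metabolites + 1)],
        "gene": [f"g{i:04d}" for i in range(1, n_genes + 1)],
        "phospho": [f"prot{i:02d}" for i in range(1, n_phospho + 1)],
    }
    tcs = {}
    truth_parts = []
    for k, (layer, ids) in enumerate(layers.items()):
        rng = np.random.default_rng([seed, k])
        n_resp = int(round(frac_responsive * len(ids)))
        responders = draw_responders(ids, layer, n_resp, rng)
        truth_parts.append(responders)
        tcs[layer] = synthesize_layer(
            layer, ids, responders, rng, cv=cv, nb_dispersion=nb_dispersion,
            missing_rate=missing_rate if layer == "metabolite" else 0.0,
        )
    truth = SyntheticTruth(
        responders=pd.concat(truth_parts, ignore_index=True),
        layer_molecules=layers,
    )
    return tcs, truth


# ---------------------------------------------------------------------------
# Knowledge base generation
# ---------------------------------------------------------------------------


def generate_knowledgebase(
    metabolite_ids: list[str],
    enzyme_gene_ids: list[str],
    tf_gene_ids: list[str],
    signal_ids: list[str],
    background_genes: set[str],
    rng: np.random.Generator,
    *,
    n_reactions: int = 200,
    n_pathways: int = 12,
    allosteric_density: float = 0.004,
    tf_clusters: dict[str, set[str]] | None = None,
    in_cluster_motif_rate: float = 0.4,
    background_motif_rate: float = 0.05,
    kinase_wiring: dict[str, set[tuple[str, str]]] | None = None,
    hub_metabolite_ids: list[str] | None = None,
    hub_pathway_coverage: float = 0.7,
) -> KnowledgeBase:
    """Random knowledge tables with planted motif-enriched clusters.

    Every reaction gets at least one enzyme gene (referential integrity by
    construction); planted TFs carry their motif in ``in_cluster_motif_rate``
    of their cluster genes versus ``background_motif_rate`` elsewhere.
    ``hub_metabolite_ids`` become currency-like regulators: each is wired as
    a substrate into ``hub_pathway_coverage`` of one pathway's reactions
    (plus a few scattered ones), giving the pathway-association stage the
    concentrated regulation real metabolic maps show for metabolites like
    ATP or citrate.
    """
    kb = KnowledgeBase()
    reactions = [f"rxn{i:03d}" for i in range(1, n_reactions + 1)]
    # each enzyme gene catalyses 1-3 reactions; then guarantee coverage
    for gid in enzyme_gene_ids:
        k = int(rng.integers(1, 4))
        for rxn in rng.choice(reactions, size=k, replace=False):
            kb.enzyme_reactions.setdefault(gid, set()).add(str(rxn))
    covered = kb.all_reactions()
    orphan = [r for r in reactions if r not in covered]
    for i, rxn in enumerate(orphan):
        gid = enzyme_gene_ids[i % len(enzyme_gene_ids)]
        kb.enzyme_reactions.setdefault(gid, set()).add(rxn)
    # substrates/products
    for rxn in reactions:
        n_sub = int(rng.integers(1, 3))
        n_pro = int(rng.integers(1, 3))
        mets = rng.choice(metabolite_ids, size=n_sub + n_pro, replace=False)
        kb.reaction_substrates[rxn] = {str(m) for m in mets[:n_sub]}
        kb.reaction_products[rxn] = {str(m) for m in mets[n_sub:]}
    # allosteric regulation
    n_allo = int(round(allosteric_density * len(metabolite_ids) * n_reactions))
    for _ in range(n_allo):
        met = str(rng.choice(metabolite_ids))
        rxn = str(rng.choice(reactions))
        mode = "activator" if rng.random() < 0.5 else "inhibitor"
        kb.allosteric.add((met, rxn, mode))
    # pathways with overlap
    pathways = [f"pw{i:02d}" for i in range(1, n_pathways + 1)]
    classes = ("carbohydrate", "lipid", "amino_acid", "other")
    kb.pathway_class = {pw: classes[i % 4] for i, pw in enumerate(pathways)}
    for rxn in reactions:
        k = 2 if rng.random() < 0.25 else 1
        for pw in rng.choice(pathways, size=k, replace=False):
            kb.reaction_pathways.setdefault(rxn, set()).add(str(pw))
    # currency-like hub metabolites concentrated in one pathway each
    pw_members: dict[str, list[str]] = {pw: [] for pw in pathways}
    for rxn, pws in kb.reaction_pathways.items():
        for pw in pws:
            pw_members[pw].append(rxn)
    for i, met in enumerate(hub_metabolite_ids or []):
        pw = pathways[i % len(pathways)]
        members = sorted(pw_members[pw])
        n_in = max(1, int(round(hub_pathway_coverage * len(members))))
        for rxn in rng.choice(members, size=n_in, replace=False):
            kb.reaction_substrates[str(rxn)].add(met)
        for rxn in rng.choice(reactions, size=3, replace=False):
            kb.reaction_products[str(rxn)].add(met)
    # motif targets
    kb.background_genes = set(background_genes)
    kb.tf_genes = set(tf_gene_ids)
    tf_clusters = tf_clusters or {}
    bg_list = sorted(background_genes)
    for tf in tf_gene_ids:
        cluster = tf_clusters.get(tf, set())
        targets = set()
        for g in bg_list:
            rate = in_cluster_motif_rate if g in cluster else background_motif_rate
            if rng.random() < rate:
                targets.add(g)
        kb.motif_targets[tf] = targets
    # kinase wiring
    kb.kinase_targets = {s: set() for s in signal_ids}
    if kinase_wiring:
        for s, targets in kinase_wiring.items():
            kb.kinase_targets.setdefault(s, set()).update(targets)
    for s in signal_ids:
        if not kb.kinase_targets[s]:
            tf = str(rng.choice(tf_gene_ids))
            kb.kinase_targets[s].add((tf, "tf"))
    modes = ("activator", "repressor", "unknown")
    kb.tf_mode = {tf: modes[i % 3] for i, tf in enumerate(tf_gene_ids)}
    kb.validate()
    return kb


# ---------------------------------------------------------------------------
# Fully wired study bundle
# ---------------------------------------------------------------------------


def _planted_network(
    truth_resp: pd.DataFrame,
    kb: KnowledgeBase,
    tf_gene_edges: set[tuple[str, str]],
) -> pd.DataFrame:
    """Directly derive the edge set an assembler must produce.

    Written with plain set comprehensions over the truth labels (independent
    of the assembly module) so exact-recovery tests compare two code paths.
    A molecule responsive in both the gene and phospho layers is governed by
    its gene-layer record (transcript abundance outranks phosphorylation for
    node direction, mirroring the assembly precedence).
    """
    by_layer = {
        layer: truth_resp[truth_resp["layer"] == layer].set_index("molecule_id")
        for layer in ("metabolite", "gene", "phospho")
    }
    met_nodes = set(by_layer["metabolite"].index)
    gene_resp = set(by_layer["gene"].index)
    phos_resp = set(by_layer["phospho"].index)

    def _record(mol):
        if mol in met_nodes:
            return by_layer["metabolite"].loc[mol]
        if mol in gene_resp:
            return by_layer["gene"].loc[mol]
        if mol in phos_resp:
            return by_layer["phospho"].loc[mol]
        return None

    def dir_of(mol, g):
        r = _record(mol)
        return r[f"direction_{g}"] if r is not None else "none"

    def klass(mol):
        r = _record(mol)
        return r["pattern"] if r is not None else "none"
    enzyme_nodes = (gene_resp & kb.enzyme_gene_ids) | (phos_resp & kb.enzyme_gene_ids)
    tf_nodes = (gene_resp & kb.tf_ids) | (phos_resp & kb.tf_ids)
    signal_nodes = phos_resp & kb.signal_ids

    rows = []
    for gid in sorted(enzyme_nodes):
        for rxn in sorted(kb.enzyme_reactions.get(gid, ())):
            rows.append((gid, rxn, "enzyme_to_reaction", "not_applicable", klass(gid)))
    for met, rxn, mode in sorted(kb.allosteric):
        if met in met_nodes:
            rows.append((met, rxn, f"allosteric_{mode}", "not_applicable", klass(met)))
    for rxn in sorted(kb.all_reactions()):
        partners = kb.reaction_substrates.get(rxn, set()) | kb.reaction_products.get(rxn, set())
        for met in sorted(partners & met_nodes):
            rows.append((met, rxn, "substrate_or_product", "not_applicable", klass(met)))

    def signed(src, dst, rtype):
        signs = {}
        for g in ("WT", "OB"):
            ds, dt = dir_of(src, g), dir_of(dst, g)
            if "none" in (ds, dt):
                signs[g] = None
            else:
                signs[g] = "positive" if ds == dt else "negative"
        if signs["WT"] and signs["OB"]:
            gc = "common" if signs["WT"] == signs["OB"] else "opposite"
        elif signs["WT"]:
            gc = "WT_specific"
        elif signs["OB"]:
            gc = "OB_specific"
        else:
            return None
        return (src, dst, rtype, signs["WT"] or signs["OB"], gc)

    for sig in sorted(signal_nodes):
        for target, kind in sorted(kb.kinase_targets.get(sig, ())):
            if kind == "tf" and target in tf_nodes:
                e = signed(sig, target, "kinase_to_tf")
            elif kind == "enzyme" and target in enzyme_nodes:
                e = signed(sig, target, "kinase_to_enzyme")
            else:
                e = None
            if e:
                rows.append(e)
    for tf, gene in sorted(tf_gene_edges):
        if tf in tf_nodes and gene in enzyme_nodes:
            e = signed(tf, gene, "tf_to_enzyme_gene")
            if e:
                rows.append(e)
    return pd.DataFrame(
        rows, columns=["source", "target", "regulation_type", "sign", "genotype_class"]
    )


def generate_study_bundle(
    seed: int = 0,
    *,
    n_metabolites: int = 104,
    cluster_size: int = 120,
    n_background_genes: int = 480,
    n_enzyme_genes: int = 120,
    n_tfs: int = 12,
    n_background_responsive_genes: int = 60,
    amplitude_log2: float = 1.5,
    cv: float = 0.2,
    nb_dispersion: float = 0.05,
    missing_rate: float = 0.02,
    n_reactions: int = 200,
    n_pathways: int = 12,
) -> tuple[dict[str, OmicsTimeCourse], KnowledgeBase, SyntheticTruth]:
    """One coherent study: omics tables + knowledge base + planted truth.

    Default composition mirrors the emulated study: 104 metabolites with 29
    planted responders (21 WT-specific decreases including one strong
    ketone-body-like drop, 4 OB-specific increases, 4 OB-specific decreases),
    10 phosphoproteins spanning common/specific/opposite patterns, and a gene
    panel containing three motif-marked clusters of ``cluster_size`` genes
    driven by three planted transcription factors.
    """
    rng = np.random.default_rng([seed, 100])

    # ---- identifiers -----------------------------------------------------
    met_ids = [f"met{i:03d}" for i in range(1, n_metabolites + 1)]
    tf_ids = [f"tf{i:02d}" for i in range(1, n_tfs + 1)]
    planted_tfs = tf_ids[:3]
    cluster_genes = {
        tf: [f"g{tf[-2:]}_{j:03d}" for j in range(1, cluster_size + 1)]
        for tf in planted_tfs
    }
    bg_genes = [f"gbg_{j:04d}" for j in range(1, n_background_genes + 1)]
    all_genes = [g for tf in planted_tfs for g in cluster_genes[tf]] + bg_genes + tf_ids
    # enzyme genes: spread across the three clusters and the background
    per_cluster = n_enzyme_genes // 6  # one sixth from each cluster
    enzyme_genes: list[str] = []
    for tf in planted_tfs:
        enzyme_genes += cluster_genes[tf][:per_cluster]
    enzyme_genes += bg_genes[: n_enzyme_genes - len(enzyme_genes)]
    signal_ids = [f"sig{i:02d}" for i in range(1, 7)]
    phospho_enzymes = enzyme_genes[-2:]  # phospho-only regulated enzymes
    phospho_ids = signal_ids + tf_ids[:2] + phospho_enzymes

    # ---- planted responders ---------------------------------------------
    rows = []

    def add(mol, layer, pattern, direction, speed, amplitude=amplitude_log2, t_half=None):
        if t_half is None:
            lo, hi = SPEED_RANGES[speed]
            t_half = float(rng.uniform(lo, hi))
        dw, do = _directions(pattern, direction)
        rows.append((mol, layer, pattern, dw, do, amplitude, t_half, speed))

    # metabolites: 21 WT-specific decreased, 4 OB-specific increased,
    # 4 OB-specific decreased; met001 is the strong rapid ketone-like drop
    add("met001", "metabolite", "WT_specific", "decrease", "rapid",
        amplitude=abs(KETONE_AMPLITUDE), t_half=KETONE_T_HALF)
    speed_cycle = ("rapid", "intermediate", "slow")
    for i in range(2, 22):
        add(f"met{i:03d}", "metabolite", "WT_specific", "decrease", speed_cycle[i % 3])
    for i in range(22, 26):
        add(f"met{i:03d}", "metabolite", "OB_specific", "increase", speed_cycle[i % 3])
    for i in range(26, 30):
        add(f"met{i:03d}", "metabolite", "OB_specific", "decrease", speed_cycle[i % 3])

    # gene clusters: co-regulated genes share one transcriptional wave (one
    # pattern and one representative T1/2 per cluster) so each planted
    # cluster is a coherent dendrogram node
    cluster_patterns = [("common", "increase", "rapid", 10.0),
                        ("WT_specific", "decrease", "intermediate", 40.0),
                        ("OB_specific", "increase", "slow", 140.0)]
    for tf, (pattern, direction, speed, t_half) in zip(planted_tfs, cluster_patterns):
        for g in cluster_genes[tf]:
            add(g, "gene", pattern, direction, speed, t_half=t_half)
        add(tf, "gene", pattern, direction, speed, t_half=t_half)  # the TF's own transcript
    # scattered background responders (outside the enzyme panel, so the
    # phospho-only regulated enzymes keep flat transcripts)
    eligible = [g for g in bg_genes if g not in set(enzyme_genes)]
    chosen = rng.choice(eligible, size=n_background_responsive_genes, replace=False)
    for i, g in enumerate(sorted(map(str, chosen))):
        pattern = PATTERNS[i % 4]
        direction = "increase" if rng.random() < 0.5 else "decrease"
        add(g, "gene", pattern, direction, speed_cycle[i % 3])

    # phosphoproteins: fixed panel spanning the response classes
    add("sig01", "phospho", "common", "increase", "rapid")
    add("sig02", "phospho", "WT_specific", "increase", "rapid")
    add("sig03", "phospho", "OB_specific", "increase", "intermediate")
    add("sig04", "phospho", "opposite", "increase", "rapid")
    add(tf_ids[0], "phospho", "WT_specific", "increase", "rapid")
    add(tf_ids[1], "phospho", "OB_specific", "increase", "intermediate")
    add(phospho_enzymes[0], "phospho", "WT_specific", "decrease", "rapid")
    add(phospho_enzymes[1], "phospho", "opposite", "decrease", "intermediate")
    # sig05 and sig06 stay flat

    responders = pd.DataFrame(rows, columns=[
        "molecule_id", "layer", "pattern", "direction_WT", "direction_OB",
        "amplitude_log2", "t_half_true", "speed_true",
    ])

    # ---- knowledge base ---------------------------------------------------
    kinase_wiring = {
        "sig01": {(tf_ids[0], "tf"), (planted_tfs[0], "tf")},
        "sig02": {(phospho_enzymes[0], "enzyme"), (enzyme_genes[0], "enzyme")},
        "sig03": {(tf_ids[1], "tf")},
        "sig04": {(phospho_enzymes[1], "enzyme")},
        "sig05": {(tf_ids[2], "tf")},
        "sig06": {(enzyme_genes[1], "enzyme")},
    }
    tf_only_genes = [t for t in tf_ids]  # TF gene ids are their own gene rows
    kb = generate_knowledgebase(
        met_ids,
        [g for g in enzyme_genes],
        tf_only_genes,
        signal_ids,
        background_genes=set(all_genes),
        rng=rng,
        n_reactions=n_reactions,
        n_pathways=n_pathways,
        tf_clusters={tf: set(gs) for tf, gs in cluster_genes.items()},
        kinase_wiring=kinase_wiring,
        # responsive currency-like metabolites: six WT-specific decreases and
        # three OB-specific responders act as pathway-concentrated regulators
        hub_metabolite_ids=["met002", "met003", "met004", "met005", "met006",
                            "met007", "met022", "met023", "met026"],
    )

    # ---- time courses ------------------------------------------------------
    tcs = {}
    layer_specs = {
        "metabolite": (met_ids, missing_rate),
        "gene": (all_genes, 0.0),
        "phospho": (phospho_ids, 0.0),
    }
    for k, (layer, (ids, miss)) in enumerate(layer_specs.items()):
        layer_rng = np.random.default_rng([seed, 200 + k])
        sub = responders[responders["layer"] == layer]
        tcs[layer] = synthesize_layer(
            layer, ids, sub, layer_rng, cv=cv, nb_dispersion=nb_dispersion,
            missing_rate=miss,
        )

    # ---- truth -------------------------------------------------------------
    tf_gene_edges = {
        (tf, g) for tf, genes in cluster_genes.items() for g in genes
    }
    truth = SyntheticTruth(
        responders=responders,
        layer_molecules={layer: spec[0] for layer, spec in layer_specs.items()},
        tf_clusters={tf: set(gs) for tf, gs in cluster_genes.items()},
        tf_gene_edges=tf_gene_edges,
    )
    truth.planted_network = _planted_network(responders, kb, tf_gene_edges)
    return tcs, kb, truth
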