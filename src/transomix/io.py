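"""Readers and writers for omics tables, knowledge tables and GML networks.

Tabular dialect: tab-separated, UTF-8, "." decimal, empty cell = missing.
Time-course columns are named ``<genotype>_<time>_<replicate>`` (e.g.
``WT_20_3``); one molecule per row, first column ``molecule_id``.
"""

from __future__ import annotations

import math
import re
from pathlib import Path

import networkx as nx
import pandas as pd

from .datatypes import (
    FormatError,
    KnowledgeBase,
    OmicsTimeCourse,
    ValidationError,
)

_COLUMN_RE = re.compile(r"^(WT|OB)_(\d+)_(\d+)$")

KB_FILES = {
    "enzyme_reactions": ("enzyme_reactions.tsv", ["gene_id", "reaction_id"]),
    "reaction_metabolites": ("reaction_metabolites.tsv", ["reaction_id", "metabolite_id", "role"]),
    "allosteric": ("allosteric.tsv", ["metabolite_id", "reaction_id", "mode"]),
    "motif_targets": ("motif_targets.tsv", ["tf_id", "gene_id"]),
    "background_genes": ("background_genes.txt", None),
    "kinase_targets": ("kinase_targets.tsv", ["signal_id", "target_id", "target_kind"]),
    "tf_mode": ("tf_mode.tsv", ["tf_id", "mode"]),
    "reaction_pathways": ("reaction_pathways.tsv", ["reaction_id", "pathway_id"]),
    "pathway_class": ("pathway_class.tsv", ["pathway_id", "class"]),
    "tf_genes": ("tf_genes.txt", None),
}


# ---------------------------------------------------------------------------
# Time-course tables
# ---------------------------------------------------------------------------


def read_timecourse_table(path, layer: str) -> OmicsTimeCourse:
    """Read a replicate-level time-course TSV into a validated container.

    Missing cells stay missing (NaN), never zero.  Malformed headers raise
    :class:`FormatError` naming the offending column; negative abundances and
    a missing 0-min baseline raise :class:`ValidationError`.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "molecule_id":
        raise FormatError(f"first column must be 'molecule_id', got {df.columns[0]!r}")
    tuples = []
    for col in df.columns[1:]:
        m = _COLUMN_RE.match(col)
        if not m:
            raise FormatError(
                f"column {col!r} does not match '<genotype>_<time>_<replicate>'"
            )
        tuples.append((m.group(1), int(m.group(2)), int(m.group(3))))
    data = df.set_index("molecule_id")
    data.columns = pd.MultiIndex.from_tuples(tuples, names=["genotype", "time", "replicate"])
    data = data.astype(float)
    neg = data.lt(0).any(axis=1)
    if neg.any():
        raise ValidationError(f"negative abundance in row {data.index[neg][0]!r}")
    return OmicsTimeCourse(layer, data)


def write_timecourse_table(tc: OmicsTimeCourse, path) -> None:
    out = tc.data.copy()
    out.columns = [f"{g}_{t}_{r}" for g, t, r in tc.data.columns]
    out.index.name = "molecule_id"
    out.to_csv(path, sep="\t", na_rep="")


# ---------------------------------------------------------------------------
# Knowledge tables
# ---------------------------------------------------------------------------


def _read_tsv(path: Path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing columns {missing}")
    return df.drop_duplicates()


def read_knowledgebase(directory) -> KnowledgeBase:
    """Load the knowledge tables from a directory of TSVs.

    Absent optional tables load as empty; duplicate rows are deduplicated and
    referential integrity is checked on the assembled object.
    """
    d = Path(directory)
    kb = KnowledgeBase()

    def maybe(name):
        fname, cols = KB_FILES[name]
        p = d / fname
        if not p.exists():
            return None
        if cols is None:
            return {line.strip() for line in p.read_text().splitlines() if line.strip()}
        return _read_tsv(p, cols)

    er = maybe("enzyme_reactions")
    if er is not None:
        for r in er.itertuples():
            kb.enzyme_reactions.setdefault(r.gene_id, set()).add(r.reaction_id)
    rm = maybe("reaction_metabolites")
    if rm is not None:
        for r in rm.itertuples():
            if r.role == "substrate":
                kb.reaction_substrates.setdefault(r.reaction_id, set()).add(r.metabolite_id)
            elif r.role == "product":
                kb.reaction_products.setdefault(r.reaction_id, set()).add(r.metabolite_id)
            else:
                raise FormatError(f"reaction_metabolites: unknown role {r.role!r}")
    al = maybe("allosteric")
    if al is not None:
        kb.allosteric = {(r.metabolite_id, r.reaction_id, r.mode) for r in al.itertuples()}
    mt = maybe("motif_targets")
    if mt is not None:
        for r in mt.itertuples():
            kb.motif_targets.setdefault(r.tf_id, set()).add(r.gene_id)
    bg = maybe("background_genes")
    if bg is not None:
        kb.background_genes = bg
    kt = maybe("kinase_targets")
    if kt is not None:
        for r in kt.itertuples():
            kb.kinase_targets.setdefault(r.signal_id, set()).add((r.target_id, r.target_kind))
    tm = maybe("tf_mode")
    if tm is not None:
        kb.tf_mode = dict(zip(tm["tf_id"], tm["mode"]))
    rp = maybe("reaction_pathways")
    if rp is not None:
        for r in rp.itertuples():
            kb.reaction_pathways.setdefault(r.reaction_id, set()).add(r.pathway_id)
    pc = maybe("pathway_class")
    if pc is not None:
        kb.pathway_class = dict(zip(pc["pathway_id"], pc["class"]))
    tg = maybe("tf_genes")
    if tg is not None:
        kb.tf_genes = tg
    kb.validate()
    return kb


def write_knowledgebase(kb: KnowledgeBase, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)

    def tsv(name, rows, columns):
        pd.DataFrame(sorted(rows), columns=columns).to_csv(
            d / KB_FILES[name][0], sep="\t", index=False
        )

    tsv("enzyme_reactions",
        [(g, r) for g, rs in kb.enzyme_reactions.items() for r in rs],
        ["gene_id", "reaction_id"])
    rows = [(r, m, "substrate") for r, ms in kb.reaction_substrates.items() for m in ms]
    rows += [(r, m, "product") for r, ms in kb.reaction_products.items() for m in ms]
    tsv("reaction_metabolites", rows, ["reaction_id", "metabolite_id", "role"])
    tsv("allosteric", list(kb.allosteric), ["metabolite_id", "reaction_id", "mode"])
    tsv("motif_targets",
        [(tf, g) for tf, gs in kb.motif_targets.items() for g in gs],
        ["tf_id", "gene_id"])
    (d / KB_FILES["background_genes"][0]).write_text(
        "\n".join(sorted(kb.background_genes)) + "\n")
    tsv("kinase_targets",
        [(s, t, k) for s, ts in kb.kinase_targets.items() for t, k in ts],
        ["signal_id", "target_id", "target_kind"])
    tsv("tf_mode", list(kb.tf_mode.items()), ["tf_id", "mode"])
    tsv("reaction_pathways",
        [(r, p) for r, ps in kb.reaction_pathways.items() for p in ps],
        ["reaction_id", "pathway_id"])
    tsv("pathway_class", list(kb.pathway_class.items()), ["pathway_id", "class"])
    (d / KB_FILES["tf_genes"][0]).write_text("\n".join(sorted(kb.tf_genes)) + "\n")


# ---------------------------------------------------------------------------
# GML
# ---------------------------------------------------------------------------


def _gml_safe(value):
    if value is None:
        return "NA"
    if isinstance(value, float) and math.isnan(value):
        return "NA"
    if isinstance(value, (bool,)):
        return int(value)
    return value


def write_network_gml(graph: nx.Graph, path) -> None:
    """Write an attributed network as GML (round-trip safe).

    None/NaN attributes are encoded as the string ``"NA"`` since GML has no
    null literal.
    """
    g = graph.copy()
    for _n, d in g.nodes(data=True):
        for k in list(d):
            d[k] = _gml_safe(d[k])
    if g.is_multigraph():
        for _u, _v, _k, d in g.edges(data=True, keys=True):
            for k in list(d):
                d[k] = _gml_safe(d[k])
    else:
        for _u, _v, d in g.edges(data=True):
            for k in list(d):
                d[k] = _gml_safe(d[k])
    nx.write_gml(g, path)


def read_network_gml(path) -> nx.Graph:
    return nx.read_gml(path)
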