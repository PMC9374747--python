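"""Time-course normalization, Ward dendrograms, and TF-motif enrichment.

Gene (and metabolite) time courses of both genotypes are concatenated into a
single row per molecule, clustered with Ward linkage on Euclidean distances,
and every sufficiently large dendrogram node is tested for transcription
factor binding-motif enrichment with a one-tailed Fisher test.  A TF is
assigned to a node only when no large descendant node is more enriched for
the same motif (child-cluster exclusion), and regulatory TF->gene edges are
drawn to every gene of the assigned node.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage

from .datatypes import OmicsTimeCourse, ValidationError
from .stats import bh_qvalues, fisher_enrichment

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def normalize_metabolites(tc: OmicsTimeCourse) -> pd.DataFrame:
    """Fasting-anchored log-ratio matrix combining both genotypes.

    Each molecule's WT and OB mean traces are divided by the geometric mean
    of the two genotype fasting (0-min) means and log2-transformed; the
    output row is the concatenated (WT, OB) trace.  Molecules with a
    non-positive fasting mean in either genotype are excluded with a warning.
    """
    wt = tc.mean_traces("WT")
    ob = tc.mean_traces("OB")
    geo = np.sqrt(wt[0] * ob[0])
    ok = geo > 0
    n_bad = int((~ok.fillna(False)).sum())
    if n_bad:
        logger.warning("normalize_metabolites: excluded %d molecules with zero fasting mean", n_bad)
    geo = geo.where(ok)
    out = pd.concat(
        {"WT": np.log2(wt.div(geo, axis=0)), "OB": np.log2(ob.div(geo, axis=0))}, axis=1
    )
    out.columns = out.columns.set_names(["genotype", "time"])
    return out.loc[ok[ok].index].dropna()


def normalize_genes_zscore(tc_or_matrix) -> pd.DataFrame:
    """Z-score each gene's concatenated (WT, OB) mean trace.

    The combined 2T-point trace is centred on its own mean and divided by its
    standard deviation, so every surviving row has mean 0 and sd 1.  Rows
    with zero variance are excluded with a warning.
    """
    if isinstance(tc_or_matrix, OmicsTimeCourse):
        tc = tc_or_matrix
        mat = pd.concat({"WT": tc.mean_traces("WT"), "OB": tc.mean_traces("OB")}, axis=1)
        mat.columns = mat.columns.set_names(["genotype", "time"])
    else:
        mat = tc_or_matrix
    mat = mat.dropna()
    mu = mat.mean(axis=1)
    sd = mat.std(axis=1, ddof=0)
    ok = sd > 0
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("normalize_genes_zscore: excluded %d constant rows", n_bad)
    return mat.loc[ok].sub(mu[ok], axis=0).div(sd[ok], axis=0)


def cluster_selection_filter(
    calls_wt: pd.DataFrame,
    calls_ob: pd.DataFrame,
    baseline_q: pd.Series,
    q_threshold: float = 0.1,
) -> list[str]:
    """Genes entering the clustering: baseline-different or responsive-in-time.

    Union of (i) genes whose 0-min WT-vs-OB test q-value is below
    ``q_threshold`` and (ii) genes with q <= ``q_threshold`` at any post-bolus
    time in either genotype.  ``calls_wt``/``calls_ob`` are per-genotype
    slices of the responsiveness call table carrying ``q_<t>`` columns.
    """
    qcols_wt = [c for c in calls_wt.columns if c.startswith("q_")]
    qcols_ob = [c for c in calls_ob.columns if c.startswith("q_")]
    any_wt = (calls_wt[qcols_wt] <= q_threshold).any(axis=1)
    any_ob = (calls_ob[qcols_ob] <= q_threshold).any(axis=1)
    base = baseline_q < q_threshold
    selected = set(any_wt[any_wt].index) | set(any_ob[any_ob].index) | set(base[base].index)
    genes = [g for g in calls_wt.index if g in selected]
    logger.info("cluster_selection_filter: %d of %d genes selected", len(genes), len(calls_wt))
    return genes


# ---------------------------------------------------------------------------
# Ward dendrogram
# ---------------------------------------------------------------------------


@dataclass
class ClusterTree:
    """Agglomerative tree (Ward / Euclidean) over molecule rows.

    ``merges`` is the scipy linkage matrix; leaves are identified by the row
    ids of the clustered matrix.  Internal nodes are numbered scipy-style:
    node i >= n_leaves is the cluster created by merge i - n_leaves.
    """

    leaves: list[str]
    merges: np.ndarray

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def node_leaves(self) -> dict[int, frozenset[str]]:
        """Leaf set (molecule ids) under every node, keyed by node id."""
        out: dict[int, frozenset[str]] = {
            i: frozenset([mol]) for i, mol in enumerate(self.leaves)
        }
        n = self.n_leaves
        for i, (a, b, _h, _c) in enumerate(self.merges):
            out[n + i] = out[int(a)] | out[int(b)]
        return out

    def internal_nodes(self) -> list[int]:
        return [self.n_leaves + i for i in range(len(self.merges))]

    def descendants(self, node: int) -> list[int]:
        """All internal descendant node ids of an internal node."""
        n = self.n_leaves
        stack = [int(self.merges[node - n][0]), int(self.merges[node - n][1])]
        out = []
        while stack:
            v = stack.pop()
            if v >= n:
                out.append(v)
                stack.append(int(self.merges[v - n][0]))
                stack.append(int(self.merges[v - n][1]))
        return out


def ward_tree(matrix: pd.DataFrame) -> ClusterTree:
    """Ward's-method agglomeration on Euclidean distances between rows."""
    if matrix.shape[0] < 2:
        raise ValidationError("need at least 2 rows to cluster")
    if matrix.isna().any().any():
        raise ValidationError("matrix contains missing values; normalize first")
    Z = linkage(matrix.to_numpy(dtype=float), method="ward")
    return ClusterTree(list(matrix.index), Z)


def extract_clusters(tree: ClusterTree, k: int) -> dict[str, set[str]]:
    """The k disjoint clusters obtained by cutting below the k-1 top merges."""
    if not 1 <= k <= tree.n_leaves:
        raise ValueError(f"k must lie in [1, {tree.n_leaves}], got {k}")
    labels = cut_tree(tree.merges, n_clusters=k).ravel()
    out: dict[str, set[str]] = {}
    for mol, lab in zip(tree.leaves, labels):
        out.setdefault(f"C{lab + 1}", set()).add(mol)
    return out


# ---------------------------------------------------------------------------
# Motif enrichment with child-cluster exclusion
# ---------------------------------------------------------------------------


def enrich_tree_nodes(
    tree: ClusterTree,
    motif_targets: dict[str, set[str]],
    background: set[str],
    *,
    min_cluster_size: int = 100,
    enrichment_q: float = 0.1,
) -> pd.DataFrame:
    """Fisher motif enrichment at every tree node of size >= min_cluster_size.

    The 2x2 table contrasts motif presence inside the node's gene set with
    the rest of the background; p-values are one-tailed (enrichment) and BH
    q-values are computed across all (TF, node) tests.
    """
    node_sets = tree.node_leaves()
    big_nodes = [v for v in tree.internal_nodes() if len(node_sets[v]) >= min_cluster_size]
    n_bg = len(background)
    rows = []
    for tf, targets in sorted(motif_targets.items()):
        targets = targets & background
        k_total = len(targets)
        for v in big_nodes:
            cluster = node_sets[v] & background
            k_in = len(cluster & targets)
            odds, p = fisher_enrichment(k_in, len(cluster), k_total, n_bg)
            rows.append((tf, v, len(cluster), k_in, k_total, odds, p))
    out = pd.DataFrame(
        rows, columns=["tf_id", "node", "cluster_size", "k_in", "k_total", "odds_ratio", "p"]
    )
    if len(out):
        out["q"] = bh_qvalues(out["p"].to_numpy())
        out["enriched"] = out["q"] <= enrichment_q
    else:
        out["q"] = pd.Series(dtype=float)
        out["enriched"] = pd.Series(dtype=bool)
    logger.info(
        "enrich_tree_nodes: %d nodes >= %d genes, %d TFs, %d enriched pairs",
        len(big_nodes), min_cluster_size, len(motif_targets), int(out["enriched"].sum()),
    )
    return out


def assign_tf_clusters(
    tree: ClusterTree,
    enrichment: pd.DataFrame,
    *,
    comparator: str = "odds_ratio",
) -> pd.DataFrame:
    """Assign each TF to enriched nodes, excluding out-competed parents.

    A TF is assigned to a node iff the motif is enriched there and no large
    descendant node is *strictly* more enriched for it (odds-ratio comparison
    by default; ties keep the parent).  Returns the enrichment rows with an
    ``assigned`` flag and the winning descendant in ``excluded_by_child``.
    """
    if comparator not in ("odds_ratio", "p"):
        raise ValueError("comparator must be 'odds_ratio' or 'p'")
    out = enrichment.copy()
    out["assigned"] = False
    out["excluded_by_child"] = None
    desc_cache: dict[int, set[int]] = {}
    for tf, grp in enrichment.groupby("tf_id"):
        metric = {int(r.node): (r.odds_ratio if comparator == "odds_ratio" else -r.p)
                  for r in grp.itertuples()}
        for r in grp.itertuples():
            if not r.enriched:
                continue
            node = int(r.node)
            if node not in desc_cache:
                desc_cache[node] = set(tree.descendants(node))
            beaten_by = None
            own = metric[node]
            for d in desc_cache[node]:
                if d in metric and _strictly_greater(metric[d], own):
                    beaten_by = d
                    break
            if beaten_by is None:
                out.loc[r.Index, "assigned"] = True
            else:
                out.loc[r.Index, "excluded_by_child"] = beaten_by
    logger.info("assign_tf_clusters: %d assignments", int(out["assigned"].sum()))
    return out


def _strictly_greater(a: float, b: float) -> bool:
    # inf vs inf and nan comparisons must not exclude the parent
    if np.isnan(a) or np.isnan(b):
        return False
    return a > b


def infer_tf_gene_edges(
    assignments: pd.DataFrame, tree: ClusterTree
) -> set[tuple[str, str]]:
    """One edge from every assigned TF to every gene of its assigned node(s)."""
    node_sets = tree.node_leaves()
    edges: set[tuple[str, str]] = set()
    for r in assignments[assignments["assigned"]].itertuples():
        for gene in node_sets[int(r.node)]:
            edges.add((r.tf_id, gene))
    return edges


def validate_against_external_targets(
    inferred: dict[str, set[str]],
    external: dict[str, set[str]],
    background: set[str],
    *,
    q_threshold: float = 0.1,
) -> pd.DataFrame:
    """Overlap of inferred target genes with external (ChIP-style) targets.

    One-tailed Fisher per TF on the overlap within ``background``; BH
    q-values across TFs; significance flag at ``q_threshold``.
    """
    if not background:
        raise ValueError("background must be non-empty")
    rows = []
    for tf in sorted(set(inferred) & set(external)):
        inf_set = inferred[tf] & background
        ext_set = external[tf] & background
        k = len(inf_set & ext_set)
        if not inf_set:
            continue
        odds, p = fisher_enrichment(k, len(inf_set), len(ext_set), len(background))
        rows.append((tf, len(inf_set), len(ext_set), k, odds, p))
    out = pd.DataFrame(
        rows, columns=["tf_id", "n_inferred", "n_external", "n_overlap", "odds_ratio", "p"]
    )
    if len(out):
        out["q"] = bh_qvalues(out["p"].to_numpy())
        out["significant"] = out["q"] <= q_threshold
    else:
        out["q"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out
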