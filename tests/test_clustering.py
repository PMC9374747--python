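import itertools

import numpy as np
import pandas as pd
import pytest

from transomix.clustering import (
    ClusterTree,
    assign_tf_clusters,
    cluster_selection_filter,
    enrich_tree_nodes,
    extract_clusters,
    infer_tf_gene_edges,
    normalize_genes_zscore,
    normalize_metabolites,
    validate_against_external_targets,
    ward_tree,
)
from transomix.datatypes import ValidationError

from conftest import TIMES, make_tc


def brute_force_ward(X):
    """Naive Ward agglomeration from the ESS-increase definition.

    Merge cost computed directly as sqrt(2 |A||B| / (|A|+|B|)) * ||mean(A) -
    mean(B)||, scanning all cluster pairs at every step.
    """
    clusters = {i: [i] for i in range(len(X))}
    merges = []
    next_id = len(X)
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            ma = X[clusters[a]].mean(axis=0)
            mb = X[clusters[b]].mean(axis=0)
            na, nb = len(clusters[a]), len(clusters[b])
            d = np.sqrt(2 * na * nb / (na + nb)) * np.linalg.norm(ma - mb)
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        merges.append((frozenset(clusters[a]) | frozenset(clusters[b]), d))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


class TestNormalization:
    def test_geometric_mean_anchoring(self):
        rows = {
            "m": {
                ("WT", 0): [4.0] * 3, ("WT", 20): [8.0] * 3,
                ("WT", 60): [16.0] * 3, ("WT", 120): [8.0] * 3, ("WT", 240): [8.0] * 3,
                ("OB", 0): [16.0] * 3, ("OB", 20): [8.0] * 3,
                ("OB", 60): [8.0] * 3, ("OB", 120): [8.0] * 3, ("OB", 240): [8.0] * 3,
            }
        }
        norm = normalize_metabolites(make_tc(rows))
        # geometric mean of fasting means sqrt(4 * 16) = 8
        assert norm.loc["m", ("WT", 20)] == pytest.approx(0.0)
        assert norm.loc["m", ("WT", 60)] == pytest.approx(1.0)
        assert norm.loc["m", ("WT", 0)] == pytest.approx(-1.0)

    def test_identical_traces_symmetric(self):
        rows = {"m": {(g, t): [5.0 + t / 100] * 3 for g in ("WT", "OB") for t in TIMES}}
        norm = normalize_metabolites(make_tc(rows))
        np.testing.assert_allclose(norm["WT"].to_numpy(), norm["OB"].to_numpy())

    def test_zero_fasting_mean_excluded(self):
        rows = {
            "bad": {(g, t): ([0.0] * 3 if t == 0 and g == "WT" else [5.0] * 3)
                    for g in ("WT", "OB") for t in TIMES},
            "good": {(g, t): [5.0] * 3 for g in ("WT", "OB") for t in TIMES},
        }
        norm = normalize_metabolites(make_tc(rows))
        assert list(norm.index) == ["good"]

    def test_zscore_moments_and_affine_invariance(self):
        rng = np.random.default_rng(0)
        mat = pd.DataFrame(rng.normal(5, 2, (4, 10)), index=list("abcd"))
        z = normalize_genes_zscore(mat)
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=1, ddof=0), 1.0, atol=1e-12)
        z2 = normalize_genes_zscore(mat * 3.5 + 11.0)
        np.testing.assert_allclose(z2.to_numpy(), z.to_numpy(), atol=1e-12)

    def test_constant_rows_excluded(self):
        mat = pd.DataFrame([[1.0] * 6, [1, 2, 3, 4, 5, 6]], index=["const", "var"])
        assert list(normalize_genes_zscore(mat).index) == ["var"]


class TestSelectionFilter:
    def frame(self, qs: dict[str, list[float]]):
        cols = [f"q_{t}" for t in (20, 60, 120, 240)]
        return pd.DataFrame.from_dict(qs, orient="index", columns=cols)

    def test_union_of_baseline_and_timecourse(self):
        wt = self.frame({
            "base_only": [0.9, 0.9, 0.9, 0.9],
            "ob_late": [0.9, 0.9, 0.9, 0.9],
            "never": [0.9, 0.9, 0.9, 0.9],
        })
        ob = self.frame({
            "base_only": [0.9, 0.9, 0.9, 0.9],
            "ob_late": [0.9, 0.9, 0.05, 0.9],
            "never": [0.9, 0.9, 0.9, 0.9],
        })
        baseline_q = pd.Series({"base_only": 0.01, "ob_late": 0.9, "never": 0.9})
        got = cluster_selection_filter(wt, ob, baseline_q, 0.1)
        assert got == ["base_only", "ob_late"]


class TestWardTree:
    def test_one_dimensional_merge_order(self):
        mat = pd.DataFrame([[0.0], [1.0], [10.0]], index=["a", "b", "c"])
        tree = ward_tree(mat)
        sets = tree.node_leaves()
        assert sets[3] == {"a", "b"}  # closest pair merges first
        assert tree.merges[0, 2] == pytest.approx(1.0)
        # Ward distance of {a,b} to {c}: sqrt(2*2*1/3) * |0.5 - 10|
        assert tree.merges[1, 2] == pytest.approx(np.sqrt(4 / 3) * 9.5)

    def test_identical_rows_merge_at_zero(self):
        mat = pd.DataFrame([[1.0, 2], [5, 5], [1, 2], [9, 0]], index=list("abcd"))
        tree = ward_tree(mat)
        assert tree.node_leaves()[4] == {"a", "c"}
        assert tree.merges[0, 2] == pytest.approx(0.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        mat = pd.DataFrame(rng.normal(size=(6, 4)), index=list("abcdef"))
        t1 = ward_tree(mat)
        perm = mat.sample(frac=1.0, random_state=5)
        t2 = ward_tree(perm)
        parts1 = {frozenset(s) for s in t1.node_leaves().values()}
        parts2 = {frozenset(s) for s in t2.node_leaves().values()}
        assert parts1 == parts2
        np.testing.assert_allclose(
            np.sort(t1.merges[:, 2]), np.sort(t2.merges[:, 2]), atol=1e-10
        )

    @pytest.mark.parametrize("n", [3, 5, 7])
    def test_matches_brute_force_agglomeration(self, n):
        rng = np.random.default_rng(n)
        for _ in range(5):
            X = rng.normal(size=(n, 3))
            tree = ward_tree(pd.DataFrame(X, index=[f"r{i}" for i in range(n)]))
            expected = brute_force_ward(X)
            sets = tree.node_leaves()
            for i, (members, height) in enumerate(expected):
                got = {int(m[1:]) for m in sets[n + i]}
                assert got == set(members)
                assert tree.merges[i, 2] == pytest.approx(height)

    def test_missing_values_rejected(self):
        mat = pd.DataFrame([[1.0, np.nan], [2, 3]])
        with pytest.raises(ValidationError):
            ward_tree(mat)


class TestExtractClusters:
    def test_extreme_cuts(self):
        rng = np.random.default_rng(1)
        mat = pd.DataFrame(rng.normal(size=(5, 3)), index=list("abcde"))
        tree = ward_tree(mat)
        singletons = extract_clusters(tree, 5)
        assert sorted(len(v) for v in singletons.values()) == [1] * 5
        whole = extract_clusters(tree, 1)
        assert set.union(*whole.values()) == set("abcde")
        with pytest.raises(ValueError):
            extract_clusters(tree, 6)

    def test_planted_partition_recovered(self):
        rng = np.random.default_rng(4)
        lo = rng.normal(0, 0.1, (6, 4))
        hi = rng.normal(10, 0.1, (5, 4))
        mat = pd.DataFrame(
            np.vstack([lo, hi]),
            index=[f"lo{i}" for i in range(6)] + [f"hi{i}" for i in range(5)],
        )
        clusters = extract_clusters(ward_tree(mat), 2)
        parts = {frozenset(v) for v in clusters.values()}
        assert frozenset(f"lo{i}" for i in range(6)) in parts
        assert frozenset(f"hi{i}" for i in range(5)) in parts


def toy_tree():
    """Six leaves g0..g5; nodes: 6={g0,g1}, 7={g2,g3}, 8={g0..g3}, 9={g4,g5}, 10=all."""
    Z = np.array([
        [0, 1, 1.0, 2],
        [2, 3, 1.5, 2],
        [6, 7, 2.0, 4],
        [4, 5, 2.5, 2],
        [8, 9, 3.0, 6],
    ])
    return ClusterTree([f"g{i}" for i in range(6)], Z)


class TestAssignment:
    def enrichment_frame(self, rows):
        df = pd.DataFrame(
            rows, columns=["tf_id", "node", "cluster_size", "k_in", "k_total",
                           "odds_ratio", "p", "q"]
        )
        df["enriched"] = df["q"] <= 0.1
        return df

    def test_more_enriched_child_excludes_parent(self):
        tree = toy_tree()
        enr = self.enrichment_frame([
            ("tfX", 8, 4, 3, 5, 3.0, 0.01, 0.02),
            ("tfX", 6, 2, 2, 5, 5.0, 0.01, 0.02),
        ])
        out = assign_tf_clusters(tree, enr)
        by_node = out.set_index("node")
        assert not by_node.loc[8, "assigned"]
        assert by_node.loc[8, "excluded_by_child"] == 6
        assert by_node.loc[6, "assigned"]

    def test_small_children_cannot_exclude(self):
        # children below the size threshold never entered the enrichment table
        tree = toy_tree()
        enr = self.enrichment_frame([("tfX", 8, 4, 3, 5, 3.0, 0.01, 0.02)])
        out = assign_tf_clusters(tree, enr)
        assert out.loc[out["node"] == 8, "assigned"].item()

    def test_tie_keeps_parent(self):
        tree = toy_tree()
        enr = self.enrichment_frame([
            ("tfX", 8, 4, 3, 5, 4.0, 0.01, 0.02),
            ("tfX", 6, 2, 2, 5, 4.0, 0.01, 0.02),
        ])
        out = assign_tf_clusters(tree, enr).set_index("node")
        assert out.loc[8, "assigned"]
        assert out.loc[6, "assigned"]  # the child stands on its own too

    def test_unenriched_rows_never_assigned(self):
        tree = toy_tree()
        enr = self.enrichment_frame([("tfX", 8, 4, 1, 5, 1.2, 0.5, 0.7)])
        out = assign_tf_clusters(tree, enr)
        assert not out["assigned"].any()

    def test_exclusion_soundness_invariant(self):
        # after assignment no assigned node has a bigger-OR large descendant
        tree = toy_tree()
        enr = self.enrichment_frame([
            ("tfX", 10, 6, 4, 5, 2.0, 0.01, 0.02),
            ("tfX", 8, 4, 3, 5, 3.0, 0.01, 0.02),
            ("tfX", 6, 2, 2, 5, 5.0, 0.01, 0.02),
            ("tfY", 10, 6, 4, 6, 6.0, 0.01, 0.02),
            ("tfY", 9, 2, 1, 6, 1.5, 0.01, 0.02),
        ])
        out = assign_tf_clusters(tree, enr)
        metric = {(r.tf_id, int(r.node)): r.odds_ratio for r in enr.itertuples()}
        for r in out[out["assigned"]].itertuples():
            for d in tree.descendants(int(r.node)):
                if (r.tf_id, d) in metric:
                    assert metric[(r.tf_id, d)] <= metric[(r.tf_id, int(r.node))]


class TestEdgesAndValidation:
    def test_edge_cardinality_and_dedup(self):
        tree = toy_tree()
        assignments = pd.DataFrame({
            "tf_id": ["tfX", "tfX"], "node": [6, 8], "assigned": [True, True],
        })
        edges = infer_tf_gene_edges(assignments, tree)
        # node 6 is inside node 8: union is just node 8's four genes
        assert edges == {("tfX", f"g{i}") for i in range(4)}

    def test_no_assignments_no_edges(self):
        tree = toy_tree()
        assignments = pd.DataFrame({"tf_id": [], "node": [], "assigned": []})
        assert infer_tf_gene_edges(assignments, tree) == set()

    def test_enrich_tree_nodes_respects_size_threshold(self):
        tree = toy_tree()
        background = set(tree.leaves)
        enr = enrich_tree_nodes(
            tree, {"tfX": {"g0", "g1"}}, background,
            min_cluster_size=4, enrichment_q=0.1,
        )
        assert set(enr["node"]) == {8, 10}  # only nodes with >= 4 leaves

    def test_external_validation_extremes(self):
        background = {f"g{i}" for i in range(1000)}
        strong = {f"g{i}" for i in range(50)}
        out = validate_against_external_targets(
            {"tfA": strong, "tfB": {"g1", "g2"}},
            {"tfA": strong, "tfB": background},
            background,
        )
        by_tf = out.set_index("tf_id")
        assert by_tf.loc["tfA", "p"] < 1e-20
        assert bool(by_tf.loc["tfA", "significant"])
        assert by_tf.loc["tfB", "p"] == pytest.approx(1.0)  # external = background
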