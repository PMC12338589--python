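import math
from collections import deque

import dendropy
import numpy as np
import pytest
from scipy import stats

from epoclib.tree_ops import (
    DISCARD_OVER_30,
    leaf_names,
    partition_supercluster,
    prune_branch_outliers,
    side_sums_at_root,
    taxonomy_aware_subsample,
    topo_distance,
    tree_from_string,
    tree_to_string,
    weighted_midpoint_root,
)
from epoclib.taxonomy import DOMAIN_EUK, DOMAIN_PROK

from conftest import make_taxonomy, random_binary_tree


# ---------------------------------------------------------------------------
# outlier pruning
# ---------------------------------------------------------------------------

def _lognormal_tree(n_leaves, rng):
    return random_binary_tree(
        [f"L{i}" for i in range(n_leaves)], rng,
        bl=lambda r: float(r.lognormal(0.0, 1.0)),
    )


class TestPruneBranchOutliers:
    def test_equal_branch_lengths_degenerate_fit(self, rng):
        tree = random_binary_tree(list("ABCDEF"), rng, bl=lambda r: 0.5)
        pruned, report = prune_branch_outliers(tree)
        assert report.degenerate_fit
        assert not report.removed_leaves
        assert sorted(leaf_names(pruned)) == sorted(leaf_names(tree))

    def test_huge_branch_removed_against_quantile_oracle(self, rng):
        # ~100 log-normal(0,1) branches plus one terminal branch at e^10
        tree = _lognormal_tree(51, rng)
        target = next(l for l in tree.leaf_node_iter()
                      if l.taxon.label == "L17")
        target.edge.length = math.exp(10.0)
        # independent oracle: MLE log-normal fit, flag > 99.5% quantile
        lengths = np.array([
            e.length for e in tree.preorder_edge_iter()
            if e.length and e.head_node is not tree.seed_node
        ])
        logs = np.log(lengths)
        cutoff = math.exp(logs.mean() + logs.std() * stats.norm.ppf(0.995))
        expected = {
            l.taxon.label for l in tree.leaf_node_iter()
            if (l.edge.length or 0.0) > cutoff
        }
        assert "L17" in expected
        pruned, report = prune_branch_outliers(tree)
        assert "L17" in report.removed_leaves
        assert report.upper_cutoff == pytest.approx(cutoff, rel=1e-9)
        assert expected <= report.removed_leaves

    def test_long_internal_edge_removes_whole_clade(self, rng):
        tree = _lognormal_tree(40, rng)
        # pick an internal node with a modest subtree and stretch its stem
        node = next(
            n for n in tree.preorder_internal_node_iter()
            if n is not tree.seed_node
            and 2 <= sum(1 for _ in n.leaf_iter()) <= 5
        )
        members = {l.taxon.label for l in node.leaf_iter()}
        node.edge.length = math.exp(12.0)
        _, report = prune_branch_outliers(tree)
        assert members <= report.removed_leaves
        assert any(set(c) == members for c in report.removed_clades)

    def test_forty_percent_loss_flags_discard(self, rng):
        # 40 of 100 leaves hang under one absurdly long internal edge
        big = random_binary_tree(
            [f"B{i}" for i in range(60)], rng,
            bl=lambda r: float(r.lognormal(0.0, 1.0)),
        )
        doomed = random_binary_tree(
            [f"D{i}" for i in range(40)], rng,
            bl=lambda r: float(r.lognormal(0.0, 1.0)),
        )
        root = dendropy.Node()
        for sub, stem in ((big, 0.5), (doomed, math.exp(12.0))):
            child = sub.seed_node
            child.edge.length = stem
            root.add_child(child)
        tree = dendropy.Tree()
        tree.seed_node = root
        ns = tree.taxon_namespace
        for leaf in tree.leaf_node_iter():
            leaf.taxon = ns.new_taxon(label=leaf.taxon.label)
        _, report = prune_branch_outliers(tree)
        assert report.discarded
        assert report.discard_reason == DISCARD_OVER_30
        assert len(report.removed_leaves) == 40

    def test_all_eukaryotes_removed_flags_discard(self, rng):
        tree = tree_from_string(
            "((E1:0.1,E2:0.1):60.0,((P1:0.1,P2:0.2):0.15,"
            "(P3:0.1,(P4:0.12,P5:0.2):0.1):0.2):0.1);"
        )
        tax = make_taxonomy({
            "E1": (DOMAIN_EUK, "Metazoa", "Amorphea"),
            "E2": (DOMAIN_EUK, "Fungi", "Amorphea"),
            **{f"P{i}": (DOMAIN_PROK, "Asgard") for i in range(1, 6)},
        })
        _, report = prune_branch_outliers(tree, taxonomy=tax)
        assert report.removed_leaves == {"E1", "E2"}
        assert report.discarded
        assert report.discard_reason == "all-eukaryotes-removed"

    def test_null_false_removal_rate_is_low(self, rng):
        # fraction of branches falsely flagged on clean log-normal data
        flagged = total = 0
        for _ in range(30):
            tree = _lognormal_tree(40, rng)
            n_branches = sum(
                1 for e in tree.preorder_edge_iter()
                if e.head_node is not tree.seed_node
            )
            _, report = prune_branch_outliers(tree)
            in_clades = set().union(*report.removed_clades) \
                if report.removed_clades else set()
            flagged += len(report.removed_clades) \
                + len(report.removed_leaves - in_clades)
            total += n_branches
        assert flagged / total <= 0.02


# ---------------------------------------------------------------------------
# weighted midpoint rooting
# ---------------------------------------------------------------------------

def _brute_force_balance(tree, n_grid=2001):
    """Exhaustive edge/position scan for the minimal side imbalance."""
    below = {}
    for node in tree.postorder_node_iter():
        below[id(node)] = sum(
            (c.edge.length or 0.0) + below[id(c)] for c in node.child_nodes()
        )
    total = sum(
        e.length or 0.0 for e in tree.preorder_edge_iter()
        if e.head_node is not tree.seed_node
    )
    best = math.inf
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        length = edge.length or 0.0
        s_below = below[id(edge.head_node)]
        for x in np.linspace(0.0, length, n_grid):
            best = min(best, abs(total - 2 * (s_below + x)))
    return best, total


class TestWeightedMidpointRoot:
    def test_two_leaf_balance(self):
        rooted = weighted_midpoint_root(tree_from_string("(A:3,B:1);"))
        assert side_sums_at_root(rooted) == pytest.approx((2.0, 2.0))

    def test_symmetric_tree_roots_at_center(self):
        tree = tree_from_string("((A:1,B:1):2,(C:1,D:1):2);")
        rooted = weighted_midpoint_root(tree)
        left, right = side_sums_at_root(rooted)
        assert left == pytest.approx(right, abs=1e-12)

    def test_caterpillar_matches_exhaustive_scan(self):
        tree = tree_from_string(
            "(((((A:1,B:2):6,C:3):7,D:4):8,E:5):9,F:10);"
        )
        best, total = _brute_force_balance(tree, n_grid=10**6 // 100)
        rooted = weighted_midpoint_root(tree)
        sums = side_sums_at_root(rooted)
        assert abs(sums[0] - sums[1]) <= best + total * 1e-6

    def test_random_trees_match_brute_force(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 15))
            tree = random_binary_tree([f"T{i}" for i in range(n)], rng)
            best, total = _brute_force_balance(tree)
            rooted = weighted_midpoint_root(tree)
            sums = side_sums_at_root(rooted)
            achieved = abs(sums[0] - sums[1])
            assert achieved <= best + total * 1e-5
            # interior balance points are exact
            if best < total * 1e-9:
                assert achieved <= total * 1e-9

    def test_leaf_set_and_lengths_preserved(self, rng):
        tree = random_binary_tree(list("ABCDEFG"), rng)
        total_before = sum(
            e.length or 0.0 for e in tree.preorder_edge_iter()
            if e.head_node is not tree.seed_node
        )
        rooted = weighted_midpoint_root(tree)
        assert sorted(leaf_names(rooted)) == sorted(leaf_names(tree))
        total_after = sum(
            e.length or 0.0 for e in rooted.preorder_edge_iter()
            if e.head_node is not rooted.seed_node
        )
        assert total_after == pytest.approx(total_before, rel=1e-9)


# ---------------------------------------------------------------------------
# topological distance
# ---------------------------------------------------------------------------

def _bfs_path_oracle(tree, a, b):
    """Interior non-root node count on the a--b path via plain BFS."""
    adj = {}
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            adj.setdefault(id(node), []).append(child)
            adj.setdefault(id(child), []).append(node)
    prev = {id(a): None}
    queue = deque([a])
    while queue:
        cur = queue.popleft()
        if cur is b:
            break
        for nxt in adj.get(id(cur), []):
            if id(nxt) not in prev:
                prev[id(nxt)] = cur
                queue.append(nxt)
    path = [b]
    while prev[id(path[-1])] is not None:
        path.append(prev[id(path[-1])])
    interior = path[1:-1]
    return sum(1 for n in interior if n is not tree.seed_node)


class TestTopoDistance:
    def test_node_to_itself_is_zero(self, rng):
        tree = random_binary_tree(list("ABCD"), rng)
        leaf = next(tree.leaf_node_iter())
        assert topo_distance(tree, leaf, leaf) == 0

    def test_siblings_below_non_root_parent(self):
        tree = tree_from_string("(((A:1,B:1):1,C:1):1,D:1);")
        a = next(l for l in tree.leaf_node_iter() if l.taxon.label == "A")
        b = next(l for l in tree.leaf_node_iter() if l.taxon.label == "B")
        assert topo_distance(tree, a, b) == 1

    def test_matches_bfs_oracle_on_random_pairs(self, rng):
        tree = random_binary_tree([f"T{i}" for i in range(20)], rng)
        nodes = list(tree.preorder_node_iter())
        for _ in range(100):
            i, j = rng.integers(len(nodes), size=2)
            a, b = nodes[int(i)], nodes[int(j)]
            expected = 0 if a is b else _bfs_path_oracle(tree, a, b)
            assert topo_distance(tree, a, b) == expected
            assert topo_distance(tree, b, a) == expected

    def test_foreign_node_rejected(self, rng):
        tree = random_binary_tree(list("ABCD"), rng)
        other = random_binary_tree(list("XY"), rng)
        with pytest.raises(ValueError):
            topo_distance(tree, next(tree.leaf_node_iter()),
                          next(other.leaf_node_iter()))


# ---------------------------------------------------------------------------
# taxonomy-aware subsampling
# ---------------------------------------------------------------------------

class TestTaxonomyAwareSubsample:
    def test_target_above_size_keeps_everything(self, rng):
        tree = random_binary_tree([f"L{i}" for i in range(10)], rng)
        tax = make_taxonomy({
            f"L{i}": (DOMAIN_PROK, "Asgard") for i in range(10)
        })
        keep = taxonomy_aware_subsample(tree, tax, target=30)
        assert keep == set(leaf_names(tree))

    def test_cherry_keeps_leaf_closest_to_root(self):
        tree = tree_from_string("((A:0.3,B:0.5):0.1,(C:1.0,D:1.0):0.1);")
        # A and B share a label and a parent; A is 0.4 from the root,
        # B is 0.6: the prune must keep A.
        tax = make_taxonomy({
            "A": (DOMAIN_PROK, "Asgard"), "B": (DOMAIN_PROK, "Asgard"),
            "C": (DOMAIN_PROK, "Bacilli"), "D": (DOMAIN_PROK, "Chlorobi"),
        })
        keep = taxonomy_aware_subsample(tree, tax, target=3)
        assert keep == {"A", "C", "D"}

    def test_label_diversity_preserved_at_label_count_target(self):
        # 9 leaves, 3 monophyletic labels; target 3 keeps one per label
        tree = tree_from_string(
            "((a1:0.1,(a2:0.1,a3:0.1):0.1):0.2,"
            "((b1:0.1,(b2:0.1,b3:0.1):0.1):0.3,"
            "(c1:0.1,(c2:0.1,c3:0.1):0.1):0.3):0.2);"
        )
        tax = make_taxonomy({
            **{f"a{i}": (DOMAIN_PROK, "Asgard") for i in (1, 2, 3)},
            **{f"b{i}": (DOMAIN_PROK, "Bacilli") for i in (1, 2, 3)},
            **{f"c{i}": (DOMAIN_PROK, "Chlorobi") for i in (1, 2, 3)},
        })
        keep = taxonomy_aware_subsample(tree, tax, target=3)
        assert len(keep) == 3
        labels = {tax.label_of(name) for name in keep}
        assert labels == {"Asgard", "Bacilli", "Chlorobi"}

    def test_singletons_deleted_first_after_convergence(self):
        # Converges with 4 leaves (no same-label cherry left); the two
        # surviving collapsed leaves have pruned relatives, the two
        # singleton labels do not and are deleted first.
        tree = tree_from_string(
            "(((a1:0.1,a2:0.2):0.1,(b1:0.1,b2:0.2):0.1):0.1,"
            "(x1:0.1,y1:0.1):0.1);"
        )
        tax = make_taxonomy({
            "a1": (DOMAIN_PROK, "Asgard"), "a2": (DOMAIN_PROK, "Asgard"),
            "b1": (DOMAIN_PROK, "Bacilli"), "b2": (DOMAIN_PROK, "Bacilli"),
            "x1": (DOMAIN_PROK, "Chlorobi"), "y1": (DOMAIN_PROK, "Aquificae"),
        })
        keep = taxonomy_aware_subsample(tree, tax, target=2)
        assert keep == {"a1", "b1"}


# ---------------------------------------------------------------------------
# supercluster partitioning
# ---------------------------------------------------------------------------

def _planted_clades_tree(rng, sizes, separation=50.0):
    """Well-separated clades joined by internal edges far longer than the
    within-clade diameter."""
    subtrees = []
    ns = dendropy.TaxonNamespace()
    for ci, size in enumerate(sizes):
        sub = random_binary_tree(
            [f"g{ci}_{i}" for i in range(size)], rng,
            bl=lambda r: float(r.uniform(0.01, 0.05)),
        )
        subtrees.append(sub)
    root = dendropy.Node()
    for sub in subtrees:
        child = sub.seed_node
        child.edge.length = separation
        root.add_child(child)
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = root
    for leaf in tree.leaf_node_iter():
        leaf.taxon = ns.new_taxon(label=leaf.taxon.label)
    return tree


class TestPartitionSupercluster:
    def test_two_planted_clades_recovered(self, rng):
        tree = _planted_clades_tree(rng, [20, 20])
        groups = partition_supercluster(tree, random_state=0)
        assert len(groups) == 2
        expected = [{f"g0_{i}" for i in range(20)},
                    {f"g1_{i}" for i in range(20)}]
        assert sorted(map(sorted, groups)) == sorted(map(sorted, expected))

    def test_three_planted_clades_monophyletic(self, rng):
        tree = _planted_clades_tree(rng, [15, 15, 15])
        groups = partition_supercluster(tree, random_state=0)
        assert len(groups) == 3
        for group in groups:
            prefixes = {name.split("_")[0] for name in group}
            assert len(prefixes) == 1

    def test_homogeneous_tree_single_partition(self, rng):
        tree = random_binary_tree(
            [f"L{i}" for i in range(40)], rng, bl=lambda r: 0.1
        )
        groups = partition_supercluster(tree, random_state=0)
        assert len(groups) == 1
        assert groups[0] == set(leaf_names(tree))

    def test_tiny_tree_falls_back_to_single_partition(self, rng):
        tree = random_binary_tree(list("ABCDE"), rng)
        groups = partition_supercluster(tree)
        assert groups == [set("ABCDE")]


def test_newick_round_trip_preserves_underscores():
    newick = "((Asgard_1:0.1,Asgard_2:0.2):0.1,Euk_1:0.3);"
    tree = tree_from_string(newick)
    assert sorted(leaf_names(tree)) == ["Asgard_1", "Asgard_2", "Euk_1"]
    assert "Asgard_1" in tree_to_string(tree)
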