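"""Gene-tree manipulations on dendropy trees.

Covers the preprocessing steps applied to every gene tree before ancestry
inference: log-normal long-branch outlier pruning, weighted midpoint
rooting, topological distances, taxonomy-aware subsampling and the
embedding-based partitioning of superclusters into well-separated clades.

Trees are ``dendropy.Tree`` objects throughout; leaves are identified by
their taxon labels (sequence ids), which must be unique.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
from scipy import stats

DISCARD_NONE = "none"
DISCARD_ALL_EUK = "all-eukaryotes-removed"
DISCARD_OVER_30 = "over-30-percent-removed"


# ---------------------------------------------------------------------------
# IO helpers
# ---------------------------------------------------------------------------

def tree_from_string(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
    # treat the data structure as rooted so MRCA queries never collapse the
    # basal bifurcation in place
    tree.is_rooted = True
    return tree


def load_tree(path) -> dendropy.Tree:
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    tree.is_rooted = True
    return tree


def tree_to_string(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick", unquoted_underscores=True, suppress_rooting=True
    ).strip()


def save_tree(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree_to_string(tree) + "\n")


def clone_tree(tree: dendropy.Tree) -> dendropy.Tree:
    return tree.clone(depth=1)


def leaf_names(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def find_mrca(tree: dendropy.Tree, names) -> dendropy.Node:
    """MRCA node of a set of leaf labels."""
    names = set(names)
    if len(names) == 1:
        (name,) = names
        for lf in tree.leaf_node_iter():
            if lf.taxon.label == name:
                return lf
        raise KeyError(name)
    tree.is_rooted = True  # keep MRCA from derooting the structure
    return tree.mrca(taxon_labels=list(names))


def assert_valid(tree: dendropy.Tree) -> None:
    """Invariant check: unique leaf names and non-negative branch lengths."""
    names = leaf_names(tree)
    if len(names) != len(set(names)):
        raise ValueError("leaf names are not unique")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError("negative branch length")


# ---------------------------------------------------------------------------
# Long-branch outlier pruning
# ---------------------------------------------------------------------------

@dataclass
class PruneReport:
    """Outcome of the log-normal branch-length outlier screen."""

    removed_leaves: set = field(default_factory=set)
    removed_clades: list = field(default_factory=list)
    fitted_logmean: float = float("nan")
    fitted_logsd: float = float("nan")
    upper_cutoff: float = float("inf")
    discarded: bool = False
    discard_reason: str = DISCARD_NONE
    degenerate_fit: bool = False

    def to_json_dict(self) -> dict:
        d = asdict(self)
        d["removed_leaves"] = sorted(self.removed_leaves)
        d["removed_clades"] = [sorted(c) for c in self.removed_clades]
        return d


def prune_branch_outliers(
    tree: dendropy.Tree,
    ppf_upper: float = 0.995,
    taxonomy=None,
    max_removed_frac: float = 0.30,
    terminal_only: bool = False,
    sd_tol: float = 1e-8,
) -> tuple[dendropy.Tree, PruneReport]:
    """Remove subtrees hanging from implausibly long branches.

    A log-normal distribution is fitted by maximum likelihood (mean/sd of the
    log lengths) to all positive branch lengths — terminal and internal by
    default — and every subtree whose stem exceeds the upper ``ppf_upper``
    quantile is removed, which deletes both long terminal leaf branches and
    highly diverged clades in one pass. The one-sided upper interval is used
    because the lower bound 0 excludes nothing.

    The tree is flagged ``discarded`` when the screen would remove the entire
    eukaryotic clade (requires ``taxonomy``) or more than ``max_removed_frac``
    of all leaves. A degenerate fit (log-sd below ``sd_tol``, e.g. all branch
    lengths equal) prunes nothing and is flagged on the report.
    """
    if not 0 < ppf_upper < 1:
        raise ValueError("ppf_upper must be in (0, 1)")
    n_leaves_total = sum(1 for _ in tree.leaf_node_iter())
    if n_leaves_total < 4:
        raise ValueError("tree must have at least 4 leaves")

    work = clone_tree(tree)
    lengths = []
    for edge in work.preorder_edge_iter():
        if edge.head_node is work.seed_node or edge.length is None:
            continue
        if terminal_only and not edge.head_node.is_leaf():
            continue
        if edge.length > 0:
            lengths.append(edge.length)
    if len(lengths) < 3:
        raise ValueError("need at least 3 positive branch lengths")

    logs = np.log(lengths)
    mu = float(np.mean(logs))
    sd = float(np.std(logs))  # MLE (ddof=0)
    report = PruneReport(fitted_logmean=mu, fitted_logsd=sd)
    if sd < sd_tol:
        report.degenerate_fit = True
        return work, report
    report.upper_cutoff = float(math.exp(mu + sd * stats.norm.ppf(ppf_upper)))

    # Collect offending edges top-down; nested hits are subsumed by their
    # ancestor's removal.
    to_remove: list[dendropy.Node] = []
    removed_set: set[int] = set()
    for edge in work.preorder_edge_iter():
        node = edge.head_node
        if node is work.seed_node or edge.length is None:
            continue
        if any(id(a) in removed_set for a in node.ancestor_iter()):
            continue
        if terminal_only and not node.is_leaf():
            continue
        if edge.length > report.upper_cutoff:
            to_remove.append(node)
            removed_set.add(id(node))

    for node in to_remove:
        members = {lf.taxon.label for lf in node.leaf_iter()}
        if node.is_leaf():
            report.removed_leaves.add(node.taxon.label)
        else:
            report.removed_clades.append(frozenset(members))
            report.removed_leaves.update(members)
        node.parent_node.remove_child(node)
    if to_remove:
        work.suppress_unifurcations()

    n_removed = len(report.removed_leaves)
    if n_removed > max_removed_frac * n_leaves_total:
        report.discarded = True
        report.discard_reason = DISCARD_OVER_30
    elif taxonomy is not None and n_removed:
        euk_left = any(
            taxonomy.is_eukaryote(lf.taxon.label)
            for lf in work.leaf_node_iter()
        )
        euk_existed = any(
            taxonomy.is_eukaryote(name)
            for name in leaf_names(tree)
        )
        if euk_existed and not euk_left:
            report.discarded = True
            report.discard_reason = DISCARD_ALL_EUK
    return work, report


# ---------------------------------------------------------------------------
# Weighted midpoint rooting
# ---------------------------------------------------------------------------

def weighted_midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root where the total branch length on either side balances.

    Scans every edge for the split point at which the summed branch lengths of
    the two sides are as close as possible; within an edge the balance point
    is solved linearly and clamped to the edge. Ties between edges are broken
    by preorder edge index. Zero total length leaves the tree unchanged with a
    warning.
    """
    work = clone_tree(tree)
    n_leaves = sum(1 for _ in work.leaf_node_iter())
    if n_leaves < 2:
        raise ValueError("tree must have at least 2 leaves")

    total = 0.0
    below: dict[int, float] = {}
    for node in work.postorder_node_iter():
        s = 0.0
        for ch in node.child_nodes():
            s += (ch.edge.length or 0.0) + below[id(ch)]
        below[id(node)] = s
    for edge in work.preorder_edge_iter():
        if edge.head_node is not work.seed_node and edge.length:
            total += edge.length
    if total <= 0:
        warnings.warn("zero total branch length; keeping original root",
                      stacklevel=2)
        return work

    best = None  # (imbalance, index, edge, x_below)
    for idx, edge in enumerate(work.preorder_edge_iter()):
        if edge.head_node is work.seed_node:
            continue
        length = edge.length or 0.0
        s_below = below[id(edge.head_node)]
        x = min(max(total / 2.0 - s_below, 0.0), length)
        imbalance = abs(total - 2.0 * (s_below + x))
        if best is None or imbalance < best[0] - 1e-15:
            best = (imbalance, idx, edge, x)
    _, _, edge, x = best
    length = edge.length or 0.0
    # length1 applies to the tail (parent) side, length2 to the head (child)
    # side of the split edge.
    work.reroot_at_edge(edge, length1=length - x, length2=x)
    work.suppress_unifurcations()
    return work


def side_sums_at_root(tree: dendropy.Tree) -> tuple[float, ...]:
    """Total branch length hanging under each child of the root."""
    sums = []
    for ch in tree.seed_node.child_nodes():
        s = ch.edge.length or 0.0
        for edge in (e for n in ch.preorder_iter() for e in [n.edge]
                     if n is not ch):
            s += edge.length or 0.0
        sums.append(s)
    return tuple(sums)


# ---------------------------------------------------------------------------
# Topological distance
# ---------------------------------------------------------------------------

def _check_in_tree(tree: dendropy.Tree, node: dendropy.Node) -> None:
    cur = node
    while cur.parent_node is not None:
        cur = cur.parent_node
    if cur is not tree.seed_node:
        raise ValueError("node not found in tree")


def topo_distance(
    tree: dendropy.Tree, node_a: dendropy.Node, node_b: dendropy.Node
) -> int:
    """Number of non-root internal nodes strictly between two nodes.

    Counts the bifurcation (or multifurcation, once per node) points on the
    path connecting ``node_a`` and ``node_b``, excluding both endpoints and
    the tree root. Symmetric; 0 for a node paired with itself.
    """
    _check_in_tree(tree, node_a)
    _check_in_tree(tree, node_b)
    if node_a is node_b:
        return 0
    anc_a = [node_a] + list(node_a.ancestor_iter())
    anc_b = [node_b] + list(node_b.ancestor_iter())
    set_a = {id(n) for n in anc_a}
    lca = next(n for n in anc_b if id(n) in set_a)
    path: list[dendropy.Node] = []
    for n in anc_a:
        if n is lca:
            break
        path.append(n)
    path.append(lca)
    tail = []
    for n in anc_b:
        if n is lca:
            break
        tail.append(n)
    path.extend(reversed(tail))
    interior = path[1:-1]
    return sum(1 for n in interior if n is not tree.seed_node)


# ---------------------------------------------------------------------------
# Taxonomy-aware subsampling
# ---------------------------------------------------------------------------

def _root_distance(node: dendropy.Node) -> float:
    d = 0.0
    cur = node
    while cur.parent_node is not None:
        d += cur.edge.length or 0.0
        cur = cur.parent_node
    return d


def taxonomy_aware_subsample(
    tree: dendropy.Tree,
    taxonomy,
    target: int,
    labels: dict | None = None,
    protected=frozenset(),
) -> set[str]:
    """Reduce a tree to ``target`` leaves while preserving label diversity.

    Iteratively collapses the closest pair of same-label sibling leaves
    (label-monophyletic cherries), keeping the leaf closest to the root and
    accumulating the count of pruned relatives on the survivor. If the
    procedure converges above ``target`` (no same-label cherry left), the
    remaining leaves are ordered by their pruned-relative counts and the
    lowest-count leaves — isolated singletons first — are deleted until the
    target is reached. Leaves in ``protected`` are never deleted (used to
    subsample one domain of a mixed tree without touching the other).
    Returns the retained leaf names.
    """
    if target < 1:
        raise ValueError("target must be >= 1")
    label_of = (labels.__getitem__ if labels is not None
                else taxonomy.label_of)
    work = clone_tree(tree)
    leaves = list(work.leaf_node_iter())
    if target >= len(leaves):
        return {lf.taxon.label for lf in leaves}

    pruned_count: dict[str, int] = {lf.taxon.label: 0 for lf in leaves}

    def same_label_cherries():
        out = []
        for node in work.preorder_internal_node_iter():
            kids = node.child_nodes()
            leaf_kids = [k for k in kids if k.is_leaf()]
            for i in range(len(leaf_kids)):
                for j in range(i + 1, len(leaf_kids)):
                    a, b = leaf_kids[i], leaf_kids[j]
                    if label_of(a.taxon.label) == label_of(b.taxon.label):
                        dist = (a.edge.length or 0.0) + (b.edge.length or 0.0)
                        out.append((dist, a, b))
        return out

    n = len(leaves)
    while n > target:
        cherries = same_label_cherries()
        if not cherries:
            break
        cherries.sort(key=lambda t: (t[0],
                                     min(t[1].taxon.label, t[2].taxon.label)))
        _, a, b = cherries[0]
        da, db = _root_distance(a), _root_distance(b)
        if (da, a.taxon.label) <= (db, b.taxon.label):
            keep, drop = a, b
        else:
            keep, drop = b, a
        pruned_count[keep.taxon.label] += pruned_count[drop.taxon.label] + 1
        drop.parent_node.remove_child(drop)
        work.suppress_unifurcations()
        n -= 1

    if n > target:
        remaining = sorted(
            (lf.taxon.label for lf in work.leaf_node_iter()
             if lf.taxon.label not in protected),
            key=lambda name: (pruned_count[name], name),
        )
        doomed = set(remaining[: n - target])
        for lf in list(work.leaf_node_iter()):
            if lf.taxon.label not in doomed:
                continue
            parent = lf.parent_node
            parent.remove_child(lf)
            while parent is not None and not parent.child_nodes():
                grand = parent.parent_node
                if grand is None:
                    break
                grand.remove_child(parent)
                parent = grand
        work.suppress_unifurcations()

    return {lf.taxon.label for lf in work.leaf_node_iter()}


# ---------------------------------------------------------------------------
# Supercluster partitioning
# ---------------------------------------------------------------------------

def patristic_matrix(tree: dendropy.Tree) -> tuple[np.ndarray, list[str]]:
    """All-vs-all leaf patristic distances and the leaf order used."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(
        (lf.taxon for lf in tree.leaf_node_iter()), key=lambda t: t.label
    )
    n = len(taxa)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[i], taxa[j])
            mat[i, j] = mat[j, i] = d
    return mat, [t.label for t in taxa]


def partition_supercluster(
    tree: dendropy.Tree,
    n_neighbors: int = 50,
    min_dist: float = 0.3,
    metric: str = "euclidean",
    min_cluster_size: int = 5,
    random_state: int = 0,
) -> list[set[str]]:
    """Split a supercluster tree into well-separated leaf groups.

    The square patristic distance matrix is embedded into two dimensions with
    UMAP (rows of the matrix as feature vectors under the chosen metric) and
    the embedding is clustered with HDBSCAN. Single-partition outputs are
    explicitly allowed: trees with a homogeneous distribution of pairwise
    distances come back as one group. Noise points are attached to the
    nearest cluster centroid in the embedding. Trees with fewer than 8 leaves
    fall back to a single partition; the UMAP neighbourhood is capped at
    n_leaves − 1.
    """
    names = leaf_names(tree)
    n = len(names)
    if n < 3:
        raise ValueError("tree must have at least 3 leaves")
    if n < 8:
        return [set(names)]

    mat, order = patristic_matrix(tree)
    import umap  # deferred: numba-jitted import is expensive
    from sklearn.cluster import HDBSCAN

    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=min(n_neighbors, n - 1),
        min_dist=min_dist,
        metric=metric,
        random_state=random_state,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        emb = reducer.fit_transform(mat)
    clusterer = HDBSCAN(
        min_cluster_size=min(min_cluster_size, max(2, n // 2)),
        allow_single_cluster=True,
    )
    labels = clusterer.fit_predict(emb)

    unique = sorted(set(labels) - {-1})
    if not unique:
        return [set(order)]
    centroids = {k: emb[labels == k].mean(axis=0) for k in unique}
    for i in np.flatnonzero(labels == -1):
        labels[i] = min(
            unique, key=lambda k: float(np.sum((emb[i] - centroids[k]) ** 2))
        )
    groups = [
        {order[i] for i in np.flatnonzero(labels == k)} for k in unique
    ]
    return groups
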