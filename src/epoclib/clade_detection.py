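"""Soft-LCA clade detection and EPOC assembly.

Leaves of a rooted gene tree carry curated class labels. Real gene trees are
rarely cleanly monophyletic per label — single intruding leaves from local
topology errors or within-tree transfer are common — so instead of requiring
strict monophyly we score every ancestor of each monophyletic label group
with a "soft LCA" statistic that balances label purity against label scope,
and accept the best-scoring non-overlapping clades per label that meet the
size and purity validity thresholds. The score itself is kept as metadata
only; validity is decided purely by clade size and purity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

from .taxonomy import TaxonomyTable
from .alignment_ops import Alignment

STATUS_ACCEPTED = "accepted"
REASON_NO_EUK = "no-eukaryotic-clade"
REASON_NO_PROK = "no-prokaryotic-clade"
REASON_HIGH_PARAPHYLY = "high-paraphyly"

DEFAULT_MIN_PROK_SIZE = 3
DEFAULT_MIN_EUK_SIZE = 5
DEFAULT_MIN_PURITY = 0.8
DEFAULT_MAX_EUK_CLADES = 3

# Eukaryotic clades are detected at domain level: a single "Eukaryota" group
# spanning many eukaryotic class labels (the class labels matter later, for
# the LECA scope check). Prokaryotic clades are detected per class label.
EUK_CLADE_LABEL = "Eukaryota"


def soft_lca_score(n_label_in_clade: int, clade_size: int,
                   total_label: int) -> float:
    """(n/clade_size)·(n/total_label): label purity times label scope.

    1.0 for a clade that contains all leaves of its label and nothing else;
    always ≤ purity, with equality exactly when the clade holds every leaf
    of the label.
    """
    if clade_size <= 0 or total_label <= 0:
        raise ValueError("clade_size and total_label must be positive")
    if not 1 <= n_label_in_clade <= min(clade_size, total_label):
        raise ValueError("n_label_in_clade out of range")
    return (n_label_in_clade / clade_size) * (n_label_in_clade / total_label)


@dataclass
class CladeCall:
    """One detected (near-)monophyletic clade of a single class label."""

    node: dendropy.Node
    label: str
    member_leaves: frozenset
    clade_size: int
    n_label: int
    score: float
    domain: str
    clade_id: str = ""

    @property
    def purity(self) -> float:
        return self.n_label / self.clade_size

    def to_json_dict(self) -> dict:
        return {
            "clade_id": self.clade_id,
            "label": self.label,
            "domain": self.domain,
            "clade_size": self.clade_size,
            "n_label": self.n_label,
            "purity": self.purity,
            "score": self.score,
            "member_leaves": sorted(self.member_leaves),
        }


@dataclass
class Epoc:
    """One assembled eukaryotic–prokaryotic orthologous cluster."""

    epoc_id: str
    alignment: Alignment | None
    tree: dendropy.Tree
    euk_clades: list = field(default_factory=list)
    prok_clades: list = field(default_factory=list)
    annotations: list = field(default_factory=list)
    status: str = STATUS_ACCEPTED
    reason: str = ""

    @property
    def accepted(self) -> bool:
        return self.status == STATUS_ACCEPTED


def _monophyletic_group_roots(tree: dendropy.Tree, label: str,
                              labels: dict) -> list[dendropy.Node]:
    """Maximal nodes whose entire leaf set carries ``label``."""
    pure: set[int] = set()
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            if labels[node.taxon.label] == label:
                pure.add(id(node))
        elif all(id(c) in pure for c in node.child_nodes()):
            pure.add(id(node))
    roots = []
    for node in tree.preorder_node_iter():
        if id(node) in pure and (
            node.parent_node is None or id(node.parent_node) not in pure
        ):
            roots.append(node)
    return roots


def detect_clades(
    tree: dendropy.Tree,
    taxonomy: TaxonomyTable,
    min_prok_size: int = DEFAULT_MIN_PROK_SIZE,
    min_euk_size: int = DEFAULT_MIN_EUK_SIZE,
    min_purity: float = DEFAULT_MIN_PURITY,
) -> list[CladeCall]:
    """Detect valid soft-LCA clades for every class label on the tree.

    For each label, every ancestor of each monophyletic group of that label
    is scored with ``soft_lca_score``; candidates are ranked by score and
    accepted greedily, skipping candidates that overlap an already accepted
    clade of the same label. Validity requires at least ``min_prok_size``
    (prokaryotes) or ``min_euk_size`` (eukaryotes) label-bearing sequences
    and purity strictly greater than ``min_purity``. Labels are processed
    independently, so clades of different labels may overlap (nested calls
    along one lineage are possible and resolved downstream).
    """
    leaf_labels: dict[str, str] = {}
    for leaf in tree.leaf_node_iter():
        name = leaf.taxon.label
        if name not in taxonomy:
            raise ValueError(f"leaf {name!r} has no taxonomy entry")
        leaf_labels[name] = (
            EUK_CLADE_LABEL if taxonomy.is_eukaryote(name)
            else taxonomy.label_of(name)
        )

    # leaf sets and per-label counts per node, one postorder pass
    leafset: dict[int, frozenset] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            leafset[id(node)] = frozenset([node.taxon.label])
        else:
            s = set()
            for c in node.child_nodes():
                s |= leafset[id(c)]
            leafset[id(node)] = frozenset(s)

    totals: dict[str, int] = {}
    for name, lab in leaf_labels.items():
        totals[lab] = totals.get(lab, 0) + 1

    calls: list[CladeCall] = []
    counter = 0
    for label in sorted(totals):
        total = totals[label]
        is_euk = label == EUK_CLADE_LABEL
        min_size = min_euk_size if is_euk else min_prok_size

        candidates: dict[int, CladeCall] = {}
        for group_root in _monophyletic_group_roots(tree, label, leaf_labels):
            node = group_root
            while node is not None:
                if id(node) not in candidates:
                    members = leafset[id(node)]
                    n_label = sum(
                        1 for m in members if leaf_labels[m] == label
                    )
                    candidates[id(node)] = CladeCall(
                        node=node,
                        label=label,
                        member_leaves=members,
                        clade_size=len(members),
                        n_label=n_label,
                        score=soft_lca_score(n_label, len(members), total),
                        domain="eukaryotic" if is_euk else "prokaryotic",
                    )
                node = node.parent_node

        ranked = sorted(
            candidates.values(),
            key=lambda c: (-c.score, -c.n_label, c.clade_size,
                           min(c.member_leaves)),
        )
        taken: set[str] = set()
        for cand in ranked:
            if cand.n_label < min_size or cand.purity <= min_purity:
                continue
            if cand.member_leaves & taken:
                continue
            cand.clade_id = f"c{counter}"
            counter += 1
            taken |= cand.member_leaves
            calls.append(cand)
    return calls


def assemble_epoc(
    tree: dendropy.Tree,
    alignment: Alignment | None,
    calls: list[CladeCall],
    epoc_id: str = "epoc",
    annotations=(),
    max_euk_clades: int = DEFAULT_MAX_EUK_CLADES,
) -> Epoc:
    """Assemble detected clades into an EPOC, or reject it.

    Rejection reasons: no valid eukaryotic clade, no valid prokaryotic
    clade, or more than ``max_euk_clades`` eukaryotic clades (high
    paraphyly).
    """
    euk = [c for c in calls if c.domain == "eukaryotic"]
    prok = [c for c in calls if c.domain == "prokaryotic"]
    epoc = Epoc(
        epoc_id=epoc_id, alignment=alignment, tree=tree,
        euk_clades=euk, prok_clades=prok, annotations=list(annotations),
    )
    if not euk:
        epoc.status, epoc.reason = "rejected", REASON_NO_EUK
    elif not prok:
        epoc.status, epoc.reason = "rejected", REASON_NO_PROK
    elif len(euk) > max_euk_clades:
        epoc.status, epoc.reason = "rejected", REASON_HIGH_PARAPHYLY
    return epoc
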