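"""Synthetic gene-family fixtures with a planted prokaryotic sister clade.

Generates labelled gene trees containing one eukaryotic clade attached by a
stem of known length to a chosen prokaryotic sister clade, protein alignments
evolved on those trees, and stem-length cohorts with planted group
differences. Every downstream stage of the pipeline is testable against the
recorded ground truth without any external data.

Within-clade topologies are pure-birth (Yule) trees scaled to a target
root-to-tip depth, with mild log-normal rate jitter per branch so trees are
not exactly ultrametric. Horizontally transferred leaves are emulated by
relabelling a prokaryotic leaf with an off-clade class label; long-branch
outliers by inflating a leaf's terminal branch by a fixed factor. All
randomness flows from a single integer seed through independent child
streams, so e.g. switching outliers on does not perturb the base tree.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import NamedTuple

import dendropy
import numpy as np

from .alignment_ops import Alignment, AMINO_ACIDS
from .subst_models import get_model
from .taxonomy import (
    TaxonomyTable,
    TaxonEntry,
    DOMAIN_EUK,
    DOMAIN_PROK,
    SUPERGROUP_AMORPHEA,
    SUPERGROUP_DIAPHORETICKES,
)

# Default eukaryotic class labels cycled over the eukaryotic leaves; the two
# supergroups are both represented so simulated clades pass the LECA scope
# check (>5 distinct labels, one from each supergroup) whenever the clade has
# at least 6 leaves.
EUK_LABEL_CYCLE: tuple[tuple[str, str], ...] = (
    ("Metazoa", SUPERGROUP_AMORPHEA),
    ("Streptophyta", SUPERGROUP_DIAPHORETICKES),
    ("Fungi", SUPERGROUP_AMORPHEA),
    ("Alveolata", SUPERGROUP_DIAPHORETICKES),
    ("Amoebozoa", SUPERGROUP_AMORPHEA),
    ("Stramenopila", SUPERGROUP_DIAPHORETICKES),
    ("Choanoflagellata", SUPERGROUP_AMORPHEA),
    ("Rhodophyta", SUPERGROUP_DIAPHORETICKES),
)

DEFAULT_PROK_CLADES: tuple[tuple[str, int], ...] = (
    ("Asgard", 7),
    ("Alphaproteobacteria", 7),
    ("Cyanobacteria", 6),
    ("Actinomycetota", 6),
)


@dataclass(frozen=True)
class SimConfig:
    """Conditions for one simulated gene family.

    Defaults give a 36-leaf tree (10 eukaryotes, four prokaryotic clades of
    6–7 leaves), a 0.3 substitutions/site stem, 300 alignment columns under
    the equal-rates model and no injected noise.
    """

    seed: int = 0
    n_euk_leaves: int = 10
    n_euk_clades: int = 1
    prok_clades: tuple[tuple[str, int], ...] = DEFAULT_PROK_CLADES
    true_sister: str = "Asgard"
    stem_length: float = 0.3
    euk_depth: float = 0.4
    prok_depth: float = 0.3
    clade_stem: float = 0.15
    backbone_length: float = 0.2
    n_sites: int = 300
    substitution_model: str = "eq20"
    hgt_leaf_count: int = 0
    outlier_count: int = 0
    outlier_factor: float = 10.0
    rate_jitter_sd: float = 0.25

    def __post_init__(self) -> None:
        labels = [lab for lab, _ in self.prok_clades]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate prokaryotic clade labels")
        if self.true_sister not in labels:
            raise ValueError("true_sister must be one of the prokaryotic clades")
        if self.n_euk_leaves < 1 or any(n < 1 for _, n in self.prok_clades):
            raise ValueError("every declared clade needs at least one leaf")
        if self.n_euk_clades < 1:
            raise ValueError("need at least one eukaryotic clade")
        if min(self.stem_length, self.euk_depth, self.prok_depth,
               self.n_sites) < 0:
            raise ValueError("lengths and counts must be non-negative")
        if self.hgt_leaf_count < 0 or self.outlier_count < 0:
            raise ValueError("noise counts must be non-negative")


@dataclass
class TruthRecord:
    """Planted ground truth for one simulated gene family."""

    epoc_id: str
    true_sister: str
    true_stem_length: float
    injected_outlier_leaves: set = field(default_factory=set)
    injected_hgt_leaves: set = field(default_factory=set)
    euk_leaves: set = field(default_factory=set)
    sister_leaves: set = field(default_factory=set)
    euk_clade_sets: list = field(default_factory=list)

    def to_json(self) -> str:
        d = asdict(self)
        for k in ("injected_outlier_leaves", "injected_hgt_leaves",
                  "euk_leaves", "sister_leaves"):
            d[k] = sorted(d[k])
        d["euk_clade_sets"] = [sorted(s) for s in self.euk_clade_sets]
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        d = json.loads(text)
        for k in ("injected_outlier_leaves", "injected_hgt_leaves",
                  "euk_leaves", "sister_leaves"):
            d[k] = set(d[k])
        d["euk_clade_sets"] = [set(s) for s in d.get("euk_clade_sets", [])]
        return cls(**d)


class EpocSim(NamedTuple):
    tree: dendropy.Tree
    alignment: Alignment
    truth: TruthRecord
    taxonomy: TaxonomyTable


# ---------------------------------------------------------------------------
# tree assembly
# ---------------------------------------------------------------------------

def _jitter(rng: np.random.Generator, sd: float) -> float:
    return float(np.exp(rng.normal(0.0, sd))) if sd > 0 else 1.0


def _yule_subtree(names: list[str], depth: float, rng: np.random.Generator,
                  jitter_sd: float) -> dendropy.Node:
    """Pure-birth subtree over ``names`` scaled to root-to-tip ``depth``."""
    n = len(names)
    if n == 1:
        node = dendropy.Node()
        node._leaf_name = names[0]
        node.edge.length = 0.0
        return node
    root = dendropy.Node()

    # simulate split times
    times = [0.0]
    t = 0.0
    for k in range(1, n):
        t += rng.exponential(1.0 / k)
        times.append(t)
    t_end = t + rng.exponential(1.0 / n)

    # grow lineages: each active lineage = (node, birth_time)
    active = [(root, 0.0)]
    for split_time in times[1:]:
        i = rng.integers(len(active))
        node, _ = active.pop(int(i))
        node._split_time = split_time
        left, right = dendropy.Node(), dendropy.Node()
        node.add_child(left)
        node.add_child(right)
        active.append((left, split_time))
        active.append((right, split_time))
    order = rng.permutation(len(active))
    for leaf_idx, (node, birth) in enumerate(active):
        node._leaf_name = names[int(order[leaf_idx])]
        node._birth = birth
    # assign branch lengths scaled so depth(root->tip) == depth
    scale = depth / t_end if t_end > 0 else 0.0

    def _assign(node, node_time):
        for ch in node.child_nodes():
            ch_time = getattr(ch, "_split_time", t_end)
            ch.edge.length = max(ch_time - node_time, 0.0) * scale \
                * _jitter(rng, jitter_sd)
            _assign(ch, ch_time)

    _assign(root, 0.0)
    return root


def simulate_epoc(config: SimConfig) -> EpocSim:
    """Simulate one gene family: tree, alignment, truth record, taxonomy.

    The tree contains one monophyletic eukaryotic clade attached as sister to
    the ``true_sister`` prokaryotic clade via a stem of ``stem_length``
    substitutions/site; the alignment has ``n_sites`` columns evolved along
    the tree under the configured model. Identical seeds give bit-identical
    output.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_tree, rng_aln, rng_noise = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )

    taxonomy_entries: dict[str, TaxonEntry] = {}

    # prokaryotic clades
    clade_roots: dict[str, dendropy.Node] = {}
    for label, count in config.prok_clades:
        names = [f"{label}_{i}" for i in range(count)]
        for name in names:
            taxonomy_entries[name] = TaxonEntry(
                domain=DOMAIN_PROK, class_label=label, species_id=f"sp_{name}"
            )
        clade_roots[label] = _yule_subtree(
            names, config.prok_depth, rng_tree, config.rate_jitter_sd
        )

    # eukaryotic clade(s): the first is the "real" one attached to the true
    # sister; any additional clades emulate paraphyly and attach elsewhere
    euk_clade_names: list[list[str]] = []
    euk_roots = []
    for c in range(config.n_euk_clades):
        prefix = "Euk" if config.n_euk_clades == 1 else f"Euk{c}"
        names = [f"{prefix}_{i}" for i in range(config.n_euk_leaves)]
        for i, name in enumerate(names):
            label, supergroup = EUK_LABEL_CYCLE[i % len(EUK_LABEL_CYCLE)]
            taxonomy_entries[name] = TaxonEntry(
                domain=DOMAIN_EUK, class_label=label,
                species_id=f"sp_{name}", supergroup=supergroup,
            )
        euk_clade_names.append(names)
        euk_roots.append(_yule_subtree(
            names, config.euk_depth, rng_tree, config.rate_jitter_sd
        ))
    euk_root = euk_roots[0]

    # backbone over prokaryotic clades, random join order
    labels = [lab for lab, _ in config.prok_clades]
    order = [labels[int(i)] for i in rng_tree.permutation(len(labels))]
    for lab in order:
        clade_roots[lab].edge.length = (
            config.clade_stem * _jitter(rng_tree, config.rate_jitter_sd)
        )
    current = clade_roots[order[0]]
    for lab in order[1:]:
        join = dendropy.Node()
        join.add_child(current)
        join.add_child(clade_roots[lab])
        if current.edge.length is None:
            current.edge.length = (
                config.backbone_length
                * _jitter(rng_tree, config.rate_jitter_sd)
            )
        join.edge.length = (
            config.backbone_length * _jitter(rng_tree, config.rate_jitter_sd)
        )
        current = join
    top = current
    top.edge.length = None

    # graft the eukaryotic clade onto the midpoint of the sister's stem
    sister_root = clade_roots[config.true_sister]
    parent = sister_root.parent_node
    stem = sister_root.edge.length or 0.0
    feca = dendropy.Node()
    if parent is None:  # single prokaryotic clade: join at top
        top2 = dendropy.Node()
        top2.add_child(feca)
        feca.edge.length = None
        top = top2
        feca.add_child(sister_root)
        sister_root.edge.length = stem if stem else config.clade_stem
    else:
        parent.remove_child(sister_root)
        parent.add_child(feca)
        feca.edge.length = stem / 2.0
        feca.add_child(sister_root)
        sister_root.edge.length = stem / 2.0
    euk_root.edge.length = config.stem_length
    feca.add_child(euk_root)

    # additional (paraphyly) clades attach to other prokaryotic clade stems
    if config.n_euk_clades > 1:
        hosts = [lab for lab in labels if lab != config.true_sister]
        if not hosts:
            raise ValueError(
                "paraphyletic simulation needs a second prokaryotic clade"
            )
        for c in range(1, config.n_euk_clades):
            host = clade_roots[hosts[(c - 1) % len(hosts)]]
            h_parent = host.parent_node
            h_len = host.edge.length or config.clade_stem
            junction = dendropy.Node()
            h_parent.remove_child(host)
            h_parent.add_child(junction)
            junction.edge.length = h_len / 2.0
            junction.add_child(host)
            host.edge.length = h_len / 2.0
            euk_roots[c].edge.length = config.stem_length
            junction.add_child(euk_roots[c])

    tree = dendropy.Tree()
    tree.seed_node = top
    tree.is_rooted = True
    ns = tree.taxon_namespace
    for leaf in tree.leaf_node_iter():
        taxon = ns.new_taxon(label=leaf._leaf_name)
        leaf.taxon = taxon

    truth = TruthRecord(
        epoc_id=f"sim{config.seed}",
        true_sister=config.true_sister,
        true_stem_length=config.stem_length,
        euk_leaves={n for names in euk_clade_names for n in names},
        sister_leaves={
            lf.taxon.label for lf in sister_root.leaf_iter()
        },
        euk_clade_sets=[set(names) for names in euk_clade_names],
    )

    # injected noise (dedicated stream: does not perturb the base tree)
    all_leaves = sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label)
    if config.outlier_count:
        picks = rng_noise.choice(
            len(all_leaves), size=config.outlier_count, replace=False
        )
        for i in picks:
            leaf = all_leaves[int(i)]
            leaf.edge.length = (leaf.edge.length or 0.0) * config.outlier_factor
            truth.injected_outlier_leaves.add(leaf.taxon.label)
    if config.hgt_leaf_count:
        prok_leaves = [
            lf for lf in all_leaves
            if taxonomy_entries[lf.taxon.label].domain == DOMAIN_PROK
        ]
        picks = rng_noise.choice(
            len(prok_leaves), size=min(config.hgt_leaf_count,
                                       len(prok_leaves)),
            replace=False,
        )
        for i in picks:
            leaf = prok_leaves[int(i)]
            name = leaf.taxon.label
            own = taxonomy_entries[name].class_label
            others = [lab for lab in labels if lab != own]
            new_label = others[int(rng_noise.integers(len(others)))]
            taxonomy_entries[name] = TaxonEntry(
                domain=DOMAIN_PROK, class_label=new_label,
                species_id=f"sp_{name}",
            )
            truth.injected_hgt_leaves.add(name)

    alignment = simulate_alignment(
        tree, config.n_sites, config.substitution_model, rng_aln
    )
    return EpocSim(tree, alignment, truth, TaxonomyTable(taxonomy_entries))


def simulate_alignment(tree: dendropy.Tree, n_sites: int, model_name: str,
                       rng: np.random.Generator) -> Alignment:
    """Evolve a gap-free protein alignment along a tree."""
    model = get_model(model_name)
    states: dict[int, np.ndarray] = {
        id(tree.seed_node): model.sample_stationary(n_sites, rng)
    }
    rows: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            pass
        else:
            parent_states = states[id(node.parent_node)]
            states[id(node)] = model.evolve(
                parent_states, node.edge.length or 0.0, rng
            )
        if node.is_leaf():
            seq = "".join(AMINO_ACIDS[s] for s in states[id(node)])
            rows[node.taxon.label] = seq
    return Alignment(rows)


# ---------------------------------------------------------------------------
# stem-length cohorts
# ---------------------------------------------------------------------------

_FAMILIES = {
    "normal": lambda rng, n, p: rng.normal(p[0], p[1], size=n),
    "lognormal": lambda rng, n, p: rng.lognormal(p[0], p[1], size=n),
    "uniform": lambda rng, n, p: rng.uniform(p[0], p[1], size=n),
    "exponential": lambda rng, n, p: rng.exponential(p[0], size=n),
    "gamma": lambda rng, n, p: rng.gamma(p[0], p[1], size=n),
}


def simulate_stem_cohort(n_per_group: int, nsl_dists: dict, seed: int = 0):
    """Sample normalized-stem-length records per group.

    ``nsl_dists`` maps group label → (family, params) with family one of
    normal, lognormal, uniform, exponential, gamma. Records carry the group
    label as their assigned sister taxon and a unit median branch length, so
    NSL equals the sampled value; draws are clipped at 0 (stem lengths are
    non-negative by definition).
    """
    from .aggregation_stats import StemRecord

    if n_per_group < 0:
        raise ValueError("n_per_group must be non-negative")
    rng = np.random.default_rng(seed)
    records = []
    for group in sorted(nsl_dists):
        family, params = nsl_dists[group]
        if family not in _FAMILIES:
            raise ValueError(f"unknown distribution family {family!r}")
        if not all(np.isfinite(params)):
            raise ValueError("distribution parameters must be finite")
        values = np.clip(_FAMILIES[family](rng, n_per_group, params), 0, None)
        for i, v in enumerate(values):
            records.append(
                StemRecord(
                    epoc_id=f"{group}_{i}", euk_clade_id="e0",
                    sister_label=group, sl=float(v), median_bl=1.0,
                )
            )
    return records
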