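import dendropy
import numpy as np
import pytest

from epoclib.taxonomy import (
    TaxonEntry,
    TaxonomyTable,
    DOMAIN_EUK,
    DOMAIN_PROK,
    SUPERGROUP_AMORPHEA,
    SUPERGROUP_DIAPHORETICKES,
)


def make_taxonomy(spec):
    """Build a TaxonomyTable from {seq_id: (domain, label[, supergroup])}."""
    entries = {}
    for seq_id, fields in spec.items():
        domain, label = fields[0], fields[1]
        supergroup = fields[2] if len(fields) > 2 else None
        entries[seq_id] = TaxonEntry(
            domain=domain, class_label=label, species_id=f"sp_{seq_id}",
            supergroup=supergroup,
        )
    return TaxonomyTable(entries)


def random_binary_tree(names, rng, bl=None):
    """Random rooted binary tree over ``names`` by successive joins."""
    if bl is None:
        bl = lambda r: float(r.exponential(0.1))
    ns = dendropy.TaxonNamespace()
    nodes = []
    for name in names:
        node = dendropy.Node()
        node.taxon = ns.new_taxon(label=name)
        node.edge.length = bl(rng)
        nodes.append(node)
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(int(j))
        a = nodes.pop(int(i))
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        parent.edge.length = bl(rng)
        nodes.append(parent)
    root = dendropy.Node()
    for node in nodes:
        root.add_child(node)
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = root
    tree.is_rooted = True
    return tree


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def prok_taxonomy_10species():
    """One prokaryotic class with 10 species, one eukaryotic with 5."""
    spec = {}
    for i in range(10):
        spec[f"b{i}"] = (DOMAIN_PROK, "Bacilli")
    for i in range(5):
        spec[f"e{i}"] = (DOMAIN_EUK, "Metazoa", SUPERGROUP_AMORPHEA)
    return make_taxonomy(spec)


EUK_SUPERGROUPS = {
    "Metazoa": SUPERGROUP_AMORPHEA,
    "Fungi": SUPERGROUP_AMORPHEA,
    "Amoebozoa": SUPERGROUP_AMORPHEA,
    "Choanoflagellata": SUPERGROUP_AMORPHEA,
    "Streptophyta": SUPERGROUP_DIAPHORETICKES,
    "Alveolata": SUPERGROUP_DIAPHORETICKES,
    "Stramenopila": SUPERGROUP_DIAPHORETICKES,
    "Rhodophyta": SUPERGROUP_DIAPHORETICKES,
}


def scope_taxonomy(labels):
    """Taxonomy with one eukaryotic sequence per class label."""
    spec = {}
    for i, lab in enumerate(labels):
        spec[f"s{i}"] = (DOMAIN_EUK, lab, EUK_SUPERGROUPS.get(lab, None))
    return make_taxonomy(spec)
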