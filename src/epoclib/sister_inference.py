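"""Constrained sister-clade hypothesis testing scored by ELW.

For each detected eukaryotic clade, the nearest prokaryotic clades (by
topological distance on the master tree) are enumerated as candidate
sisters. Each candidate defines a constrained topology — the eukaryotic
clade regrafted as the candidate's sibling, all other leaves untouched —
whose branch lengths are re-optimised and whose per-site log-likelihoods are
computed under the chosen substitution model. Hypotheses are compared with
Expected Likelihood Weights estimated by RELL: bootstrap alignment columns,
recompute each hypothesis's total log-likelihood from the fixed per-site
values, convert to normalised likelihood weights, and average over
replicates. ELWs sum to one over the candidate set and are read as the
confidence that a candidate is the true sister.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .alignment_ops import Alignment
from .clade_detection import CladeCall, Epoc
from .likelihood import TreeLikelihood
from .subst_models import SubstitutionModel, get_model
from .tree_ops import clone_tree, find_mrca, topo_distance

DEFAULT_MAX_CANDIDATES = 12
DEFAULT_N_BOOT = 1000

ELW_COLUMNS = ["epoc_id", "clade_id", "candidate_label", "elw"]


@dataclass
class SiteLLMatrix:
    """Per-site log-likelihoods (nats), one row per candidate hypothesis."""

    hypotheses: list          # candidate CladeCalls (or labels)
    site_ll: np.ndarray       # (n_hypotheses, n_sites)

    def __post_init__(self) -> None:
        self.site_ll = np.asarray(self.site_ll, dtype=float)
        if self.site_ll.ndim != 2 or self.site_ll.shape[0] < 1:
            raise ValueError("site_ll must be a (hypotheses x sites) matrix")
        if len(self.hypotheses) != self.site_ll.shape[0]:
            raise ValueError("hypothesis count does not match matrix rows")
        if not np.all(np.isfinite(self.site_ll)):
            raise ValueError("non-finite site log-likelihoods")

    def labels(self) -> list[str]:
        return [
            h.label if isinstance(h, CladeCall) else str(h)
            for h in self.hypotheses
        ]

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            self.site_ll,
            index=self.labels(),
            columns=[f"site_{i}" for i in range(self.site_ll.shape[1])],
        )
        df.to_csv(path, sep="\t", index_label="hypothesis")

    @classmethod
    def from_tsv(cls, path) -> "SiteLLMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), df.to_numpy())


def enumerate_hypotheses(
    epoc: Epoc,
    euk_clade: CladeCall,
    max_candidates: int = DEFAULT_MAX_CANDIDATES,
) -> list[CladeCall]:
    """Candidate prokaryotic sisters, nearest first.

    Prokaryotic clade calls are sorted by ascending topological distance
    from the eukaryotic clade root; ties broken by larger clade size, then
    lexical label. At most ``max_candidates`` are returned.
    """
    if not epoc.prok_clades:
        raise ValueError("EPOC has no prokaryotic clades")
    keyed = []
    for cand in epoc.prok_clades:
        d = topo_distance(epoc.tree, euk_clade.node, cand.node)
        keyed.append((d, -cand.clade_size, cand.label, cand))
    keyed.sort(key=lambda t: t[:3])
    return [cand for *_, cand in keyed[:max_candidates]]


def build_constrained_topology(
    master: dendropy.Tree,
    euk_clade: CladeCall,
    sister: CladeCall,
) -> dendropy.Tree:
    """Topology with the eukaryotic clade forced to be the candidate's sibling.

    The eukaryotic subtree is pruned from a clone of the master tree and
    regrafted onto the midpoint of the candidate sister's stem, preserving
    the internal arrangement of everything else; the leaf set is identical
    to the master's. Three groups are therefore enforced: the eukaryotic
    clade, the candidate sister, and all remaining leaves.
    """
    if euk_clade.member_leaves & sister.member_leaves:
        raise ValueError("eukaryotic and sister clades overlap")
    work = clone_tree(master)
    euk_node = find_mrca(work, euk_clade.member_leaves)
    if {lf.taxon.label for lf in euk_node.leaf_iter()} \
            != set(euk_clade.member_leaves):
        raise ValueError("eukaryotic clade is not monophyletic in master")
    stem = euk_node.edge.length or 0.0
    parent = euk_node.parent_node
    if parent is None:
        raise ValueError("cannot regraft the whole tree")
    parent.remove_child(euk_node)
    work.suppress_unifurcations()

    sister_node = find_mrca(work, sister.member_leaves)
    s_len = sister_node.edge.length or 0.0
    s_parent = sister_node.parent_node
    join = dendropy.Node()
    if s_parent is None:
        # candidate clade spans everything else: join above it
        join.add_child(sister_node)
        sister_node.edge.length = s_len
        work.seed_node = join
    else:
        s_parent.remove_child(sister_node)
        s_parent.add_child(join)
        join.edge.length = s_len / 2.0
        join.add_child(sister_node)
        sister_node.edge.length = s_len / 2.0
    euk_node.edge.length = stem if stem > 0 else 1e-3
    join.add_child(euk_node)
    return work


def rell_elw(
    matrix: SiteLLMatrix,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | np.random.Generator | None = 0,
) -> np.ndarray:
    """Expected Likelihood Weights by RELL bootstrap.

    Each replicate resamples site indices with replacement, totals every
    hypothesis's log-likelihood, and converts the totals to likelihood
    weights w_h = exp(LL_h − max)/Σexp(·); the ELW of a hypothesis is its
    mean weight over replicates. The returned vector sums to one.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    ll = matrix.site_ll
    n_hyp, n_sites = ll.shape
    if n_sites < 1:
        raise ValueError("need at least one site")
    if n_hyp == 1:
        return np.ones(1)
    counts = rng.multinomial(n_sites, np.full(n_sites, 1.0 / n_sites),
                             size=n_boot)
    totals = counts @ ll.T  # (n_boot, n_hyp)
    totals -= totals.max(axis=1, keepdims=True)
    w = np.exp(totals)
    w /= w.sum(axis=1, keepdims=True)
    return w.mean(axis=0)


def score_sisters(
    epoc: Epoc,
    model: SubstitutionModel | str = "eq20",
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    max_candidates: int = DEFAULT_MAX_CANDIDATES,
    optimize_branch_lengths: bool = True,
    sweeps: int = 2,
) -> tuple[pd.DataFrame, dict[str, SiteLLMatrix]]:
    """Score every (eukaryotic clade, candidate sister) pair of an EPOC.

    Returns the ELW table (epoc_id, clade_id, candidate_label, elw) and the
    per-clade site log-likelihood matrices.
    """
    if not epoc.accepted:
        raise ValueError(f"EPOC {epoc.epoc_id!r} was rejected ({epoc.reason})")
    if epoc.alignment is None:
        raise ValueError("EPOC has no alignment")
    if isinstance(model, str):
        model = get_model(model)
    rng = np.random.default_rng(seed)

    rows = []
    matrices: dict[str, SiteLLMatrix] = {}
    for euk in epoc.euk_clades:
        candidates = enumerate_hypotheses(epoc, euk, max_candidates)
        site_lls = []
        for cand in candidates:
            topo = build_constrained_topology(epoc.tree, euk, cand)
            engine = TreeLikelihood(topo, epoc.alignment, model)
            if optimize_branch_lengths:
                engine.optimize_branch_lengths(sweeps=sweeps)
            site_lls.append(engine.site_loglik())
        matrix = SiteLLMatrix(candidates, np.vstack(site_lls))
        matrices[euk.clade_id] = matrix
        elw = rell_elw(matrix, n_boot=n_boot, seed=rng)
        for cand, w in zip(candidates, elw):
            rows.append(
                {"epoc_id": epoc.epoc_id, "clade_id": euk.clade_id,
                 "candidate_label": cand.label, "elw": float(w)}
            )
    return pd.DataFrame(rows, columns=ELW_COLUMNS), matrices
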