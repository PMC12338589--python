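"""Per-site log-likelihoods on fixed trees via Felsenstein pruning.

Gaps (and ambiguous residues) are treated as missing data: their partial
likelihood is 1 for every state. Likelihoods are computed with per-node
per-site rescaling so deep trees do not underflow. Branch lengths of a fixed
topology can be re-optimised one edge at a time against cached inside/outside
partials (bounded scalar maximisation per edge, a few sweeps), which is the
desk-scale analogue of a constrained maximum-likelihood search.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar

import dendropy

from .alignment_ops import Alignment
from .subst_models import SubstitutionModel, N_STATES

_MIN_BL = 1e-9
_MAX_BL = 15.0


class TreeLikelihood:
    """Likelihood engine bound to one (tree, alignment, model) triple.

    The tree is used in place: ``optimize_branch_lengths`` mutates its edge
    lengths. Leaf taxon labels must be a subset of the alignment row ids.
    """

    def __init__(self, tree: dendropy.Tree, alignment: Alignment,
                 model: SubstitutionModel):
        self.tree = tree
        self.model = model
        self.n_sites = alignment.n_sites
        arr = alignment.to_array()
        row_index = {name: i for i, name in enumerate(alignment.ids())}

        self._leaf_partials: dict[int, np.ndarray] = {}
        for leaf in tree.leaf_node_iter():
            name = leaf.taxon.label
            if name not in row_index:
                raise ValueError(f"leaf {name!r} has no sequence")
            states = arr[row_index[name]]
            partial = np.zeros((N_STATES, self.n_sites))
            gap = states < 0
            partial[:, gap] = 1.0
            idx = np.flatnonzero(~gap)
            partial[states[idx], idx] = 1.0
            self._leaf_partials[id(leaf)] = partial

    # -- inside (downward) pass ---------------------------------------

    def _down_pass(self):
        down: dict[int, np.ndarray] = {}
        scale: dict[int, np.ndarray] = {}
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                down[id(node)] = self._leaf_partials[id(node)]
                scale[id(node)] = np.zeros(self.n_sites)
                continue
            partial = np.ones((N_STATES, self.n_sites))
            sc = np.zeros(self.n_sites)
            for child in node.child_nodes():
                p = self.model.transition_matrix(child.edge.length or 0.0)
                partial = partial * (p @ down[id(child)])
                sc = sc + scale[id(child)]
            m = partial.max(axis=0)
            safe = np.where(m > 0, m, 1.0)
            down[id(node)] = partial / safe
            scale[id(node)] = sc + np.log(safe, where=m > 0,
                                          out=np.full_like(m, -np.inf))
        return down, scale

    def site_loglik(self) -> np.ndarray:
        """Natural-log likelihood per alignment column."""
        down, scale = self._down_pass()
        root = self.tree.seed_node
        site_l = self.model.freqs @ down[id(root)]
        with np.errstate(divide="ignore"):
            return np.log(site_l) + scale[id(root)]

    def loglik(self) -> float:
        return float(self.site_loglik().sum())

    # -- per-edge optimisation -----------------------------------------

    def _msg(self, node, down, scale):
        """Message from a child subtree to its parent: P(t) @ inside."""
        p = self.model.transition_matrix(node.edge.length or 0.0)
        return p @ down[id(node)], scale[id(node)]

    def _refresh_down(self, node, down, scale):
        partial = np.ones((N_STATES, self.n_sites))
        sc = np.zeros(self.n_sites)
        for child in node.child_nodes():
            msg, msc = self._msg(child, down, scale)
            partial = partial * msg
            sc = sc + msc
        m = partial.max(axis=0)
        safe = np.where(m > 0, m, 1.0)
        down[id(node)] = partial / safe
        scale[id(node)] = sc + np.log(safe)

    def _outside_at(self, node, down, scale):
        """Partial of everything outside ``node``'s subtree, expressed at
        the parent end of its edge, with stationary frequencies included
        once. Computed fresh along the root-to-node path so it always
        reflects the current branch lengths."""
        path = [node]
        while path[-1].parent_node is not None:
            path.append(path[-1].parent_node)
        path.reverse()  # root ... node
        out = np.repeat(self.model.freqs[:, None], self.n_sites, axis=1)
        out_scale = np.zeros(self.n_sites)
        for parent, child in zip(path[:-1], path[1:]):
            if parent is not path[0]:
                p = self.model.transition_matrix(parent.edge.length or 0.0)
                out = p.T @ out
            for sib in parent.child_nodes():
                if sib is child:
                    continue
                msg, msc = self._msg(sib, down, scale)
                out = out * msg
                out_scale = out_scale + msc
            m = out.max(axis=0)
            safe = np.where(m > 0, m, 1.0)
            out = out / safe
            out_scale = out_scale + np.log(safe)
        return out, out_scale

    def optimize_branch_lengths(self, sweeps: int = 2, tol: float = 1e-4,
                                max_bl: float = _MAX_BL) -> float:
        """Re-optimise every branch length on the fixed topology.

        Edges are visited in preorder; each is maximised with a bounded
        scalar search against exact inside/outside partials (the inside
        partials along the path to the root are refreshed after every edge
        update, so the coordinate-wise optimisation is consistent). A
        second sweep refines the joint optimum. Returns the final
        log-likelihood.
        """
        down, scale = self._down_pass()
        for _ in range(max(1, sweeps)):
            for node in self.tree.preorder_node_iter():
                if node is self.tree.seed_node:
                    continue
                d = down[id(node)]
                d_scale = scale[id(node)]
                o, o_scale = self._outside_at(node, down, scale)
                base = d_scale + o_scale

                def negll(t):
                    p = self.model.transition_matrix(t)
                    site = np.einsum("xs,xy,ys->s", o, p, d)
                    with np.errstate(divide="ignore"):
                        return -float((np.log(site) + base).sum())

                res = minimize_scalar(
                    negll, bounds=(_MIN_BL, max_bl), method="bounded",
                    options={"xatol": tol},
                )
                if res.fun <= negll(node.edge.length or 0.0):
                    node.edge.length = float(res.x)
                # keep inside partials exact for subsequent edges
                parent = node.parent_node
                while parent is not None:
                    self._refresh_down(parent, down, scale)
                    parent = parent.parent_node
        return self.loglik()


def site_loglik(tree: dendropy.Tree, aln: Alignment,
                model: SubstitutionModel) -> np.ndarray:
    """Per-site log-likelihood (nats) of an alignment on a fixed tree."""
    return TreeLikelihood(tree, aln, model).site_loglik()
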