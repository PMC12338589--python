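"""Model/Results front end for single-gene-family ancestry inference.

``EpocAncestryModel`` is built from one gene tree, its protein alignment and
a taxonomy table; ``fit()`` runs the whole per-family pipeline — optional
taxonomy-aware subsampling and information trimming, log-normal outlier
pruning, weighted midpoint rooting, soft-LCA clade detection, EPOC assembly,
constrained sister-hypothesis scoring with RELL Expected Likelihood Weights
— and returns an ``EpocAncestryResults`` carrying the ELW estimates, the
per-clade stem-length records and the preprocessing diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aggregation_stats import StemRecord, stem_lengths, stem_records_to_df
from .alignment_ops import Alignment, trim_alignment
from .clade_detection import (
    DEFAULT_MAX_EUK_CLADES,
    DEFAULT_MIN_EUK_SIZE,
    DEFAULT_MIN_PROK_SIZE,
    DEFAULT_MIN_PURITY,
    Epoc,
    assemble_epoc,
    detect_clades,
)
from .sister_inference import (
    DEFAULT_MAX_CANDIDATES,
    DEFAULT_N_BOOT,
    score_sisters,
)
from .taxonomy import TaxonomyTable, DOMAIN_EUK
from .tree_ops import (
    PruneReport,
    clone_tree,
    load_tree,
    prune_branch_outliers,
    taxonomy_aware_subsample,
    weighted_midpoint_root,
)

DEFAULT_EUK_CAP = 30
DEFAULT_PROK_CAP = 70


@dataclass(frozen=True)
class FitOptions:
    """Stage parameters; defaults are the pipeline's standard constants."""

    euk_cap: int = DEFAULT_EUK_CAP
    prok_cap: int = DEFAULT_PROK_CAP
    trim_bits: float = 0.15
    ppf_upper: float = 0.995
    max_removed_frac: float = 0.30
    min_prok_size: int = DEFAULT_MIN_PROK_SIZE
    min_euk_size: int = DEFAULT_MIN_EUK_SIZE
    min_purity: float = DEFAULT_MIN_PURITY
    max_euk_clades: int = DEFAULT_MAX_EUK_CLADES
    max_candidates: int = DEFAULT_MAX_CANDIDATES
    n_boot: int = DEFAULT_N_BOOT
    optimize_branch_lengths: bool = True
    opt_sweeps: int = 2
    subsample: bool = True
    trim: bool = True


class EpocAncestryModel:
    """Ancestry inference for one eukaryotic gene family.

    Parameters
    ----------
    tree : dendropy.Tree
        Gene tree with branch lengths; leaf labels are sequence ids.
    alignment : Alignment
        Protein alignment covering every leaf.
    taxonomy : TaxonomyTable
        Curated labels for every leaf.
    epoc_id : str
    annotations : iterable of str
        Functional category labels attached to the family.
    model : str
        Substitution model identifier ('eq20' or 'empirical').
    """

    def __init__(self, tree, alignment: Alignment,
                 taxonomy: TaxonomyTable, *, epoc_id: str = "epoc",
                 annotations=(), model: str = "eq20",
                 options: FitOptions | None = None):
        self.tree = tree
        self.alignment = alignment
        self.taxonomy = taxonomy
        self.epoc_id = epoc_id
        self.annotations = list(annotations)
        self.model_name = model
        self.options = options or FitOptions()

    @classmethod
    def from_files(cls, tree_path, alignment_path, taxonomy_path,
                   **kwargs) -> "EpocAncestryModel":
        return cls(
            load_tree(tree_path),
            Alignment.from_fasta(alignment_path),
            TaxonomyTable.from_tsv(taxonomy_path),
            **kwargs,
        )

    # -- fitting -------------------------------------------------------

    def _cap_domain(self, tree, cap: int, domain: str):
        """Subsample one domain's leaves to ``cap`` without touching the
        other domain (its leaves get unique pseudo-labels so the label-aware
        pruning never collapses them)."""
        leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
        in_domain = [l for l in leaves if self.taxonomy[l].domain == domain]
        if len(in_domain) <= cap:
            return tree
        labels = {}
        protected = set()
        for name in leaves:
            if self.taxonomy[name].domain == domain:
                labels[name] = self.taxonomy.label_of(name)
            else:
                labels[name] = f"__keep__{name}"
                protected.add(name)
        target = len(leaves) - (len(in_domain) - cap)
        keep = taxonomy_aware_subsample(tree, self.taxonomy, target,
                                        labels=labels, protected=protected)
        pruned = clone_tree(tree)
        pruned.retain_taxa_with_labels(list(keep))
        return pruned

    def fit(self, seed: int = 0, **overrides) -> "EpocAncestryResults":
        """Run the full per-family pipeline.

        Keyword overrides replace individual ``FitOptions`` fields for this
        fit only. All randomness (RELL bootstrap) derives from ``seed``.
        """
        opts = (self.options if not overrides
                else FitOptions(**{**self.options.__dict__, **overrides}))

        tree = clone_tree(self.tree)
        if opts.subsample:
            tree = self._cap_domain(tree, opts.euk_cap, DOMAIN_EUK)
            tree = self._cap_domain(tree, opts.prok_cap, "prokaryote")
        leaf_set = {lf.taxon.label for lf in tree.leaf_node_iter()}
        aln = self.alignment.subset_rows(leaf_set)
        if opts.trim:
            aln = trim_alignment(aln, opts.trim_bits)

        tree, prune_report = prune_branch_outliers(
            tree, ppf_upper=opts.ppf_upper, taxonomy=self.taxonomy,
            max_removed_frac=opts.max_removed_frac,
        )
        if prune_report.discarded:
            epoc = Epoc(
                epoc_id=self.epoc_id, alignment=aln, tree=tree,
                annotations=self.annotations,
                status="rejected", reason=prune_report.discard_reason,
            )
            return EpocAncestryResults(self, epoc, prune_report,
                                       pd.DataFrame(), {}, [])
        if prune_report.removed_leaves:
            leaf_set -= prune_report.removed_leaves
            aln = aln.subset_rows(leaf_set)
        tree = weighted_midpoint_root(tree)

        calls = detect_clades(
            tree, self.taxonomy,
            min_prok_size=opts.min_prok_size,
            min_euk_size=opts.min_euk_size,
            min_purity=opts.min_purity,
        )
        epoc = assemble_epoc(
            tree, aln, calls, epoc_id=self.epoc_id,
            annotations=self.annotations,
            max_euk_clades=opts.max_euk_clades,
        )
        if not epoc.accepted:
            return EpocAncestryResults(self, epoc, prune_report,
                                       pd.DataFrame(), {}, [])

        elw, matrices = score_sisters(
            epoc, model=self.model_name, n_boot=opts.n_boot, seed=seed,
            max_candidates=opts.max_candidates,
            optimize_branch_lengths=opts.optimize_branch_lengths,
            sweeps=opts.opt_sweeps,
        )

        stems: list[StemRecord] = []
        for euk in epoc.euk_clades:
            sub = elw[elw["clade_id"] == euk.clade_id]
            if sub.empty:
                continue
            top_label = sub.loc[sub["elw"].idxmax(), "candidate_label"]
            sister = next(
                c for c in epoc.prok_clades if c.label == top_label
            )
            rec = stem_lengths(tree, euk, sister, epoc_id=self.epoc_id)
            if rec is not None:
                stems.append(rec)
        return EpocAncestryResults(self, epoc, prune_report, elw,
                                   matrices, stems)


class EpocAncestryResults:
    """Fitted ancestry inference for one gene family.

    Attributes
    ----------
    epoc : Epoc
        The assembled (or rejected) cluster with its clade calls.
    prune_report : PruneReport
        Outlier-pruning diagnostics.
    elw : pandas.DataFrame
        Columns epoc_id, clade_id, candidate_label, elw; ELWs sum to 1 per
        eukaryotic clade.
    stem_records : list of StemRecord
    """

    def __init__(self, model: EpocAncestryModel, epoc: Epoc,
                 prune_report: PruneReport, elw: pd.DataFrame,
                 site_ll_matrices: dict, stem_records: list):
        self.model = model
        self.epoc = epoc
        self.prune_report = prune_report
        self.elw = elw
        self.site_ll_matrices = site_ll_matrices
        self.stem_records = stem_records

    @property
    def accepted(self) -> bool:
        return self.epoc.accepted

    @property
    def status(self) -> str:
        return (self.epoc.status if self.epoc.accepted
                else f"{self.epoc.status}:{self.epoc.reason}")

    def top_sisters(self) -> pd.DataFrame:
        """Best candidate per eukaryotic clade with its ELW."""
        if self.elw.empty:
            return pd.DataFrame(
                columns=["epoc_id", "clade_id", "candidate_label", "elw"]
            )
        idx = self.elw.groupby("clade_id")["elw"].idxmax()
        return self.elw.loc[idx].reset_index(drop=True)

    def stem_table(self) -> pd.DataFrame:
        return stem_records_to_df(self.stem_records)

    def summary(self) -> str:
        e = self.epoc
        lines = [
            "EPOC ancestry inference",
            "=" * 56,
            f"family:            {e.epoc_id}",
            f"status:            {self.status}",
            f"substitution model:{self.model.model_name:>10}",
            f"leaves after prep: {sum(1 for _ in e.tree.leaf_node_iter())}",
            f"outliers removed:  {len(self.prune_report.removed_leaves)}"
            f" (cutoff {self.prune_report.upper_cutoff:.4g})",
            f"eukaryotic clades: {len(e.euk_clades)}"
            f"   prokaryotic clades: {len(e.prok_clades)}",
        ]
        if not self.elw.empty:
            lines.append("-" * 56)
            lines.append("Expected Likelihood Weights per candidate sister:")
            for clade_id, sub in self.elw.groupby("clade_id"):
                lines.append(f"  eukaryotic clade {clade_id}:")
                for row in sub.sort_values("elw", ascending=False) \
                        .itertuples(index=False):
                    lines.append(
                        f"    {row.candidate_label:<24}{row.elw:8.4f}"
                    )
        for rec in self.stem_records:
            lines.append(
                f"stem ({rec.euk_clade_id} -> {rec.sister_label}): "
                f"SL={rec.sl:.4f}  median BL={rec.median_bl:.4f}  "
                f"NSL={rec.nsl:.4f}"
            )
        return "\n".join(lines)
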