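"""Curated taxonomic labels, soft-core pangenome filtering and LECA-scope checks.

Every sequence in the analysis carries a curated class-level label (e.g.
``Asgard``, ``Alphaproteobacteria``, ``Metazoa``), a domain flag and, for
eukaryotes, an optional supergroup membership (``Amorphea`` or
``Diaphoretickes``) used to decide whether a eukaryotic clade plausibly spans
the last eukaryotic common ancestor.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass

import pandas as pd

DOMAIN_EUK = "eukaryote"
DOMAIN_PROK = "prokaryote"
SUPERGROUP_AMORPHEA = "Amorphea"
SUPERGROUP_DIAPHORETICKES = "Diaphoretickes"
SUPERGROUP_OTHER = "other"

_VALID_DOMAINS = frozenset({DOMAIN_EUK, DOMAIN_PROK})
_VALID_SUPERGROUPS = frozenset(
    {SUPERGROUP_AMORPHEA, SUPERGROUP_DIAPHORETICKES, SUPERGROUP_OTHER}
)


@dataclass(frozen=True)
class TaxonEntry:
    """Curated taxonomy for one sequence."""

    domain: str
    class_label: str
    species_id: str
    supergroup: str | None = None

    def __post_init__(self) -> None:
        if self.domain not in _VALID_DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r}")
        if self.domain == DOMAIN_PROK and self.supergroup is not None:
            raise ValueError("supergroup is only defined for eukaryotic entries")
        if self.supergroup is not None and self.supergroup not in _VALID_SUPERGROUPS:
            raise ValueError(f"unknown supergroup {self.supergroup!r}")


class TaxonomyTable:
    """Mapping from sequence id to curated taxonomy.

    The table is authoritative: species identity is the ``species_id`` column
    and supergroup membership is declared, never inferred.
    """

    def __init__(self, entries: Mapping[str, TaxonEntry]):
        if not entries:
            raise ValueError("empty taxonomy")
        self.entries: dict[str, TaxonEntry] = dict(entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self.entries

    def __getitem__(self, seq_id: str) -> TaxonEntry:
        try:
            return self.entries[seq_id]
        except KeyError:
            raise KeyError(f"unknown sequence id {seq_id!r}") from None

    def domain_of(self, seq_id: str) -> str:
        return self[seq_id].domain

    def label_of(self, seq_id: str) -> str:
        return self[seq_id].class_label

    def is_eukaryote(self, seq_id: str) -> bool:
        return self[seq_id].domain == DOMAIN_EUK

    def class_labels(self) -> set[str]:
        return {e.class_label for e in self.entries.values()}

    def supergroup_of_label(self, class_label: str) -> str:
        """Supergroup declared for a eukaryotic class label ('other' if unset)."""
        for entry in self.entries.values():
            if entry.class_label == class_label and entry.supergroup is not None:
                return entry.supergroup
        return SUPERGROUP_OTHER

    def species_of_label(self, class_label: str) -> set[str]:
        return {
            e.species_id
            for e in self.entries.values()
            if e.class_label == class_label
        }

    def sequences_of_label(self, class_label: str) -> set[str]:
        return {
            s for s, e in self.entries.items() if e.class_label == class_label
        }

    # -- IO ------------------------------------------------------------

    @classmethod
    def from_tsv(cls, path) -> "TaxonomyTable":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        required = {"seq_id", "domain", "class_label", "species_id", "supergroup"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"taxonomy TSV missing columns: {sorted(missing)}")
        entries = {}
        for row in df.itertuples(index=False):
            sg = row.supergroup or None
            if row.seq_id in entries:
                raise ValueError(f"duplicate sequence id {row.seq_id!r}")
            entries[row.seq_id] = TaxonEntry(
                domain=row.domain,
                class_label=row.class_label,
                species_id=row.species_id,
                supergroup=sg if row.domain == DOMAIN_EUK else None,
            )
        return cls(entries)

    def to_tsv(self, path) -> None:
        rows = [
            {
                "seq_id": s,
                "domain": e.domain,
                "class_label": e.class_label,
                "species_id": e.species_id,
                "supergroup": e.supergroup or "",
            }
            for s, e in self.entries.items()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


class ClusterTable:
    """Cluster-id → member sequence-ids, consumed from upstream clustering."""

    def __init__(self, clusters: Mapping[str, Iterable[str]]):
        self.clusters: dict[str, frozenset[str]] = {
            cid: frozenset(members) for cid, members in clusters.items()
        }
        for cid, members in self.clusters.items():
            if not members:
                raise ValueError(f"cluster {cid!r} is empty")

    def __len__(self) -> int:
        return len(self.clusters)

    def __getitem__(self, cid: str) -> frozenset[str]:
        return self.clusters[cid]

    def __iter__(self):
        return iter(self.clusters)

    @classmethod
    def from_tsv(cls, path) -> "ClusterTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"cluster_id", "seq_id"} <= set(df.columns):
            raise ValueError("cluster TSV requires columns cluster_id, seq_id")
        grouped = df.groupby("cluster_id")["seq_id"].apply(set)
        return cls(grouped.to_dict())

    def to_tsv(self, path) -> None:
        rows = [
            {"cluster_id": cid, "seq_id": s}
            for cid in sorted(self.clusters)
            for s in sorted(self.clusters[cid])
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def softcore_filter(
    clusters: ClusterTable,
    taxonomy: TaxonomyTable,
    prok_frac: float = 0.5,
    euk_frac: float = 0.2,
    mode: str = "species",
) -> ClusterTable:
    """Soft-core pangenome filter.

    Keeps exactly the clusters whose members cover at least ``prok_frac`` of
    the distinct species of their (prokaryotic) taxonomic group, or
    ``euk_frac`` for eukaryotic groups. Each cluster's members must all share
    one class label (clusters are built per taxonomic group upstream).

    ``mode="species"`` counts distinct ``species_id`` values (default);
    ``mode="sequences"`` counts member sequences against all sequences of the
    group.
    """
    for frac, name in ((prok_frac, "prok_frac"), (euk_frac, "euk_frac")):
        if not 0 < frac <= 1:
            raise ValueError(f"{name} must be in (0, 1], got {frac}")
    if mode not in ("species", "sequences"):
        raise ValueError(f"unknown mode {mode!r}")

    kept: dict[str, frozenset[str]] = {}
    for cid, members in clusters.clusters.items():
        labels = set()
        for seq_id in members:
            labels.add(taxonomy[seq_id].class_label)  # raises on unknown id
        if len(labels) != 1:
            raise ValueError(
                f"cluster {cid!r} spans multiple taxonomic groups: {sorted(labels)}"
            )
        label = labels.pop()
        domain = taxonomy[next(iter(members))].domain
        frac = euk_frac if domain == DOMAIN_EUK else prok_frac
        if mode == "species":
            covered = {taxonomy[s].species_id for s in members}
            total = taxonomy.species_of_label(label)
        else:
            covered = set(members)
            total = taxonomy.sequences_of_label(label)
        if total and len(covered) / len(total) >= frac:
            kept[cid] = members
    return ClusterTable(kept) if kept else _empty_cluster_table()


def _empty_cluster_table() -> ClusterTable:
    table = ClusterTable.__new__(ClusterTable)
    table.clusters = {}
    return table


def check_leca_scope(
    labels: Iterable[str],
    taxonomy: TaxonomyTable,
    min_labels: int = 5,
) -> bool:
    """Does a eukaryotic clade plausibly span the LECA?

    True iff the clade carries strictly more than ``min_labels`` distinct
    class labels, with at least one label from Amorphea and one from
    Diaphoretickes — the two deepest-branching eukaryotic supergroups, whose
    joint presence places the clade's ancestor at or before the first
    eukaryotic bifurcation.
    """
    distinct = set(labels)
    if len(distinct) <= min_labels:
        return False
    supergroups = {taxonomy.supergroup_of_label(lab) for lab in distinct}
    return (
        SUPERGROUP_AMORPHEA in supergroups
        and SUPERGROUP_DIAPHORETICKES in supergroups
    )
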