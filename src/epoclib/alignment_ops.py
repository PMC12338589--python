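"""Protein alignment container, per-column Shannon information and trimming.

Columns are scored as log2(20) minus the Shannon entropy of the amino-acid
frequency distribution among non-gap residues; low-information columns are
removed before tree building (0.15-bit threshold) or profile construction
(0.2-bit threshold).
"""

from __future__ import annotations

import math
import warnings
from collections.abc import Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
MAX_BITS = math.log2(20)

# Ambiguous/non-standard residues carry no usable frequency information and
# are treated as gaps.
_GAP_EQUIVALENT = set("-.*BZXUOJ")


class Alignment:
    """A protein multiple sequence alignment with uniquely named rows."""

    def __init__(self, rows: Mapping[str, str]):
        self.rows: dict[str, str] = {k: str(v).upper() for k, v in rows.items()}
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("alignment rows have unequal lengths")
        self.n_sites: int = lengths.pop() if lengths else 0

    def __len__(self) -> int:
        return len(self.rows)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self.rows

    def __getitem__(self, seq_id: str) -> str:
        return self.rows[seq_id]

    def ids(self) -> list[str]:
        return list(self.rows)

    def column(self, i: int) -> str:
        return "".join(s[i] for s in self.rows.values())

    def subset_rows(self, keep) -> "Alignment":
        keep = set(keep)
        return Alignment({k: v for k, v in self.rows.items() if k in keep})

    # -- IO ------------------------------------------------------------

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        rows = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in rows:
                raise ValueError(f"duplicate row id {rec.id!r}")
            rows[rec.id] = str(rec.seq)
        return cls(rows)

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.rows.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    def to_array(self) -> np.ndarray:
        """Integer-encoded alignment: residues 0..19, gap/ambiguous = -1."""
        arr = np.full((len(self.rows), self.n_sites), -1, dtype=np.int8)
        for r, seq in enumerate(self.rows.values()):
            for c, ch in enumerate(seq):
                arr[r, c] = _AA_INDEX.get(ch, -1)
        return arr


def column_information(column) -> float:
    """Shannon information of one alignment column, in bits.

    log2(20) − H(p) over the 20 amino-acid frequencies among non-gap
    residues; 0·log0 ≡ 0 and no pseudocounts. An all-gap column is defined
    as 0 bits (it is always trimmed).
    """
    if len(column) == 0:
        raise ValueError("empty column")
    counts = np.zeros(20)
    for ch in column:
        idx = _AA_INDEX.get(ch.upper())
        if idx is not None:
            counts[idx] += 1
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    entropy = -(p * np.log2(p)).sum()
    return float(MAX_BITS - entropy)


def _column_information_all(aln: Alignment) -> np.ndarray:
    arr = aln.to_array()
    n_sites = aln.n_sites
    bits = np.zeros(n_sites)
    for c in range(n_sites):
        col = arr[:, c]
        col = col[col >= 0]
        if col.size == 0:
            continue
        counts = np.bincount(col, minlength=20)
        p = counts[counts > 0] / col.size
        bits[c] = MAX_BITS + (p * np.log2(p)).sum()
    return bits


def trim_alignment(aln: Alignment, min_bits: float = 0.15) -> Alignment:
    """Drop columns whose information content is ≤ ``min_bits`` (strict keep).

    Column order and the row set are preserved. Returns an empty alignment
    (with a warning) if no column survives.
    """
    if min_bits < 0:
        raise ValueError("min_bits must be non-negative")
    bits = _column_information_all(aln)
    keep = np.flatnonzero(bits > min_bits)
    if keep.size == 0:
        warnings.warn("no columns exceed the information threshold", stacklevel=2)
        return Alignment({k: "" for k in aln.rows})
    return Alignment(
        {name: "".join(seq[i] for i in keep) for name, seq in aln.rows.items()}
    )
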