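"""Repeat-family consensus sequences and overlap-masked ORF counting.

Closely related element copies (e.g. yeast Ty retrotransposons) cannot be
quantified copy-by-copy from short reads; instead reads are mapped to a
family consensus built from a multiple alignment.  The two overlapping ORFs
(gag-like ORF-A and pol-like ORF-B, joined by a programmed +1 frameshift)
are counted separately with their overlap excluded, so each A-site is
attributed unambiguously.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import AlignIO

from .annotation import OffsetTable

__all__ = ["FamilyAlignment", "OrfPair", "FamilyCounts",
           "consensus_from_msa", "count_family"]

_ALPHABET = set("ACGTN-")


@dataclass
class FamilyAlignment:
    """A column-aligned family of sequences (gaps allowed)."""

    family_id: str
    ids: List[str]
    rows: List[str]

    def __post_init__(self) -> None:
        if len(self.rows) == 0:
            raise ValueError("alignment has no rows")
        ncol = len(self.rows[0])
        for rid, row in zip(self.ids, self.rows):
            if len(row) != ncol:
                raise ValueError(
                    f"ragged alignment: row {rid} has length {len(row)}, "
                    f"expected {ncol}"
                )
            bad = set(row.upper()) - _ALPHABET
            if bad:
                raise ValueError(f"row {rid} contains invalid symbols {sorted(bad)}")
        self.rows = [r.upper() for r in self.rows]

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @classmethod
    def from_fasta(cls, path, family_id: str = "family") -> "FamilyAlignment":
        aln = AlignIO.read(path, "fasta")
        return cls(family_id, [rec.id for rec in aln], [str(rec.seq) for rec in aln])


def consensus_from_msa(aln: FamilyAlignment, max_gap_frac: float = 0.5) -> str:
    """Majority-rule consensus of a column-aligned family.

    Columns with gap fraction above ``max_gap_frac`` are dropped; otherwise
    the modal non-gap base is emitted.  Ties break to the lexicographically
    smallest base, except that N never wins a tie against a concrete base.
    """
    if len(aln.rows) < 2:
        raise ValueError("consensus requires >= 2 aligned sequences")
    n_rows = len(aln.rows)
    out = []
    for col in range(aln.n_columns):
        column = [row[col] for row in aln.rows]
        n_gap = column.count("-")
        if n_gap / n_rows > max_gap_frac:
            continue
        counts = Counter(b for b in column if b != "-")
        top = max(counts.values())
        winners = sorted(b for b, c in counts.items() if c == top)
        concrete = [b for b in winners if b != "N"]
        out.append(concrete[0] if concrete else "N")
    return "".join(out)


@dataclass
class OrfPair:
    """Two 0-based half-open ORF intervals on a consensus transcript."""

    orf_a: Tuple[int, int]
    orf_b: Tuple[int, int]

    @property
    def overlap(self) -> Tuple[int, int]:
        lo = max(self.orf_a[0], self.orf_b[0])
        hi = min(self.orf_a[1], self.orf_b[1])
        return (lo, hi) if lo < hi else (lo, lo)


@dataclass
class FamilyCounts:
    """Per-sample A-site tallies over the ORF partition.

    Columns of ``table``: ``orf_a``, ``orf_b``, ``excluded_overlap``,
    ``outside``, ``no_offset_length``; they partition the input A-sites
    exactly (``conservation_ok`` asserts it).
    """

    table: pd.DataFrame
    n_reads: int

    def conservation_ok(self) -> bool:
        return int(self.table.to_numpy().sum()) == self.n_reads

    @property
    def totals(self) -> pd.Series:
        return self.table.sum(axis=0)


def count_family(
    reads: pd.DataFrame,
    orfs: OrfPair,
    offsets: OffsetTable,
    exclude_overlap: bool = True,
    transcript_id: Optional[str] = None,
    assay: str = "ribo",
) -> FamilyCounts:
    """Assign A-sites of reads on the family consensus to ORF-A / ORF-B.

    With ``exclude_overlap`` (the default) A-sites inside the ORF-A/ORF-B
    intersection are tallied as ``excluded_overlap`` and counted to neither
    ORF; without it, overlap A-sites are attributed to ORF-A.
    """
    sub = reads[reads["assay"] == assay]
    if transcript_id is not None:
        sub = sub[sub["transcript_id"] == transcript_id]
    n_reads = len(sub)
    known = sub["length"].isin(offsets.lengths)
    o0, o1 = orfs.overlap
    a0, a1 = orfs.orf_a
    b0, b1 = orfs.orf_b
    off = sub["length"].map(offsets.offsets).fillna(0).to_numpy(np.int64)
    site = sub["five_prime"].to_numpy(np.int64) + off
    kn = known.to_numpy(bool)
    in_overlap = (site >= o0) & (site < o1) & (o1 > o0)
    in_a = (site >= a0) & (site < a1)
    in_b = (site >= b0) & (site < b1)

    cat = np.full(n_reads, "outside", dtype=object)
    if exclude_overlap:
        cat[in_a & ~in_overlap] = "orf_a"
        cat[in_b & ~in_overlap] = "orf_b"
        cat[in_overlap] = "excluded_overlap"
    else:
        cat[in_b] = "orf_b"
        cat[in_a] = "orf_a"  # overlap resolves to ORF-A
    cat[~kn] = "no_offset_length"

    columns = ["orf_a", "orf_b", "excluded_overlap", "outside", "no_offset_length"]
    tab = (
        pd.DataFrame({"sample_id": sub["sample_id"].to_numpy(), "category": cat})
        .groupby(["sample_id", "category"])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=columns, fill_value=0)
    )
    return FamilyCounts(tab, n_reads)
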