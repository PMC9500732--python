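"""Transcript models and A-site offset tables.

All coordinates are 0-based, half-open, in transcript space.  A ``GeneModel``
is one transcript with CDS bounds; the CDS includes the stop codon, so
``cds_end - cds_start`` is divisible by 3 and the number of codons is
``(cds_end - cds_start) // 3`` (codon 0 is the start codon, the last codon
is the stop).  An ``OffsetTable`` maps footprint length to the distance from
the footprint's 5' end to the first nucleotide of the ribosomal A-site codon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Tuple

import pandas as pd

__all__ = [
    "GeneModel",
    "OffsetTable",
    "PAPER_RIBO_OFFSETS",
    "RNA_FRAGMENT_OFFSET",
    "AnnotationError",
]

#: Published A-site offsets for elongating yeast ribosome footprints,
#: keyed by footprint length in nt: 13 for 26 nt, 14 for 27 nt, 15 for
#: 21-22 and 28-29 nt, 16 for 30-31 nt.
PAPER_RIBO_OFFSETS: Mapping[int, int] = {
    21: 15,
    22: 15,
    26: 13,
    27: 14,
    28: 15,
    29: 15,
    30: 16,
    31: 16,
}

#: Fixed 5'-end offset applied to every RNA-Seq fragment.
RNA_FRAGMENT_OFFSET: int = 15


class AnnotationError(ValueError):
    """Raised for inconsistent transcript models or offset tables."""


@dataclass(frozen=True)
class GeneModel:
    """One transcript with CDS bounds in transcript coordinates.

    Parameters
    ----------
    gene_id : str
        Transcript/gene identifier.
    length : int
        Transcript length in nt.
    cds_start, cds_end : int
        0-based half-open CDS interval; ``cds_end - cds_start`` must be a
        positive multiple of 3 for coding transcripts.  Non-coding
        transcripts carry ``cds_start == cds_end == 0``.
    coding : bool
        ``False`` marks ncRNA-like transcripts removed before counting.
    intron : tuple of int, optional
        0-based half-open intron interval within the transcript (the
        annotation describes the unspliced form).
    family_id : str, optional
        Repeat-family label shared by near-identical element copies.
    """

    gene_id: str
    length: int
    cds_start: int = 0
    cds_end: int = 0
    coding: bool = True
    intron: Optional[Tuple[int, int]] = None
    family_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise AnnotationError(f"{self.gene_id}: non-positive length {self.length}")
        if self.coding:
            if not (0 <= self.cds_start < self.cds_end <= self.length):
                raise AnnotationError(
                    f"{self.gene_id}: CDS [{self.cds_start}, {self.cds_end}) "
                    f"outside transcript of length {self.length}"
                )
            if (self.cds_end - self.cds_start) % 3 != 0:
                raise AnnotationError(
                    f"{self.gene_id}: CDS length {self.cds_end - self.cds_start} "
                    "not divisible by 3"
                )
        if self.intron is not None:
            i0, i1 = self.intron
            if not (0 <= i0 < i1 <= self.length):
                raise AnnotationError(
                    f"{self.gene_id}: intron [{i0}, {i1}) outside transcript"
                )

    @property
    def n_codons(self) -> int:
        """Number of codons in the CDS, stop codon included."""
        return (self.cds_end - self.cds_start) // 3


@dataclass
class OffsetTable:
    """Map footprint length (nt) -> A-site offset (nt from the 5' end).

    ``provenance`` records whether the table holds the fixed published
    constants (``"fixed"``) or was inferred from a start-codon metagene
    peak (``"calibrated"``).
    """

    offsets: dict = field(default_factory=dict)
    provenance: str = "fixed"

    def __post_init__(self) -> None:
        for length, off in self.offsets.items():
            if not (0 < off < length):
                raise AnnotationError(
                    f"offset {off} for length {length} must lie in (0, length)"
                )

    @classmethod
    def paper(cls) -> "OffsetTable":
        """The published fixed offset table (lengths 21-22, 26-31 nt)."""
        return cls(dict(PAPER_RIBO_OFFSETS), provenance="fixed")

    def __contains__(self, length: int) -> bool:
        return length in self.offsets

    def __getitem__(self, length: int) -> int:
        return self.offsets[length]

    def get(self, length: int, default=None):
        return self.offsets.get(length, default)

    @property
    def lengths(self) -> list:
        return sorted(self.offsets)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "length": sorted(self.offsets),
                "offset": [self.offsets[k] for k in sorted(self.offsets)],
                "provenance": self.provenance,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "OffsetTable":
        df = pd.read_csv(path, sep="\t")
        prov = str(df["provenance"].iloc[0]) if "provenance" in df and len(df) else "fixed"
        return cls(
            {int(r.length): int(r.offset) for r in df.itertuples()}, provenance=prov
        )


def genes_to_frame(genes: Iterable[GeneModel]) -> pd.DataFrame:
    """Tabulate transcript models (one row per transcript)."""
    rows = []
    for g in genes:
        rows.append(
            {
                "transcript_id": g.gene_id,
                "length": g.length,
                "cds_start": g.cds_start,
                "cds_end": g.cds_end,
                "coding": g.coding,
                "intron_start": g.intron[0] if g.intron else None,
                "intron_end": g.intron[1] if g.intron else None,
                "family_id": g.family_id,
            }
        )
    return pd.DataFrame(rows)
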