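"""Gene x sample count matrices and special quantifications.

Counting rules: reads on non-coding transcripts are removed; each
remaining read is assigned an A-site ``site = five_prime + offset``
(length-dependent offsets for footprints, one fixed offset for RNA
fragments); the read counts toward a gene iff the site falls inside the
CDS outside the first and last ``exclude_codons`` codons.  Every input
read lands in exactly one accounting category, so the sidecar partitions
the input (checked by the conservation invariant).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import GeneModel, OffsetTable, RNA_FRAGMENT_OFFSET

__all__ = [
    "CountTable",
    "IntronCount",
    "filter_ncrna",
    "count_cds",
    "count_intron_reads",
    "frame_in_window",
]

logger = logging.getLogger("riboage.quantify")

SIDECAR_CATEGORIES = [
    "total",
    "ncrna_filtered",
    "no_offset_length",
    "outside_cds",
    "edge_codon_excluded",
    "counted",
]


@dataclass
class CountTable:
    """Gene x sample integer counts plus per-sample read accounting.

    ``counts`` is genes x samples; ``samples`` carries assay / condition /
    replicate labels indexed by sample id; ``sidecar`` is a per-sample
    DataFrame over the accounting categories (``total`` equals the sum of
    the other columns for every sample).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    sidecar: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("count matrix has negative entries")

    def accounting_consistent(self) -> bool:
        """True iff the sidecar categories partition input reads exactly."""
        if len(self.sidecar) == 0:
            return True
        parts = self.sidecar[SIDECAR_CATEGORIES[1:]].sum(axis=1)
        return bool((parts == self.sidecar["total"]).all())

    @staticmethod
    def concat(tables: Sequence["CountTable"]) -> "CountTable":
        """Column-wise merge of per-assay tables sharing the gene axis."""
        counts = pd.concat([t.counts for t in tables], axis=1)
        samples = pd.concat([t.samples for t in tables], axis=0)
        sidecar = pd.concat([t.sidecar for t in tables], axis=0)
        return CountTable(counts.fillna(0).astype(int), samples, sidecar)

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.columns = [
            f"{c}:{self.samples.loc[c, 'assay']}:{self.samples.loc[c, 'condition']}"
            for c in out.columns
        ]
        out.to_csv(path, sep="\t")


def filter_ncrna(
    reads: pd.DataFrame, genes: Iterable[GeneModel]
) -> Tuple[pd.DataFrame, int]:
    """Drop reads on non-coding transcripts; return (kept, n_removed)."""
    coding = {g.gene_id: g.coding for g in genes}
    unknown = sorted(set(reads["transcript_id"]) - set(coding))
    if unknown:
        raise KeyError(f"reads reference unknown transcripts: {unknown}")
    keep = reads["transcript_id"].map(coding).astype(bool)
    return reads[keep].reset_index(drop=True), int((~keep).sum())


def count_cds(
    reads: pd.DataFrame,
    genes: Sequence[GeneModel],
    offsets: OffsetTable,
    assay: str = "ribo",
    exclude_codons: int = 5,
    rna_offset: int = RNA_FRAGMENT_OFFSET,
    samples: Optional[pd.DataFrame] = None,
) -> CountTable:
    """Count A-sites per gene and sample for one assay.

    Footprints use the length-dependent ``offsets``; RNA fragments use the
    single fixed ``rna_offset`` regardless of length.  A read is counted
    for gene g iff ``cds_start <= site < cds_end`` and its codon index c
    (0-based) satisfies ``exclude_codons <= c <= n_codons-1-exclude_codons``;
    otherwise it increments the matching sidecar category.
    """
    if exclude_codons < 0:
        raise ValueError("exclude_codons must be >= 0")
    coding_genes = [g for g in genes if g.coding]
    for g in coding_genes:
        if g.n_codons < 2 * exclude_codons + 1:
            logger.warning(
                "%s: CDS of %d codons shorter than 2*%d+1; all reads excluded",
                g.gene_id, g.n_codons, exclude_codons,
            )
    gene_ids = [g.gene_id for g in coding_genes]
    sub = reads[reads["assay"] == assay]
    if samples is None:
        sample_ids = sorted(sub["sample_id"].unique())
        samples = pd.DataFrame(
            {"assay": assay, "condition": "", "replicate": 0},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    else:
        samples = samples[samples["assay"] == assay]
        sample_ids = list(samples.index)

    coding = {g.gene_id: g.coding for g in genes}
    unknown = sorted(set(sub["transcript_id"]) - set(coding))
    if unknown:
        raise KeyError(f"reads reference unknown transcripts: {unknown}")

    n = len(sub)
    if n == 0:
        counts = pd.DataFrame(
            0, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids
        )
        sidecar = pd.DataFrame(
            0, index=pd.Index(sample_ids, name="sample_id"), columns=SIDECAR_CATEGORIES
        )
        return CountTable(counts, samples, sidecar)

    starts = {g.gene_id: g.cds_start for g in coding_genes}
    ends = {g.gene_id: g.cds_end for g in coding_genes}
    tid = sub["transcript_id"]
    is_coding = tid.map(coding).to_numpy(bool)
    if assay == "rna":
        off = np.full(n, rna_offset, dtype=np.int64)
        has_off = np.ones(n, dtype=bool)
    else:
        off_s = sub["length"].map(offsets.offsets)
        has_off = off_s.notna().to_numpy()
        off = off_s.fillna(0).to_numpy(np.int64)
    site = sub["five_prime"].to_numpy(np.int64) + off
    cs = tid.map(starts).fillna(0).to_numpy(np.int64)
    ce = tid.map(ends).fillna(0).to_numpy(np.int64)
    in_cds = (site >= cs) & (site < ce)
    codon = (site - cs) // 3
    n_codons = (ce - cs) // 3
    interior = (codon >= exclude_codons) & (codon <= n_codons - 1 - exclude_codons)

    # category resolution order: ncRNA, missing offset, outside CDS, edge, counted
    cat = np.full(n, "counted", dtype=object)
    cat[~(in_cds & interior)] = "edge_codon_excluded"
    cat[~in_cds] = "outside_cds"
    cat[~has_off] = "no_offset_length"
    cat[~is_coding] = "ncrna_filtered"

    frame = pd.DataFrame(
        {
            "gene_id": tid.to_numpy(),
            "sample_id": sub["sample_id"].to_numpy(),
            "category": cat,
        }
    )
    counted = frame[frame["category"] == "counted"]
    counts = (
        counted.groupby(["gene_id", "sample_id"])
        .size()
        .unstack(fill_value=0)
        .reindex(index=gene_ids, columns=sample_ids, fill_value=0)
        .astype(int)
    )
    counts.index.name = "gene_id"
    sidecar = (
        frame.groupby(["sample_id", "category"])
        .size()
        .unstack(fill_value=0)
        .reindex(index=sample_ids, columns=SIDECAR_CATEGORIES[1:], fill_value=0)
    )
    sidecar.insert(0, "total", sidecar.sum(axis=1))
    sidecar.index.name = "sample_id"
    return CountTable(counts, samples, sidecar)


@dataclass
class IntronCount:
    """Per-sample tallies for one intron-containing gene.

    ``table`` has one row per sample with columns ``intron_containing``
    (reads overlapping or contained in the intron and not flagged as
    junction reads) and ``junction_spanning`` (reads from the spliced
    template crossing the excision point).
    """

    gene_id: str
    table: pd.DataFrame
    mode: str = "overlap"


def count_intron_reads(
    reads: pd.DataFrame, gene: GeneModel, mode: str = "overlap"
) -> IntronCount:
    """Count intron-containing and junction-spanning reads for one gene.

    ``mode="overlap"`` counts any read whose half-open interval overlaps
    the intron by >= 1 nt; ``mode="contained"`` requires the read to lie
    entirely inside the intron.
    """
    if gene.intron is None:
        raise ValueError(f"{gene.gene_id} has no annotated intron")
    if mode not in ("overlap", "contained"):
        raise ValueError(f"mode must be 'overlap' or 'contained', got {mode!r}")
    i0, i1 = gene.intron
    sub = reads[reads["transcript_id"] == gene.gene_id]
    fp = sub["five_prime"].to_numpy(np.int64)
    end = fp + sub["length"].to_numpy(np.int64)
    spans = sub["spans_intron_junction"].to_numpy(bool)
    if mode == "overlap":
        hits = (fp < i1) & (end > i0) & ~spans
    else:
        hits = (fp >= i0) & (end <= i1) & ~spans
    tab = (
        pd.DataFrame(
            {
                "sample_id": sub["sample_id"].to_numpy(),
                "intron_containing": hits.astype(int),
                "junction_spanning": spans.astype(int),
            }
        )
        .groupby("sample_id")
        .sum()
    )
    return IntronCount(gene.gene_id, tab, mode)


def frame_in_window(
    reads: pd.DataFrame,
    gene: GeneModel,
    offsets: OffsetTable,
    window: Tuple[int, int],
    anchor: Optional[int] = None,
) -> pd.Series:
    """A-site frame fractions within a transcript window.

    Frames are computed relative to ``anchor`` (default: the gene's CDS
    start, i.e. ORF-A's frame for element transcripts), so a +1 programmed
    frameshift shows up as dominant frame 1 downstream of the shift site.
    Returns a Series with ``frame0..frame2`` fractions and ``n``.
    """
    w0, w1 = window
    if w0 >= w1:
        raise ValueError(f"empty window {window}")
    if not (0 <= w0 and w1 <= gene.length):
        raise ValueError(f"window {window} outside transcript of length {gene.length}")
    if anchor is None:
        anchor = gene.cds_start
    sub = reads[
        (reads["transcript_id"] == gene.gene_id) & (reads["assay"] == "ribo")
    ]
    sub = sub[sub["length"].isin(offsets.lengths)]
    off = sub["length"].map(offsets.offsets).to_numpy(np.int64)
    site = sub["five_prime"].to_numpy(np.int64) + off
    inside = (site >= w0) & (site < w1)
    frames = (site[inside] - anchor) % 3
    n = int(inside.sum())
    frac = [float((frames == k).sum()) / n if n else float("nan") for k in range(3)]
    return pd.Series(
        {"frame0": frac[0], "frame1": frac[1], "frame2": frac[2], "n": n}
    )
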