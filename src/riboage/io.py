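"""Readers and writers for the package's on-disk formats.

Transcript sequences travel as FASTA (Biopython), annotation as either a
BED-like TSV (columns: transcript_id, length, cds_start, cds_end,
coding_flag, intron_start, intron_end, family_id; 0-based half-open, "."
for absent fields) or GFF3, reads as a documented TSV dialect or SAM in
transcript space (pysam; POS is 1-based per the SAM spec), and the truth /
offset / count tables as plain TSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import GeneModel
from .simulate import READ_COLUMNS, empty_reads

__all__ = [
    "write_fasta", "read_fasta",
    "write_annotation_tsv", "read_annotation_tsv",
    "write_gff3", "read_gff3",
    "write_reads_tsv", "read_reads_tsv",
    "write_reads_sam", "read_reads_sam",
    "write_truth_tsv", "read_truth_tsv",
]


# -- sequences --------------------------------------------------------------

def write_fasta(sequences: Dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# -- annotation -------------------------------------------------------------

_ANN_COLS = [
    "transcript_id", "length", "cds_start", "cds_end", "coding_flag",
    "intron_start", "intron_end", "family_id",
]


def write_annotation_tsv(genes: Iterable[GeneModel], path) -> None:
    rows = []
    for g in genes:
        rows.append(
            [
                g.gene_id, g.length, g.cds_start, g.cds_end,
                1 if g.coding else 0,
                g.intron[0] if g.intron else ".",
                g.intron[1] if g.intron else ".",
                g.family_id if g.family_id else ".",
            ]
        )
    pd.DataFrame(rows, columns=_ANN_COLS).to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path) -> List[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    genes = []
    for r in df.itertuples():
        intron = None
        if r.intron_start != "." and not pd.isna(r.intron_start):
            intron = (int(r.intron_start), int(r.intron_end))
        genes.append(
            GeneModel(
                gene_id=str(r.transcript_id),
                length=int(r.length),
                cds_start=int(r.cds_start),
                cds_end=int(r.cds_end),
                coding=bool(int(r.coding_flag)),
                intron=intron,
                family_id=None if r.family_id in (".", None) or pd.isna(r.family_id)
                else str(r.family_id),
            )
        )
    return genes


def write_gff3(genes: Iterable[GeneModel], path) -> None:
    """GFF3 in transcript space: one region + mRNA/ncRNA, CDS and intron."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = [f"ID={g.gene_id}"]
            if g.family_id:
                attrs.append(f"family_id={g.family_id}")
            kind = "mRNA" if g.coding else "ncRNA"
            fh.write(
                f"{g.gene_id}\triboage\t{kind}\t1\t{g.length}\t.\t+\t.\t"
                + ";".join(attrs) + "\n"
            )
            if g.coding:
                fh.write(
                    f"{g.gene_id}\triboage\tCDS\t{g.cds_start + 1}\t{g.cds_end}"
                    f"\t.\t+\t0\tID={g.gene_id}.cds;Parent={g.gene_id}\n"
                )
            if g.intron:
                fh.write(
                    f"{g.gene_id}\triboage\tintron\t{g.intron[0] + 1}\t{g.intron[1]}"
                    f"\t.\t+\t.\tID={g.gene_id}.intron;Parent={g.gene_id}\n"
                )


def read_gff3(path) -> List[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for feat in db.all_features(featuretype=("mRNA", "ncRNA")):
        cds = list(db.children(feat, featuretype="CDS"))
        intron = list(db.children(feat, featuretype="intron"))
        fam = feat.attributes.get("family_id", [None])[0]
        genes.append(
            GeneModel(
                gene_id=feat.id,
                length=feat.end,
                cds_start=cds[0].start - 1 if cds else 0,
                cds_end=cds[0].end if cds else 0,
                coding=feat.featuretype == "mRNA",
                intron=(intron[0].start - 1, intron[0].end) if intron else None,
                family_id=fam,
            )
        )
    return genes


# -- reads ------------------------------------------------------------------

def write_reads_tsv(reads: pd.DataFrame, path) -> None:
    reads[READ_COLUMNS].to_csv(path, sep="\t", index=False)


def read_reads_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if len(df) == 0:
        return empty_reads()
    df["spans_intron_junction"] = df["spans_intron_junction"].astype(bool)
    return df[READ_COLUMNS]


def write_reads_sam(
    reads: pd.DataFrame,
    genes: Iterable[GeneModel],
    path,
    sequences: Optional[Dict[str, str]] = None,
) -> None:
    """Emit reads as transcript-space SAM (POS 1-based, CIGAR fully matched).

    Read sequences are sliced from ``sequences`` when given, else '*'.
    The sample and assay travel in the RG tag (``sample:assay``); junction
    flags in the custom ``XJ`` tag.
    """
    genes = list(genes)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": g.gene_id, "LN": g.length} for g in genes],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        tid_index = {g.gene_id: i for i, g in enumerate(genes)}
        for i, row in enumerate(reads.itertuples()):
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"read{i + 1}"
            a.reference_id = tid_index[row.transcript_id]
            a.reference_start = int(row.five_prime)
            a.cigarstring = f"{int(row.length)}M"
            a.mapping_quality = 255
            if sequences and row.transcript_id in sequences:
                seq = sequences[row.transcript_id]
                a.query_sequence = seq[
                    int(row.five_prime): int(row.five_prime) + int(row.length)
                ]
            a.set_tag("RG", f"{row.sample_id}:{row.assay}")
            a.set_tag("XJ", 1 if row.spans_intron_junction else 0)
            out.write(a)


def read_reads_sam(path) -> pd.DataFrame:
    rows = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for a in fh:
            sample, assay = (a.get_tag("RG") if a.has_tag("RG") else "s1:ribo").split(":")
            rows.append(
                {
                    "transcript_id": a.reference_name,
                    "five_prime": a.reference_start,
                    "length": a.query_length or a.infer_query_length(),
                    "sample_id": sample,
                    "assay": assay,
                    "spans_intron_junction": bool(a.get_tag("XJ"))
                    if a.has_tag("XJ") else False,
                }
            )
    if not rows:
        return empty_reads()
    return pd.DataFrame(rows, columns=READ_COLUMNS)


# -- tables -----------------------------------------------------------------

def write_truth_tsv(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t")


def read_truth_tsv(path) -> pd.DataFrame:
    # "null" is a class label, not a missing value
    return pd.read_csv(path, sep="\t", index_col="gene_id",
                       keep_default_na=False, na_values=[""])
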