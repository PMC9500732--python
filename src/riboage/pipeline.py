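"""End-to-end orchestration: simulate -> QC -> calibrate -> count -> TE ->
classify -> enrich -> report.

``run_pipeline`` executes the stages against either a simulation config or
on-disk inputs, writes every stage artifact into the output directory, and
returns a JSON-serializable run report (stage-by-stage read accounting,
the offset table used, classification tallies, enrichment head).  The run
is deterministic given the config and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .annotation import OffsetTable
from .config import SimConfig
from .consensus import OrfPair, count_family
from .enrichment import enrich, read_terms_tsv
from .qc import calibrate_offsets, frame_report, length_histogram, metagene_profile
from .quantify import CountTable, count_cds, count_intron_reads
from .simulate import simulate_dataset
from .te import TranslationalEfficiencyModel

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("riboage.pipeline")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``simulate`` (a SimConfig) or the triplet of input paths
    (``annotation``, ``reads``, optionally ``transcripts``) must be given.
    ``offsets_source`` is ``"paper"`` (the fixed published table) or
    ``"calibrate"`` (infer from the start-codon metagene).
    """

    outdir: str = "riboage_run"
    simulate: Optional[SimConfig] = None
    annotation: Optional[str] = None
    reads: Optional[str] = None
    transcripts: Optional[str] = None
    terms: Optional[str] = None
    offsets_source: str = "calibrate"
    reference_condition: Optional[str] = None
    lfc_threshold: float = 1.0
    fdr_threshold: float = 0.05
    exclude_codons: int = 5
    min_reads_calibration: int = 500
    search_window: tuple = (-18, -6)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if d.get("simulate") is not None:
            sim = dict(d["simulate"])
            sim.setdefault("seed", d.get("seed", 0))
            d["simulate"] = SimConfig.from_dict(sim)
        if "search_window" in d:
            d["search_window"] = tuple(d["search_window"])
        return cls(**d)

    def validate(self) -> None:
        if self.simulate is None:
            for name in ("annotation", "reads"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(
                        f"run config needs either a simulate block or a {name} path"
                    )
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name} path does not exist: {p}")
        if self.offsets_source not in ("paper", "calibrate"):
            raise ValueError("offsets_source must be 'paper' or 'calibrate'")
        if self.terms is not None and not Path(self.terms).exists():
            raise FileNotFoundError(f"terms path does not exist: {self.terms}")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the run report (also written to disk)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}

    # -- stage: inputs ----------------------------------------------------
    if config.simulate is not None:
        ds = simulate_dataset(config.simulate)
        genes, reads, samples = ds.genes, ds.reads, ds.samples
        rio.write_fasta(ds.sequences, outdir / "transcripts.fa")
        rio.write_annotation_tsv(genes, outdir / "annotation.tsv")
        rio.write_truth_tsv(ds.truth, outdir / "truth.tsv")
        rio.write_reads_tsv(reads, outdir / "reads.tsv")
        samples.to_csv(outdir / "samples.tsv", sep="\t")
        conditions = list(ds.config.conditions)
        report["stages"]["simulate"] = {
            "n_genes": len(genes),
            "n_reads": int(len(reads)),
            "n_samples": int(len(samples)),
        }
    else:
        genes = rio.read_annotation_tsv(config.annotation)
        reads = rio.read_reads_tsv(config.reads)
        samples = (
            reads[["sample_id", "assay"]]
            .drop_duplicates()
            .set_index("sample_id")
            .assign(replicate=0)
        )
        # condition inferred from sample id "assay_condition_rN" when possible
        samples["condition"] = [
            sid.split("_")[1] if len(sid.split("_")) >= 3 else "all"
            for sid in samples.index
        ]
        conditions = list(dict.fromkeys(samples["condition"]))
        report["stages"]["load"] = {
            "n_genes": len(genes),
            "n_reads": int(len(reads)),
        }

    ribo_reads = reads[reads["assay"] == "ribo"]

    # -- stage: qc --------------------------------------------------------
    hist = length_histogram(ribo_reads)
    pd.Series(hist, name="count").rename_axis("length").to_csv(
        outdir / "length_histogram.tsv", sep="\t"
    )
    profile = metagene_profile(ribo_reads, genes, anchor="start", window=(-30, 33))
    profile.to_tsv(outdir / "metagene_start.tsv")
    report["stages"]["qc"] = {
        "length_histogram": hist,
        "metagene_reads_in_window": profile.n_in_window,
        "metagene_reads_out_window": profile.n_out_window,
    }

    # -- stage: offsets ---------------------------------------------------
    if config.offsets_source == "paper":
        offsets = OffsetTable.paper()
    else:
        offsets = calibrate_offsets(
            profile,
            search_window=config.search_window,
            min_reads=config.min_reads_calibration,
        )
    offsets.to_tsv(outdir / "offsets.tsv")
    report["stages"]["offsets"] = {
        "provenance": offsets.provenance,
        "table": dict(offsets.offsets),
    }

    frames = frame_report(ribo_reads, genes, offsets)
    if not frames.empty:
        frames.to_frame().to_csv(outdir / "frame_report.tsv", sep="\t", index=False)
        report["stages"]["frames"] = {
            "frame0": frames.overall[0],
            "n": frames.n,
        }

    # -- stage: counting --------------------------------------------------
    tables: List[CountTable] = []
    for assay in ("ribo", "rna"):
        tables.append(
            count_cds(
                reads, genes, offsets, assay=assay,
                exclude_codons=config.exclude_codons,
                samples=samples if "condition" in samples else None,
            )
        )
    table = CountTable.concat(tables)
    table.to_tsv(outdir / "counts.tsv")
    table.sidecar.to_json(outdir / "count_sidecar.json", orient="index")
    report["stages"]["count"] = {
        "accounting_consistent": table.accounting_consistent(),
        "sidecar_totals": {
            c: int(table.sidecar[c].sum()) for c in table.sidecar.columns
        },
    }

    intron_genes = [g for g in genes if g.intron is not None]
    if intron_genes:
        ic = count_intron_reads(reads[reads["assay"] == "rna"], intron_genes[0])
        ic.table.to_csv(outdir / "intron_counts.tsv", sep="\t")
        report["stages"]["intron"] = {
            "gene": ic.gene_id,
            "intron_containing": int(ic.table["intron_containing"].sum()),
            "junction_spanning": int(ic.table["junction_spanning"].sum()),
        }

    family_genes = [g for g in genes if g.family_id is not None]
    if family_genes and config.simulate is not None and config.simulate.element_family:
        fam = config.simulate.element_family
        orfs = OrfPair(tuple(fam.orf_a), tuple(fam.orf_b))
        fam_reads = reads[reads["transcript_id"].isin(
            [g.gene_id for g in family_genes]
        )]
        fc = count_family(fam_reads, orfs, offsets)
        fc.table.to_csv(outdir / "family_counts.tsv", sep="\t")
        report["stages"]["family"] = {
            k: int(v) for k, v in fc.totals.items()
        }

    # -- stage: TE --------------------------------------------------------
    te_tallies = {}
    up_genes: List[str] = []
    background: List[str] = list(table.counts.index)
    reference = config.reference_condition or conditions[0]
    if len(conditions) >= 2 and {"ribo", "rna"} <= set(samples["assay"]):
        for cond in conditions:
            if cond == reference:
                continue
            model = TranslationalEfficiencyModel.from_count_table(
                table, reference, cond
            )
            res = model.fit(lfc_threshold=config.lfc_threshold)
            res.to_tsv(outdir / f"te_{cond}_vs_{reference}.tsv")
            te_tallies[cond] = res.tally
            if not up_genes:
                cls = res.table["class"]
                up_genes = list(cls.index[cls == "up"])
        report["stages"]["te"] = {"reference": reference, "tallies": te_tallies}

    # -- stage: enrichment ------------------------------------------------
    if config.terms is not None and up_genes:
        terms = read_terms_tsv(config.terms)
        rows = enrich(up_genes, background, terms)
        rows.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        report["stages"]["enrichment"] = _jsonable(
            rows.head(5).to_dict(orient="records")
        )

    report = _jsonable(report)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
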