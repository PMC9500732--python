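import numpy as np
import pandas as pd
import pytest

import riboage as ra
from riboage.simulate import READ_COLUMNS


def make_reads(rows):
    """Build a reads DataFrame from (transcript, five_prime, length, sample,
    assay[, spans]) tuples."""
    defaults = ["tx", 0, 28, "s1", "ribo", False]
    recs = []
    for r in rows:
        vals = list(r) + defaults[len(r):]
        recs.append(dict(zip(READ_COLUMNS, vals)))
    df = pd.DataFrame(recs, columns=READ_COLUMNS)
    df["spans_intron_junction"] = df["spans_intron_junction"].astype(bool)
    return df


@pytest.fixture(scope="session")
def rich_config():
    """A mid-sized config exercising every generator feature."""
    return ra.SimConfig(
        n_genes=40,
        cds_codon_range=(60, 200),
        n_replicates=2,
        conditions=("young", "aged"),
        frame_fidelity=0.9,
        start_enrichment=8.0,
        mean_expression=120.0,
        dispersion=0.05,
        frac_te_up=0.1,
        frac_te_down=0.1,
        te_effect_log2=1.5,
        n_ncrna=2,
        intron_gene=ra.IntronGeneSpec(
            unspliced_fraction={"young": 0.3, "aged": 0.1}
        ),
        element_family=ra.ElementFamilySpec(n_copies=4, mutation_rate=0.01),
        seed=11,
    )


@pytest.fixture(scope="session")
def rich_dataset(rich_config):
    return ra.simulate_dataset(rich_config)


@pytest.fixture(scope="session")
def paper_offsets():
    return ra.OffsetTable.paper()


def brute_force_count_cds(reads, genes, offsets, assay, exclude_codons,
                          rna_offset=15):
    """Reference per-read loop for CDS counting (the oracle)."""
    out = {}
    gene_by_id = {g.gene_id: g for g in genes}
    for row in reads.itertuples():
        if row.assay != assay:
            continue
        g = gene_by_id[row.transcript_id]
        if not g.coding:
            continue
        if assay == "rna":
            off = rna_offset
        else:
            if row.length not in offsets.offsets:
                continue
            off = offsets.offsets[row.length]
        site = row.five_prime + off
        if not (g.cds_start <= site < g.cds_end):
            continue
        codon = (site - g.cds_start) // 3
        n = g.n_codons
        if exclude_codons <= codon <= n - 1 - exclude_codons:
            key = (row.transcript_id, row.sample_id)
            out[key] = out.get(key, 0) + 1
    return out
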