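"""Synthetic paired Ribo-seq / RNA-Seq data with known ground truth.

The generator works in three layers, each deterministic given
``SimConfig.seed``:

1. :func:`simulate_transcriptome` — random transcripts (ATG ... stop CDS
   flanked by UTRs), optional non-coding decoys, an optional
   intron-containing gene, and an optional element family of point-mutated
   copies of one ancestor.
2. :func:`simulate_truth` — per-gene baseline expression plus
   condition-dependent transcription and translational-efficiency (TE)
   log2 fold changes with class labels (the recovery target for the
   inference stages).
3. :func:`simulate_counts` / :func:`simulate_reads` — negative-binomial
   per-gene totals per library, then individual aligned reads in
   transcript coordinates.  Ribosome footprints place an A-site codon
   (uniform over internal codons, with ``start_enrichment`` extra weight on
   the first elongation codon), jitter it off-frame with probability
   ``1 - frame_fidelity`` (uniform over {-1, 0, +1} nt), draw a length from
   ``length_dist`` and set ``five_prime = a_site - true_offsets[length]``.
   RNA fragments are placed uniformly; the intron gene draws a configurable
   fraction of fragments from the unspliced template.

Reads are returned as a :class:`pandas.DataFrame` with columns
``transcript_id, five_prime, length, sample_id, assay,
spans_intron_junction``; the same layout is used throughout the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .config import ElementFamilySpec, SimConfig

__all__ = [
    "ReadAlignment",
    "SimulatedDataset",
    "simulate_transcriptome",
    "simulate_truth",
    "simulate_counts",
    "simulate_reads",
    "simulate_dataset",
    "sample_table",
    "frameshift_asite_path",
]

READ_COLUMNS = [
    "transcript_id",
    "five_prime",
    "length",
    "sample_id",
    "assay",
    "spans_intron_junction",
]

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


@dataclass(frozen=True)
class ReadAlignment:
    """One aligned read in transcript coordinates (the atomic observation)."""

    transcript_id: str
    five_prime: int
    length: int
    sample_id: str = "s1"
    assay: str = "ribo"
    spans_intron_junction: bool = False


def reads_to_frame(reads: Sequence[ReadAlignment]) -> pd.DataFrame:
    """Convert a sequence of :class:`ReadAlignment` to the tabular layout."""
    if len(reads) == 0:
        return empty_reads()
    return pd.DataFrame([r.__dict__ for r in reads], columns=READ_COLUMNS)


def empty_reads() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "transcript_id": pd.Series(dtype=str),
            "five_prime": pd.Series(dtype=np.int64),
            "length": pd.Series(dtype=np.int64),
            "sample_id": pd.Series(dtype=str),
            "assay": pd.Series(dtype=str),
            "spans_intron_junction": pd.Series(dtype=bool),
        }
    )


# ---------------------------------------------------------------------------
# rng plumbing: one root seed; fixed stream keys per purpose and per library
# so the same library is reproduced even if the replicate count changes.

_STREAM_TRANSCRIPTOME = 11
_STREAM_TRUTH = 13
_STREAM_COUNTS = 17
_STREAM_READS = 19


def _rng(config: SimConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) & 0x7FFFFFFF, *key])


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = "".join(rng.choice(_SENSE_CODONS, size=n_codons - 2))
    stop = rng.choice(np.array(_STOPS))
    return "ATG" + body + stop


# ---------------------------------------------------------------------------
# layer 1: transcriptome


def simulate_transcriptome(
    config: SimConfig,
) -> Tuple[List[GeneModel], Dict[str, str]]:
    """Generate transcript models and sequences.

    Returns ``(genes, sequences)`` where sequences is a dict
    ``transcript_id -> str``.  Regular coding genes come first, then
    non-coding decoys, then the optional intron gene and element-family
    copies.  Deterministic given ``config.seed``.
    """
    rng = _rng(config, _STREAM_TRANSCRIPTOME)
    genes: List[GeneModel] = []
    seqs: Dict[str, str] = {}

    lo_c, hi_c = config.cds_codon_range
    lo_u, hi_u = config.utr_range
    for i in range(config.n_genes):
        gid = f"g{i + 1:04d}"
        utr5 = int(rng.integers(lo_u, hi_u + 1))
        utr3 = int(rng.integers(lo_u, hi_u + 1))
        n_codons = int(rng.integers(lo_c, hi_c + 1))
        seq = _random_seq(rng, utr5) + _random_cds(rng, n_codons) + _random_seq(rng, utr3)
        genes.append(
            GeneModel(gid, len(seq), cds_start=utr5, cds_end=utr5 + 3 * n_codons)
        )
        seqs[gid] = seq

    for i in range(config.n_ncrna):
        gid = f"nc{i + 1:03d}"
        n = int(rng.integers(config.ncrna_length_range[0], config.ncrna_length_range[1] + 1))
        seqs[gid] = _random_seq(rng, n)
        genes.append(GeneModel(gid, n, coding=False))

    if config.intron_gene is not None:
        spec = config.intron_gene
        gid = "gintron"
        cds_start = spec.utr5
        cds_end = cds_start + 3 * spec.n_codons
        i0, i1 = spec.intron_interval()
        seq = (
            _random_seq(rng, spec.utr5)
            + _random_cds(rng, spec.n_codons)
            + _random_seq(rng, spec.spacer + spec.intron_length + spec.tail)
        )
        genes.append(
            GeneModel(gid, len(seq), cds_start=cds_start, cds_end=cds_end,
                      intron=(i0, i1))
        )
        seqs[gid] = seq

    if config.element_family is not None:
        fam = config.element_family
        length = fam.transcript_length()
        ancestor = list(_random_seq(rng, length))
        # guarantee an ATG at the ORF-A start for cosmetic realism
        ancestor[fam.orf_a[0]: fam.orf_a[0] + 3] = list("ATG")
        ancestor = "".join(ancestor)
        seqs["family_ancestor"] = ancestor
        for j in range(fam.n_copies):
            gid = f"ty{j + 1:02d}"
            copy = np.array(list(ancestor))
            mutate = rng.random(length) < fam.mutation_rate
            idx = np.flatnonzero(mutate)
            for k in idx:
                choices = [b for b in "ACGT" if b != copy[k]]
                copy[k] = choices[int(rng.integers(0, 3))]
            seqs[gid] = "".join(copy)
            genes.append(
                GeneModel(
                    gid,
                    length,
                    cds_start=fam.orf_a[0],
                    cds_end=fam.orf_a[1],
                    family_id="family",
                )
            )

    return genes, seqs


# ---------------------------------------------------------------------------
# layer 2: ground truth


def simulate_truth(config: SimConfig, genes: Sequence[GeneModel]) -> pd.DataFrame:
    """Ground-truth table: baseline expression and per-condition effects.

    One row per transcript.  Columns: ``baseline`` (expected RNA count at
    size factor 1), ``te_class`` in {up, down, null, nc}, and per condition
    ``txn_log2fc_<cond>`` / ``te_log2fc_<cond>`` (zero for the first,
    reference, condition).  The intron gene and element-family copies are
    held at null TE so their dedicated analyses see a stable background.
    """
    rng = _rng(config, _STREAM_TRUTH)
    rows = []
    ref = config.conditions[0]
    for g in genes:
        if not g.coding:
            baseline = config.ncrna_expression
            te_class = "nc"
        else:
            baseline = config.mean_expression * math.exp(
                rng.normal(0.0, config.mean_expression_log_sd)
            )
            if g.family_id is not None or g.intron is not None:
                te_class = "null"
            else:
                u = rng.random()
                if u < config.frac_te_up:
                    te_class = "up"
                elif u < config.frac_te_up + config.frac_te_down:
                    te_class = "down"
                else:
                    te_class = "null"
        has_txn = g.coding and g.family_id is None and g.intron is None and (
            rng.random() < config.frac_txn
        )
        txn_sign = 1.0 if rng.random() < 0.5 else -1.0
        row = {"gene_id": g.gene_id, "baseline": baseline, "te_class": te_class}
        for cond in config.conditions:
            if cond == ref:
                row[f"txn_log2fc_{cond}"] = 0.0
                row[f"te_log2fc_{cond}"] = 0.0
                continue
            row[f"txn_log2fc_{cond}"] = (
                txn_sign * config.txn_effect_log2 if has_txn else 0.0
            )
            if te_class == "up":
                row[f"te_log2fc_{cond}"] = config.te_effect_log2
            elif te_class == "down":
                row[f"te_log2fc_{cond}"] = -config.te_effect_log2
            else:
                row[f"te_log2fc_{cond}"] = 0.0
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")


def sample_table(config: SimConfig) -> pd.DataFrame:
    """Library layout: one row per (assay, condition, replicate)."""
    rows = []
    for assay in ("ribo", "rna"):
        for cond in config.conditions:
            for rep in range(1, config.n_replicates + 1):
                sid = f"{assay}_{cond}_r{rep}"
                size = 1.0
                if config.library_sizes:
                    size = float(config.library_sizes.get(sid, 1.0))
                rows.append(
                    {
                        "sample_id": sid,
                        "assay": assay,
                        "condition": cond,
                        "replicate": rep,
                        "library_size": size,
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# layer 3: counts and reads


def _nb_draw(
    rng: np.random.Generator, mu: np.ndarray, alpha: float
) -> np.ndarray:
    """NB(mean mu, variance mu + alpha mu^2); Poisson in the alpha -> 0 limit."""
    mu = np.asarray(mu, dtype=float)
    if alpha < 1e-12:
        return rng.poisson(mu)
    size = 1.0 / alpha
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def simulate_counts(
    config: SimConfig, genes: Sequence[GeneModel], truth: pd.DataFrame
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene, per-library NB read totals (the count layer of the model).

    Returns ``(counts, samples)``: a genes x samples integer DataFrame and
    the sample table.  Ribo means are ``sf * baseline * 2**txn * 2**te``;
    RNA means omit the TE factor.
    """
    missing = [g.gene_id for g in genes if g.gene_id not in truth.index]
    if missing:
        raise KeyError(f"truth table lacks entries for: {missing}")
    samples = sample_table(config)
    gene_ids = [g.gene_id for g in genes]
    base = truth.loc[gene_ids, "baseline"].to_numpy(float)
    cond_idx = {c: i for i, c in enumerate(config.conditions)}
    cols = {}
    for sid, row in samples.iterrows():
        assay_i = 0 if row["assay"] == "ribo" else 1
        rng = _rng(
            config, _STREAM_COUNTS, assay_i, cond_idx[row["condition"]],
            int(row["replicate"]),
        )
        txn = truth.loc[gene_ids, f"txn_log2fc_{row['condition']}"].to_numpy(float)
        mu = row["library_size"] * base * np.exp2(txn)
        if row["assay"] == "ribo":
            te = truth.loc[gene_ids, f"te_log2fc_{row['condition']}"].to_numpy(float)
            mu = mu * np.exp2(te)
        cols[sid] = _nb_draw(rng, mu, config.dispersion)
    counts = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
    return counts, samples


def frameshift_asite_path(fam: ElementFamilySpec) -> np.ndarray:
    """First-nt positions of A-site codons along the +1-frameshift path.

    Ribosomes decode ORF-A codons from its first elongation codon up to the
    frameshift boundary, shift +1 nt, then decode ORF-B codons to its last
    sense codon.  Positions are transcript coordinates of each A-site
    codon's first nt.
    """
    a0, _ = fam.orf_a
    upstream = np.arange(a0 + 3, fam.frameshift_pos, 3)
    downstream = np.arange(fam.frameshift_pos + 1, fam.orf_b[1] - 3 + 1, 3)
    return np.concatenate([upstream, downstream])


def _gene_emission_tables(
    config: SimConfig, genes: Sequence[GeneModel]
) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    """Per-gene (A-site positions, sampling weights) for the ribo layer."""
    tables = {}
    fam = config.element_family
    for g in genes:
        if not g.coding:
            continue
        if g.family_id is not None and fam is not None:
            pos = frameshift_asite_path(fam)
            w = np.ones(pos.size)
        else:
            n = g.n_codons
            # A-site on codons 1 .. n-2 (0-based; codon n-1 is the stop)
            pos = g.cds_start + 3 * np.arange(1, n - 1)
            w = np.ones(pos.size)
            w[0] = config.start_enrichment
        tables[g.gene_id] = (pos, w / w.sum())
    return tables


def _emit_ribo(
    rng: np.random.Generator,
    k: int,
    pos: np.ndarray,
    weights: np.ndarray,
    length_vals: np.ndarray,
    length_probs: np.ndarray,
    offsets: np.ndarray,
    fidelity: float,
    tlen: int,
) -> Tuple[np.ndarray, np.ndarray]:
    """Draw k footprints; redraw any that would overhang the transcript."""
    fp = np.empty(k, dtype=np.int64)
    ln = np.empty(k, dtype=np.int64)
    todo = np.arange(k)
    for _ in range(100):
        m = todo.size
        if m == 0:
            break
        a = pos[rng.choice(pos.size, size=m, p=weights)]
        off_frame = rng.random(m) >= fidelity
        jitter = np.where(off_frame, rng.integers(-1, 2, size=m), 0)
        li = rng.choice(length_vals.size, size=m, p=length_probs)
        f = a + jitter - offsets[li]
        L = length_vals[li]
        ok = (f >= 0) & (f + L <= tlen)
        fp[todo[ok]] = f[ok]
        ln[todo[ok]] = L[ok]
        todo = todo[~ok]
    if todo.size:  # pragma: no cover - geometry makes this unreachable
        raise RuntimeError("footprint redraw did not converge")
    return fp, ln


def _emit_rna(
    rng: np.random.Generator,
    k: int,
    gene: GeneModel,
    length_vals: np.ndarray,
    length_probs: np.ndarray,
    unspliced_fraction: float,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Uniformly placed RNA fragments; splicing-aware for the intron gene."""
    li = rng.choice(length_vals.size, size=k, p=length_probs)
    L = length_vals[li]
    spans = np.zeros(k, dtype=bool)
    if gene.intron is None:
        hi = np.maximum(gene.length - L + 1, 1)
        fp = (rng.random(k) * hi).astype(np.int64)
        return fp, L, spans
    i0, i1 = gene.intron
    ilen = i1 - i0
    unspliced = rng.random(k) < unspliced_fraction
    fp = np.empty(k, dtype=np.int64)
    # unspliced template: uniform over the annotated (pre-mRNA) transcript
    hi_u = np.maximum(gene.length - L + 1, 1)
    fp[unspliced] = (rng.random(int(unspliced.sum())) * hi_u[unspliced]).astype(np.int64)
    # spliced template: place on the mature transcript, then lift the 5' end
    # back to pre-mRNA coordinates; fragments crossing the junction are flagged
    sp = ~unspliced
    ls = gene.length - ilen
    hi_s = np.maximum(ls - L + 1, 1)
    start_s = (rng.random(int(sp.sum())) * hi_s[sp]).astype(np.int64)
    crosses = (start_s < i0) & (start_s + L[sp] > i0)
    fp[sp] = np.where(start_s < i0, start_s, start_s + ilen)
    spans[sp] = crosses
    return fp, L, spans


def simulate_reads(
    config: SimConfig, genes: Sequence[GeneModel], truth: pd.DataFrame
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Emit individual aligned reads for every library.

    Returns ``(reads, samples)`` where reads is a DataFrame in the
    standard layout (one row per read).  Per-library totals come from
    :func:`simulate_counts`, so count-level and read-level analyses see
    the same library depths.
    """
    counts, samples = simulate_counts(config, genes, truth)
    tables = _gene_emission_tables(config, genes)
    length_vals = np.array(sorted(config.length_dist), dtype=np.int64)
    length_probs = np.array([config.length_dist[v] for v in length_vals], float)
    length_probs = length_probs / length_probs.sum()
    offsets = np.array([config.true_offsets[v] for v in length_vals], dtype=np.int64)
    cond_idx = {c: i for i, c in enumerate(config.conditions)}
    gene_by_id = {g.gene_id: g for g in genes}

    chunks = []
    for sid, row in samples.iterrows():
        is_ribo = row["assay"] == "ribo"
        rng = _rng(
            config, _STREAM_READS, 0 if is_ribo else 1,
            cond_idx[row["condition"]], int(row["replicate"]),
        )
        unspliced_frac = 0.0
        if config.intron_gene is not None:
            unspliced_frac = config.intron_gene.unspliced_fraction.get(
                row["condition"], 0.0
            )
        for gid, k in counts[sid].items():
            k = int(k)
            if k == 0:
                continue
            g = gene_by_id[gid]
            if is_ribo and not g.coding:
                # ncRNA contamination in the footprint library: uniform ends
                hi = max(g.length - int(length_vals.max()), 1)
                fp = (rng.random(k) * hi).astype(np.int64)
                ln = length_vals[rng.choice(length_vals.size, size=k, p=length_probs)]
                spans = np.zeros(k, dtype=bool)
            elif is_ribo:
                pos, w = tables[gid]
                fp, ln = _emit_ribo(
                    rng, k, pos, w, length_vals, length_probs, offsets,
                    config.frame_fidelity, g.length,
                )
                spans = np.zeros(k, dtype=bool)
            else:
                fp, ln, spans = _emit_rna(
                    rng, k, g, length_vals, length_probs, unspliced_frac
                )
            chunks.append(
                pd.DataFrame(
                    {
                        "transcript_id": gid,
                        "five_prime": fp,
                        "length": ln,
                        "sample_id": sid,
                        "assay": row["assay"],
                        "spans_intron_junction": spans,
                    }
                )
            )
    reads = pd.concat(chunks, ignore_index=True) if chunks else empty_reads()
    return reads, samples


# ---------------------------------------------------------------------------


@dataclass
class SimulatedDataset:
    """Everything one synthetic run produces, bundled for the pipeline."""

    config: SimConfig
    genes: List[GeneModel]
    sequences: Dict[str, str]
    truth: pd.DataFrame
    reads: pd.DataFrame
    samples: pd.DataFrame


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Run all three generator layers under one seed."""
    genes, seqs = simulate_transcriptome(config)
    truth = simulate_truth(config, genes)
    reads, samples = simulate_reads(config, genes, truth)
    return SimulatedDataset(config, genes, seqs, truth, reads, samples)
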