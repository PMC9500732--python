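# Methods

## Coordinate and counting conventions

All coordinates are 0-based, half-open, in transcript space.  The CDS
includes the stop codon; codon indices are 0-based (codon 0 = start codon).
Metagene positions are signed nt relative to the first nucleotide of the
start (or stop) codon.  A footprint's A-site is `five_prime + d_l`, where
`d_l` is the length-dependent offset to the first nucleotide of the A-site
codon; RNA fragments use the single fixed offset of 15 nt regardless of
length.  With this convention the published pairing is self-consistent: a
28-nt footprint with `d = 15` on an initiating ribosome (P-site on the AUG,
A-site on codon 2 at +3) puts the 5' end at −12 nt.

Counting rules: reads on non-coding transcripts are removed first; each
remaining read counts for its gene iff the A-site lies inside the CDS and
outside the first and last five codons (configurable, applied to both
assays).  Every input read falls in exactly one accounting category
(ncRNA-filtered / no-offset-length / outside-CDS / edge-codon-excluded /
counted); the sidecar partition is exact by construction and asserted in
tests.

## Offset calibration

For each footprint length the start-anchored 5'-end histogram is searched
for its argmax `p*` inside a window (default `[−18, −6)`, which brackets
`3 − d` for every published offset with margin); the offset is `d = 3 − p*`.
Ties break toward the smaller `|p*|`, then the smaller `p*` — the initiating
peak is the position closest to the start codon when two bins tie.  Lengths
with fewer than `min_reads = 500` profile reads, or an all-zero search
window, are omitted with a warning; the pipeline can substitute the fixed
published table (`--fallback-offsets paper` / `offsets_source: paper`).
Lengths without an offset are excluded from all A-site analyses.

## The TE model

Per gene, counts over both assays and two conditions follow NB2
(`Var = μ + αμ²`) with

    log μ_s = log sf_s + β₀ + β_assay·[ribo] + β_cond·[trt] + β_int·[ribo][trt]

fitted by iteratively reweighted least squares, vectorized across genes
(working weights `μ/(1+αμ)`; convergence at relative deviance change
< 1e−8, max 100 iterations; the linear predictor is clipped at ±30 to guard
zero cells).  `te_log2fc = β_int/ln 2`; the Wald z uses the observed-
information SE with a normal reference; BH-FDR is computed over converged,
tested genes.  Per-assay log2 fold changes use the same machinery with the
reduced two-group design.

**Normalization.** Median-of-ratios (log-space median against the per-gene
geometric-mean reference, genes with any zero dropped), computed per assay
by default because footprint and RNA libraries have unrelated depths; a
joint scope is available.  Known library depths can be supplied to
`fit(size_factors_=...)`.

**Dispersion.** Within each (assay, condition) cell with ≥ 2 replicates the
moment estimate on normalized counts is `(s² − m̄)/m̄²`; cells combine by a
df-weighted average.  The raw per-gene value is then shrunk toward the
common (df-weighted mean) dispersion with 10 prior degrees of freedom and
floored at 1e−8.  The moderation matters: at 3 replicates the raw per-gene
moment estimate is noisy enough to visibly inflate the Wald type-I error
(measured ≈ 0.08 at nominal 0.05, versus ≈ 0.05 when the true α is
supplied); squeezing with the standard prior restores calibration (≈ 0.054)
while leaving well-replicated designs essentially untouched.  This is a
deliberate simplification of DESeq2's trend-plus-empirical-Bayes machinery;
no LFC shrinkage or outlier handling is applied, and the twofold
classification acts on the raw point estimate with a strict inequality
(`te_log2fc > 1` / `< −1`), with genes under 5 mean normalized counts (or
unfitted/non-converged) set aside as `low_count`.

Multi-condition designs are handled as separate two-condition fits against
the first (reference) condition.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes,
in three seeded, deterministic layers (one root seed; fixed stream keys per
purpose and per library, so a library's draws do not change when the
replicate count does).

*Transcriptome* — random transcripts with 20–60 nt UTRs (minimum validated
against the largest offset so initiating footprints fit) and CDSs of 80–400
codons starting ATG and ending with a stop; optional non-coding decoys
(default 2) to exercise ncRNA filtering; an optional intron gene whose
intron sits downstream of the CDS (as for HAC1, whose intron interrupts the
3' end of the ORF — placing it there keeps the footprint layer independent
of splicing); an optional element family of 4 copies derived from one
ancestor by independent point mutations (rate 0.01/nt, no indels, so the
copies are trivially column-aligned for the consensus stage) with two
overlapping ORFs joined by a +1 frameshift at a codon boundary inside the
overlap.

*Truth* — per-gene baseline expression, log-normal around a median of 100
expected RNA counts (σ = 1 natural-log units); a configurable fraction of
genes receives a ±`txn_effect_log2` transcription shift and fractions
`frac_te_up`/`frac_te_down` receive ±`te_effect_log2` TE shifts in each
non-reference condition.  The intron gene and family copies are held at
null TE so their dedicated analyses see a stable background.

*Counts and reads* — per-library totals are NB with the configured
dispersion (Poisson at α→0); ribo means are `sf·expr·2^txn·2^te`, RNA means
omit the TE factor.  Footprints draw an A-site codon uniformly over
internal codons with `start_enrichment` (default 8×) extra weight on codon
2; with probability `1 − frame_fidelity` the A-site is jittered uniformly
over {−1, 0, +1} nt, so the frame-0 fraction converges to
`f + (1 − f)/3` — the law asserted in tests.  Lengths come from a bimodal
distribution with the main mode at 27–28 nt and a secondary mode at
20–21 nt (only lengths with defined offsets are emitted); the 5' end is
`a_site − d_l`, and reads that would overhang the transcript are redrawn so
the length distribution stays exact.  RNA fragments are uniform; for the
intron gene a per-condition fraction derives from the unspliced template,
and spliced-template fragments crossing the excision point are flagged as
junction-spanning.  Element-copy footprints follow the frameshift path:
ORF-A frame up to the shift boundary, then +1 nt into ORF-B's frame.

What the generator does *not* model — sequencing error, adapter artifacts,
rRNA contamination beyond whole-transcript decoys, multi-mapping, uneven
codon dwell times, positional ramps beyond the single initiation peak, or
genome-space alignment.  Passing tests therefore demonstrate correctness of
the analysis logic under the stated generative assumptions, not robustness
to every artifact of real libraries.

## Consensus and family counting

The multiple alignment is an input (building it is out of scope; the
simulator's indel-free families make the raw copies a valid alignment).
Consensus: per column, drop the column if its gap fraction exceeds 0.5
(ties at exactly 0.5 are kept); otherwise emit the modal non-gap base,
breaking ties to the lexicographically smallest base, with N never beating
a concrete base.  A-sites on the consensus are partitioned into
ORF-A ∖ overlap, ORF-B ∖ overlap, overlap (excluded by default), outside,
and no-offset-length; the partition is exact.

## Enrichment

Flat hypergeometric over-representation: `p = P[X ≥ k]` with
`X ~ Hypergeom(N, K, n)` via the survival function, fold enrichment
`(k/n)/(K/N)`, Bonferroni correction by default (mirroring classic GO term
finders) with BH available.  The recommended background is the set of genes
with a TE result, not the whole annotation.  No ontology propagation.

## Benchmark problem sizes

The repository's verification runs use sizes chosen to make the targeted
property measurable with comfortable statistical margin:

- offset geometry: 120 genes, ≈ 67,000 footprints per length (26/28/30 nt),
  start enrichment 10×, frame fidelity 0.9;
- null test calibration: 2,000 genes, 3 replicates/cell, α = 0.05;
  FDR: 20 seeds of the same design with 10% true effects at 1.5 log2;
- effect recovery: 30 replicates at ≈ 500 mean counts — with α = 0.05 the
  interaction SE has a dispersion floor of `√(4α/n_rep)` nats, so a
  3-replicate design cannot push the median absolute error below ≈ 0.26
  log2 regardless of depth; 30 replicates brings the floor to ≈ 0.08;
- classification recovery: exactly 100 up / 100 down genes of 1,000 at
  1.6 log2 (3.0-fold), 4 replicates, α = 0.02, ≈ 800 mean counts, where the
  per-gene misclassification probability under the strict twofold rule is
  below 1%.

## Known limitations

- Wald tests with a normal reference are approximate at very low counts;
  genes with zero cells rely on the clipped linear predictor and may be
  flagged non-converged.
- The moderated moment dispersion has no mean-dispersion trend; strongly
  expression-dependent dispersion would be over-smoothed.
- One transcript per read record: multi-mapping ambiguity is addressed only
  via the family-consensus route.
- The intron metric counts any ≥ 1 nt overlap by default
  (`mode="contained"` available); which of the two a Sashimi-style count
  corresponds to depends on the viewer's definition.
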