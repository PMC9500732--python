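"""Simulation configuration.

``SimConfig`` defines the generative conditions for the synthetic benchmark:
paired ribosome-profiling and RNA-Seq libraries over ordered conditions with
a bimodal footprint length distribution, length-dependent 5'-digestion
offsets, 3-nt periodicity of configurable fidelity, initiating-ribosome
enrichment, per-gene negative-binomial counts with condition-dependent
transcription and translational-efficiency effects, an optional
intron-containing gene with an unspliced RNA fraction, and an optional
multi-copy element family whose two overlapping ORFs are joined by a
programmed +1 frameshift.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, Optional, Tuple

import yaml

from .annotation import PAPER_RIBO_OFFSETS, RNA_FRAGMENT_OFFSET

__all__ = ["SimConfig", "IntronGeneSpec", "ElementFamilySpec", "ConfigError",
           "DEFAULT_LENGTH_DIST"]


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


#: Default footprint length distribution: bimodal with the main mode at
#: 27-28 nt (ribosomes with A-site tRNA) and a secondary mode at 20-21 nt
#: (no A-site tRNA).  Only lengths with a defined A-site offset are emitted;
#: 20 nt is folded into 21 for that reason.
DEFAULT_LENGTH_DIST: Dict[int, float] = {
    21: 0.14,
    22: 0.06,
    26: 0.06,
    27: 0.22,
    28: 0.28,
    29: 0.11,
    30: 0.09,
    31: 0.04,
}


@dataclass
class IntronGeneSpec:
    """An intron-containing transcript (the HAC1-like analog).

    The transcript is laid out as 5'UTR | CDS | spacer | intron | tail, so
    the intron sits downstream of the CDS and only the RNA layer is affected
    by splicing.  ``unspliced_fraction`` gives, per condition, the fraction
    of RNA fragments drawn from the unspliced template.
    """

    n_codons: int = 120
    intron_length: int = 60
    unspliced_fraction: Dict[str, float] = field(default_factory=dict)
    utr5: int = 30
    spacer: int = 10
    tail: int = 40

    def intron_interval(self) -> Tuple[int, int]:
        start = self.utr5 + 3 * self.n_codons + self.spacer
        return (start, start + self.intron_length)

    def transcript_length(self) -> int:
        return self.intron_interval()[1] + self.tail


@dataclass
class ElementFamilySpec:
    """A retrotransposon-like family of near-identical copies.

    Copies derive from one ancestor by independent point mutations (no
    indels, so the family is trivially column-aligned).  Two overlapping
    ORFs are joined by a programmed +1 frameshift at ``frameshift_pos``:
    ribosomes read ORF-A's frame up to that codon boundary, then continue
    one nt downstream in ORF-B's frame (= ORF-A frame + 1 mod 3).
    """

    n_copies: int = 4
    mutation_rate: float = 0.01
    orf_a: Tuple[int, int] = (30, 330)
    orf_b: Tuple[int, int] = (292, 592)
    frameshift_pos: int = 294
    utr3: int = 40

    def overlap(self) -> Tuple[int, int]:
        lo = max(self.orf_a[0], self.orf_b[0])
        hi = min(self.orf_a[1], self.orf_b[1])
        return (lo, hi) if lo < hi else (lo, lo)

    def transcript_length(self) -> int:
        return max(self.orf_a[1], self.orf_b[1]) + self.utr3

    def validate(self) -> None:
        if self.n_copies < 2:
            raise ConfigError("element_family.n_copies must be >= 2")
        if not (0.0 <= self.mutation_rate < 0.5):
            raise ConfigError("element_family.mutation_rate must be in [0, 0.5)")
        for name, (a, b) in (("orf_a", self.orf_a), ("orf_b", self.orf_b)):
            if not (0 <= a < b) or (b - a) % 3 != 0:
                raise ConfigError(
                    f"element_family.{name} must be a forward interval with "
                    "length divisible by 3"
                )
        if (self.orf_b[0] - self.orf_a[0]) % 3 != 1:
            raise ConfigError(
                "element_family.orf_b frame must equal orf_a frame + 1 (mod 3)"
            )
        lo, hi = self.overlap()
        if not (lo <= self.frameshift_pos < hi):
            raise ConfigError(
                "element_family.frameshift_pos must lie inside the ORF overlap"
            )
        if (self.frameshift_pos - self.orf_a[0]) % 3 != 0:
            raise ConfigError(
                "element_family.frameshift_pos must be a codon boundary of orf_a"
            )


@dataclass
class SimConfig:
    """Generative conditions for the synthetic paired-assay benchmark."""

    n_genes: int = 100
    cds_codon_range: Tuple[int, int] = (80, 400)
    n_replicates: int = 2
    conditions: Tuple[str, ...] = ("young", "aged")
    length_dist: Dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_DIST)
    )
    true_offsets: Dict[int, int] = field(
        default_factory=lambda: dict(PAPER_RIBO_OFFSETS)
    )
    frame_fidelity: float = 0.9
    start_enrichment: float = 8.0
    mean_expression: float = 100.0
    mean_expression_log_sd: float = 1.0
    dispersion: float = 0.05
    frac_te_up: float = 0.0
    frac_te_down: float = 0.0
    te_effect_log2: float = 1.5
    frac_txn: float = 0.2
    txn_effect_log2: float = 1.0
    library_sizes: Optional[Dict[str, float]] = None
    rna_fragment_offset: int = RNA_FRAGMENT_OFFSET
    utr_range: Tuple[int, int] = (20, 60)
    n_ncrna: int = 2
    ncrna_length_range: Tuple[int, int] = (200, 600)
    ncrna_expression: float = 50.0
    intron_gene: Optional[IntronGeneSpec] = None
    element_family: Optional[ElementFamilySpec] = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        lo, hi = self.cds_codon_range
        if not (3 <= lo <= hi):
            raise ConfigError("cds_codon_range must satisfy 3 <= min <= max")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if len(self.conditions) < 1:
            raise ConfigError("conditions must be non-empty")
        if len(set(self.conditions)) != len(self.conditions):
            raise ConfigError("conditions must be distinct labels")
        total = sum(self.length_dist.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"length_dist probabilities sum to {total}, not 1")
        for length, p in self.length_dist.items():
            if p < 0:
                raise ConfigError("length_dist probabilities must be >= 0")
            if p > 0 and length not in self.true_offsets:
                raise ConfigError(
                    f"length_dist emits {length} nt but true_offsets has no entry"
                )
        for length, off in self.true_offsets.items():
            if not (0 < off < length):
                raise ConfigError(
                    f"true_offsets[{length}] = {off} must lie in (0, length)"
                )
        if not (0.0 <= self.frame_fidelity <= 1.0):
            raise ConfigError("frame_fidelity must be in [0, 1]")
        if self.start_enrichment <= 0:
            raise ConfigError("start_enrichment must be > 0")
        if self.mean_expression <= 0:
            raise ConfigError("mean_expression must be > 0")
        if self.mean_expression_log_sd < 0:
            raise ConfigError("mean_expression_log_sd must be >= 0")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        if self.frac_te_up < 0 or self.frac_te_down < 0:
            raise ConfigError("frac_te_up/frac_te_down must be >= 0")
        if self.frac_te_up + self.frac_te_down > 1.0:
            raise ConfigError("frac_te_up + frac_te_down must be <= 1")
        if self.te_effect_log2 <= 0:
            raise ConfigError("te_effect_log2 must be > 0")
        if not (0.0 <= self.frac_txn <= 1.0):
            raise ConfigError("frac_txn must be in [0, 1]")
        if self.rna_fragment_offset <= 0:
            raise ConfigError("rna_fragment_offset must be > 0")
        max_off = max(self.true_offsets.values(), default=0)
        if self.utr_range[0] < max_off + 2:
            raise ConfigError(
                f"utr_range minimum must be >= max offset + 2 ({max_off + 2}) so "
                "initiating footprints fit inside the transcript"
            )
        if self.intron_gene is not None:
            for cond, frac in self.intron_gene.unspliced_fraction.items():
                if cond not in self.conditions:
                    raise ConfigError(
                        f"intron_gene.unspliced_fraction names unknown condition "
                        f"'{cond}'"
                    )
                if not (0.0 <= frac <= 1.0):
                    raise ConfigError(
                        "intron_gene.unspliced_fraction values must be in [0, 1]"
                    )
        if self.element_family is not None:
            self.element_family.validate()

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if d.get("intron_gene") is not None and not isinstance(
            d["intron_gene"], IntronGeneSpec
        ):
            d["intron_gene"] = IntronGeneSpec(**d["intron_gene"])
        if d.get("element_family") is not None and not isinstance(
            d["element_family"], ElementFamilySpec
        ):
            ef = dict(d["element_family"])
            for key in ("orf_a", "orf_b"):
                if key in ef and ef[key] is not None:
                    ef[key] = tuple(ef[key])
            d["element_family"] = ElementFamilySpec(**ef)
        for key in ("cds_codon_range", "conditions", "utr_range", "ncrna_length_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        for key in ("length_dist", "true_offsets"):
            if key in d and d[key] is not None:
                d[key] = {int(k): v for k, v in d[key].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
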