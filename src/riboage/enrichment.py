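"""Offline gene-set over-representation analysis.

Hypergeometric upper-tail test of a query gene list against a background,
per annotation term, reporting fold enrichment ``(k/n) / (K/N)`` and a
multiplicity-corrected p-value (Bonferroni by default, mirroring classic
GO term finders; Benjamini-Hochberg available).  No ontology structure is
used: terms are flat user-supplied gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Set, Tuple

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["TermAnnotation", "enrich", "read_terms_tsv"]


@dataclass(frozen=True)
class TermAnnotation:
    """One flat annotation term and its member genes."""

    term_id: str
    term_name: str
    genes: frozenset

    @staticmethod
    def from_mapping(mapping: Dict[str, Iterable[str]]) -> List["TermAnnotation"]:
        return [
            TermAnnotation(tid, tid, frozenset(genes))
            for tid, genes in mapping.items()
        ]


def read_terms_tsv(path) -> List[TermAnnotation]:
    """Read a term table (columns term_id, term_name, gene_id; one gene/row)."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for (tid, tname), sub in df.groupby(["term_id", "term_name"]):
        out.append(TermAnnotation(str(tid), str(tname), frozenset(sub["gene_id"])))
    return out


def enrich(
    query: Iterable[str],
    background: Iterable[str],
    terms: Iterable[TermAnnotation],
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Per-term hypergeometric over-representation of ``query``.

    For a term with K background members, query size n and k query members
    in the term, ``p = P[X >= k]`` for X ~ Hypergeom(N, K, n) and
    ``fold_enrichment = (k/n) / (K/N)``.  Rows sorted by p.
    """
    if correction not in ("bonferroni", "bh"):
        raise ValueError(f"correction must be 'bonferroni' or 'bh', got {correction!r}")
    bg: Set[str] = set(background)
    q: Set[str] = set(query)
    stray = sorted(q - bg)
    if stray:
        raise ValueError(f"query genes absent from background: {stray}")
    terms = list(terms)
    if not terms:
        raise ValueError("no annotation terms supplied")
    N, n = len(bg), len(q)
    rows = []
    for term in terms:
        members = term.genes & bg
        K = len(members)
        if K == 0:
            continue
        k = len(members & q)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N) if n > 0 else float("nan")
        rows.append(
            {
                "term_id": term.term_id,
                "term_name": term.term_name,
                "K": K,
                "N": N,
                "n": n,
                "k": k,
                "fold_enrichment": fold,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        method = "bonferroni" if correction == "bonferroni" else "fdr_bh"
        out["p_adjusted"] = multipletests(out["p"].to_numpy(), method=method)[1]
        out = out.sort_values("p", kind="mergesort").reset_index(drop=True)
    return out
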