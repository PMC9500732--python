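"""Translational-efficiency inference from paired Ribo-seq / RNA-Seq counts.

Translational efficiency (TE) is the over- or under-representation of
ribosome-footprint counts relative to RNA-Seq counts.  For a two-condition
comparison it is estimated per gene from a negative-binomial log-link GLM
with an assay x condition interaction:

    log mu_s = log sf_s + b0 + b_assay [ribo] + b_cond [treatment]
               + b_int [ribo][treatment]

The interaction ``b_int`` is the change in TE between conditions
(``te_log2fc = b_int / ln 2``), tested with a Wald z statistic and
Benjamini-Hochberg FDR.  Size factors come from the median-of-ratios
method (per assay by default, since footprint and RNA libraries have
unrelated depths); dispersion is a per-gene method-of-moments estimate
pooled over (assay, condition) cells with a small floor — a deliberate
simplification of DESeq2's empirical-Bayes machinery.

The module is organised statsmodels-style: build a
:class:`TranslationalEfficiencyModel` from a count table, call
:meth:`~TranslationalEfficiencyModel.fit`, and work with the returned
:class:`TEResults` (estimates, tests, twofold classification, gene-set
summaries, ``summary()``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .glm import fit_nb_glm
from .quantify import CountTable

__all__ = [
    "TranslationalEfficiencyModel",
    "TEResults",
    "GeneSetSummary",
    "size_factors",
    "estimate_dispersion",
    "assay_log2fc",
]

logger = logging.getLogger("riboage.te")

LN2 = math.log(2.0)


def size_factors(
    counts: pd.DataFrame,
    samples: Optional[pd.DataFrame] = None,
    scope: str = "per_assay",
) -> pd.Series:
    """Median-of-ratios size factors.

    The reference is the per-gene geometric mean over the samples in scope
    (genes with any zero dropped from the reference set); each sample's
    factor is the median of count/reference.  ``scope="per_assay"``
    normalizes footprint and RNA libraries separately; ``scope="joint"``
    uses one reference across all samples.
    """
    if scope not in ("per_assay", "joint"):
        raise ValueError(f"scope must be 'per_assay' or 'joint', got {scope!r}")
    if scope == "per_assay" and samples is None:
        raise ValueError("per-assay scope requires a sample table")
    groups: Dict[str, list]
    if scope == "joint":
        groups = {"all": list(counts.columns)}
    else:
        groups = {
            assay: list(sub.index)
            for assay, sub in samples.loc[counts.columns].groupby("assay")
        }
    out = {}
    for _, cols in groups.items():
        mat = counts[cols].to_numpy(float)
        usable = (mat > 0).all(axis=1)
        if not usable.any():
            raise ValueError(
                "no gene has nonzero counts in every sample; cannot form the "
                "geometric-mean reference"
            )
        logs = np.log(mat[usable])
        ref = logs.mean(axis=1, keepdims=True)
        factors = np.exp(np.median(logs - ref, axis=0))
        for c, f in zip(cols, factors):
            out[c] = float(f)
    return pd.Series(out).reindex(counts.columns)


def estimate_dispersion(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    sf: pd.Series,
    alpha_min: float = 1e-8,
    prior_df: float = 10.0,
) -> pd.Series:
    """Per-gene NB dispersion by moderated method of moments.

    Within each (assay, condition) cell with >= 2 replicates the moment
    estimate is ``(s^2 - m) / m^2``; cells are combined by a df-weighted
    average.  The per-gene estimate is then shrunk toward the common
    (mean) dispersion with ``prior_df`` pseudo-degrees of freedom —
    gene-wise moment estimates at few replicates are too noisy to plug
    into a Wald test directly, and this squeezing restores test
    calibration.  ``prior_df=0`` disables moderation.  Floored at
    ``alpha_min``.
    """
    cells = samples.loc[counts.columns].groupby(["assay", "condition"])
    norm = counts / sf
    num = np.zeros(len(counts))
    den = np.zeros(len(counts))
    any_cell = False
    for _, sub in cells:
        cols = list(sub.index)
        if len(cols) < 2:
            continue
        any_cell = True
        mat = norm[cols].to_numpy(float)
        m = mat.mean(axis=1)
        v = mat.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a_cell = (v - m) / (m * m)
        ok = m > 0
        df = len(cols) - 1
        num[ok] += df * a_cell[ok]
        den[ok] += df
    if not any_cell:
        raise ValueError(
            "no (assay, condition) cell has >= 2 replicates; supply a "
            "dispersion value explicitly"
        )
    with np.errstate(invalid="ignore"):
        alpha = num / den
    alpha[~np.isfinite(alpha)] = alpha_min
    alpha = np.maximum(alpha, alpha_min)
    if prior_df > 0:
        common = float(np.average(alpha, weights=np.maximum(den, 1e-12)))
        alpha = (den * alpha + prior_df * common) / (den + prior_df)
    return pd.Series(np.maximum(alpha, alpha_min), index=counts.index)


def _two_group_fit(
    y: np.ndarray,
    is_treatment: np.ndarray,
    log_sf: np.ndarray,
    alpha: np.ndarray,
    maxiter: int,
    tol: float,
):
    X = np.column_stack([np.ones(is_treatment.size), is_treatment.astype(float)])
    return fit_nb_glm(y, X, log_sf, alpha, max_iter=maxiter, tol=tol)


def assay_log2fc(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    sf: pd.Series,
    dispersions: Union[float, pd.Series],
    assay: str,
    reference: str,
    treatment: str,
    maxiter: int = 100,
    tol: float = 1e-8,
) -> pd.DataFrame:
    """Two-group NB Wald test within a single assay.

    Same GLM machinery as the interaction model with the reduced design
    ``log mu = log sf + b0 + b_cond [treatment]``.  Returns per-gene
    ``log2fc, se, p``.
    """
    cols = [
        s for s in counts.columns
        if samples.loc[s, "assay"] == assay
        and samples.loc[s, "condition"] in (reference, treatment)
    ]
    if not cols:
        raise ValueError(f"no {assay} samples for conditions {reference}/{treatment}")
    is_trt = np.array([samples.loc[s, "condition"] == treatment for s in cols])
    y = counts[cols].to_numpy(float)
    a = (
        dispersions.reindex(counts.index).to_numpy(float)
        if isinstance(dispersions, pd.Series)
        else float(dispersions)
    )
    fit = _two_group_fit(y, is_trt, np.log(sf[cols].to_numpy(float)), a, maxiter, tol)
    log2fc = fit.beta[:, 1] / LN2
    se = fit.se[:, 1] / LN2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, np.nan)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {"log2fc": log2fc, "se": se, "p": p, "converged": fit.converged},
        index=counts.index,
    )


@dataclass
class GeneSetSummary:
    """Class tallies of TE results over one gene set."""

    name: str
    n: int
    n_up: int
    n_down: int
    members: pd.DataFrame

    def __post_init__(self) -> None:
        assert self.n_up + self.n_down <= self.n


class TranslationalEfficiencyModel:
    """NB-GLM interaction model of translational efficiency change.

    Parameters
    ----------
    counts : DataFrame
        Genes x samples integer counts covering both assays and both
        conditions.
    samples : DataFrame
        Indexed by sample id with columns ``assay`` (ribo/rna),
        ``condition`` and ``replicate``.
    reference, treatment : str
        Condition labels; the interaction measures the TE change of
        ``treatment`` relative to ``reference``.
    size_factor_scope : str
        ``"per_assay"`` (default) or ``"joint"``.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        samples: pd.DataFrame,
        reference: str,
        treatment: str,
        size_factor_scope: str = "per_assay",
    ):
        keep = [
            s for s in counts.columns
            if samples.loc[s, "condition"] in (reference, treatment)
        ]
        self.counts = counts[keep]
        self.samples = samples.loc[keep]
        self.reference = reference
        self.treatment = treatment
        self.size_factor_scope = size_factor_scope
        cells = self.samples.groupby(["assay", "condition"]).size()
        for assay in ("ribo", "rna"):
            for cond in (reference, treatment):
                if (assay, cond) not in cells.index:
                    raise ValueError(
                        f"design lacks samples for ({assay}, {cond}); both assays "
                        "must be present in both conditions"
                    )

    @classmethod
    def from_count_table(
        cls, table: CountTable, reference: str, treatment: str, **kw
    ) -> "TranslationalEfficiencyModel":
        return cls(table.counts, table.samples, reference, treatment, **kw)

    # -----------------------------------------------------------------

    def design_matrix(self) -> pd.DataFrame:
        """Samples x {intercept, ribo, treatment, ribo:treatment}."""
        is_ribo = (self.samples["assay"] == "ribo").astype(float)
        is_trt = (self.samples["condition"] == self.treatment).astype(float)
        return pd.DataFrame(
            {
                "intercept": 1.0,
                "ribo": is_ribo,
                "treatment": is_trt,
                "ribo:treatment": is_ribo * is_trt,
            },
            index=self.samples.index,
        )

    def fit(
        self,
        dispersion: Union[None, float, pd.Series] = None,
        size_factors_: Optional[pd.Series] = None,
        alpha_min: float = 1e-8,
        maxiter: int = 100,
        tol: float = 1e-8,
        lfc_threshold: float = 1.0,
        min_mean_count: float = 5.0,
    ) -> "TEResults":
        """Fit the interaction GLM gene-wise and assemble results.

        ``dispersion=None`` triggers the moderated method-of-moments
        estimate; a scalar or per-gene Series is used as-is.
        ``size_factors_`` overrides the median-of-ratios normalization
        (e.g. known library depths).  Genes with all-zero counts are not
        fitted (class ``low_count``); non-converged genes are flagged and
        excluded from the BH correction.
        """
        counts, samples = self.counts, self.samples
        if size_factors_ is not None:
            sf = size_factors_.reindex(counts.columns).astype(float)
        else:
            sf = size_factors(counts, samples, scope=self.size_factor_scope)
        if dispersion is None:
            disp = estimate_dispersion(counts, samples, sf, alpha_min=alpha_min)
        elif isinstance(dispersion, pd.Series):
            disp = dispersion.reindex(counts.index)
        else:
            disp = pd.Series(float(dispersion), index=counts.index)
        disp = disp.clip(lower=alpha_min)

        X = self.design_matrix().to_numpy(float)
        y = counts.to_numpy(float)
        tested = y.sum(axis=1) > 0
        log_sf = np.log(sf.to_numpy(float))

        res = pd.DataFrame(index=counts.index)
        res["mean_normalized_count"] = (counts / sf).mean(axis=1)
        res["te_log2fc"] = np.nan
        res["se"] = np.nan
        res["wald_stat"] = np.nan
        res["p_value"] = np.nan
        res["converged"] = False

        if tested.any():
            fit = fit_nb_glm(
                y[tested], X, log_sf, disp.to_numpy(float)[tested],
                max_iter=maxiter, tol=tol,
            )
            te = fit.beta[:, 3] / LN2
            se = fit.se[:, 3] / LN2
            with np.errstate(divide="ignore", invalid="ignore"):
                z = np.where(se > 0, te / se, np.nan)
            p = 2.0 * stats.norm.sf(np.abs(z))
            res.loc[tested, "te_log2fc"] = te
            res.loc[tested, "se"] = se
            res.loc[tested, "wald_stat"] = z
            res.loc[tested, "p_value"] = p
            res.loc[tested, "converged"] = fit.converged
            n_bad = int((~fit.converged).sum())
            if n_bad:
                logger.warning("%d genes did not converge; excluded from FDR", n_bad)

        res["fdr"] = np.nan
        usable = res["converged"] & res["p_value"].notna()
        if usable.any():
            res.loc[usable, "fdr"] = multipletests(
                res.loc[usable, "p_value"].to_numpy(), method="fdr_bh"
            )[1]

        for assay, col in (("rna", "rna_log2fc"), ("ribo", "ribo_log2fc")):
            sub = assay_log2fc(
                counts, samples, sf, disp, assay, self.reference, self.treatment,
                maxiter=maxiter, tol=tol,
            )
            res[col] = sub["log2fc"].where(tested, np.nan)

        results = TEResults(
            table=res,
            model=self,
            size_factors_=sf,
            dispersions_=disp,
            tested=pd.Series(tested, index=counts.index),
        )
        results.classify(lfc_threshold=lfc_threshold, min_mean_count=min_mean_count)
        return results


@dataclass
class TEResults:
    """Per-gene TE estimates, tests and classification.

    ``table`` columns: ``mean_normalized_count, te_log2fc, se, wald_stat,
    p_value, fdr, rna_log2fc, ribo_log2fc, converged, class``.
    """

    table: pd.DataFrame
    model: TranslationalEfficiencyModel
    size_factors_: pd.Series
    dispersions_: pd.Series
    tested: pd.Series

    def classify(
        self, lfc_threshold: float = 1.0, min_mean_count: float = 5.0
    ) -> pd.Series:
        """Twofold-style classification on the point estimate.

        ``up`` iff ``te_log2fc > lfc_threshold`` (strict, per "greater than
        twofold"), ``down`` iff below ``-lfc_threshold``; genes with mean
        normalized count under ``min_mean_count``, all-zero counts or a
        non-converged fit are ``low_count``; the rest ``unchanged``.
        """
        t = self.table
        low = (
            (t["mean_normalized_count"] < min_mean_count)
            | ~self.tested
            | ~t["converged"].astype(bool)
        )
        cls = pd.Series("unchanged", index=t.index)
        cls[t["te_log2fc"] > lfc_threshold] = "up"
        cls[t["te_log2fc"] < -lfc_threshold] = "down"
        cls[low] = "low_count"
        self.table["class"] = cls
        self.lfc_threshold = lfc_threshold
        self.min_mean_count = min_mean_count
        return cls

    @property
    def tally(self) -> Dict[str, int]:
        c = self.table["class"].value_counts()
        return {"n_up": int(c.get("up", 0)), "n_down": int(c.get("down", 0))}

    def summarize_gene_set(self, name: str, genes: Iterable[str]) -> GeneSetSummary:
        """Class tallies over a gene set (e.g. ribosome components)."""
        members = self.table.loc[self.table.index.intersection(set(genes))]
        if len(members) == 0:
            logger.warning("gene set %s has no members with TE results", name)
        c = members["class"].value_counts() if len(members) else {}
        return GeneSetSummary(
            name=name,
            n=len(members),
            n_up=int(c.get("up", 0)) if len(members) else 0,
            n_down=int(c.get("down", 0)) if len(members) else 0,
            members=members,
        )

    def summary(self, top: int = 10) -> str:
        """A human-readable fit summary (statsmodels-flavoured)."""
        m = self.model
        t = self.table
        tally = self.tally
        lines = [
            "Translational efficiency model (NB GLM, assay x condition interaction)",
            "=" * 72,
            f"contrast:        {m.treatment} vs {m.reference} (reference)",
            f"genes:           {len(t)} total, {int(self.tested.sum())} tested",
            f"size factors:    {m.size_factor_scope} median-of-ratios",
            f"dispersion:      median alpha = {float(self.dispersions_.median()):.4g}",
            f"classification:  |log2 TE change| > {self.lfc_threshold:g}, "
            f"min mean count {self.min_mean_count:g}",
            f"TE up / down:    {tally['n_up']} / {tally['n_down']}",
            "-" * 72,
            f"top {top} genes by p-value:",
        ]
        cols = ["te_log2fc", "se", "p_value", "fdr", "class"]
        head = t.dropna(subset=["p_value"]).sort_values("p_value").head(top)
        lines.append(head[cols].to_string(float_format=lambda v: f"{v:.3g}"))
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")
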