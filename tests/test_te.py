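"""Normalization, dispersion, NB-GLM interaction fit, classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import riboage as ra
from riboage.simulate import simulate_counts
from riboage.te import assay_log2fc, estimate_dispersion, size_factors


def design(n_rep=2, conditions=("young", "aged")):
    rows = []
    for assay in ("ribo", "rna"):
        for cond in conditions:
            for r in range(1, n_rep + 1):
                rows.append({"sample_id": f"{assay}_{cond}_r{r}", "assay": assay,
                             "condition": cond, "replicate": r})
    return pd.DataFrame(rows).set_index("sample_id")


def exact_counts(n_rep, cells, n_genes=1):
    """Noiseless integer count matrix from per-(assay, condition) means."""
    samples = design(n_rep)
    data = {}
    for sid, row in samples.iterrows():
        data[sid] = [cells[(row["assay"], row["condition"])]] * n_genes
    idx = pd.Index([f"g{i}" for i in range(n_genes)], name="gene_id")
    return pd.DataFrame(data, index=idx), samples


class TestSizeFactors:
    def test_identical_libraries(self):
        counts, samples = exact_counts(2, {("ribo", "young"): 50,
                                           ("ribo", "aged"): 50,
                                           ("rna", "young"): 50,
                                           ("rna", "aged"): 50}, n_genes=5)
        sf = size_factors(counts, samples)
        assert np.allclose(sf, 1.0)

    def test_doubled_library(self):
        rng = np.random.default_rng(1)
        base = rng.integers(10, 200, size=30)
        counts = pd.DataFrame({"a": base, "b": 2 * base})
        samples = pd.DataFrame({"assay": ["rna", "rna"], "condition": ["x", "y"],
                                "replicate": [1, 1]}, index=["a", "b"])
        sf = size_factors(counts, samples)
        assert sf["b"] / sf["a"] == pytest.approx(2.0, rel=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        # odd gene count: the log-space median (DESeq2 convention) and the
        # ratio-space median pick the same gene
        counts = pd.DataFrame(rng.integers(1, 500, size=(41, 6)),
                              columns=[f"s{i}" for i in range(6)])
        sf = size_factors(counts, scope="joint")
        # direct median-of-ratios
        mat = counts.to_numpy(float)
        ref = np.exp(np.log(mat).mean(axis=1))
        for j, col in enumerate(counts.columns):
            assert sf[col] == pytest.approx(np.median(mat[:, j] / ref), rel=1e-12)

    def test_no_usable_genes_error(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
        with pytest.raises(ValueError, match="geometric"):
            size_factors(counts, scope="joint")


class TestDispersion:
    def test_constant_counts_floor(self):
        counts, samples = exact_counts(3, {("ribo", "young"): 50,
                                           ("ribo", "aged"): 50,
                                           ("rna", "young"): 50,
                                           ("rna", "aged"): 50}, n_genes=4)
        sf = size_factors(counts, samples)
        alpha = estimate_dispersion(counts, samples, sf, prior_df=0.0)
        assert (alpha == 1e-8).all()

    def test_poisson_limit(self):
        # Poisson data: moment estimate concentrates near zero as n grows
        rng = np.random.default_rng(3)
        samples = design(n_rep=50)
        counts = pd.DataFrame(
            {sid: rng.poisson(200.0, size=300) for sid in samples.index})
        sf = size_factors(counts, samples)
        alpha = estimate_dispersion(counts, samples, sf, prior_df=0.0)
        assert float(alpha.median()) < 0.01

    def test_nb_moment_calibration(self):
        # alpha = 0.1, 50 replicates: estimate within [0.05, 0.2] for >= 95%
        hits = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            samples = design(n_rep=50)
            mu, a = 200.0, 0.1
            counts = pd.DataFrame(
                {sid: rng.negative_binomial(1 / a, 1 / (1 + a * mu), size=50)
                 for sid in samples.index})
            sf = size_factors(counts, samples)
            alpha = estimate_dispersion(counts, samples, sf, prior_df=0.0)
            hits.append(((alpha >= 0.05) & (alpha <= 0.2)).mean())
        assert np.mean(hits) >= 0.95

    def test_single_replicate_error(self):
        counts, samples = exact_counts(1, {("ribo", "young"): 5,
                                           ("ribo", "aged"): 5,
                                           ("rna", "young"): 5,
                                           ("rna", "aged"): 5})
        sf = size_factors(counts, samples)
        with pytest.raises(ValueError, match="replicates"):
            estimate_dispersion(counts, samples, sf)


class TestInteractionFit:
    def test_closed_form_interaction(self):
        # ribo FC 4, rna FC 2 between conditions -> te_log2fc = log2(4/2) = 1
        counts, samples = exact_counts(
            3, {("rna", "young"): 100, ("rna", "aged"): 200,
                ("ribo", "young"): 100, ("ribo", "aged"): 400})
        model = ra.TranslationalEfficiencyModel(counts, samples, "young", "aged")
        sf1 = pd.Series(1.0, index=counts.columns)
        res = model.fit(dispersion=1e-8, size_factors_=sf1)
        assert res.table["te_log2fc"].iloc[0] == pytest.approx(1.0, abs=1e-4)
        assert res.table["rna_log2fc"].iloc[0] == pytest.approx(1.0, abs=1e-4)
        assert res.table["ribo_log2fc"].iloc[0] == pytest.approx(2.0, abs=1e-4)

    def test_no_interaction_when_assays_move_together(self):
        counts, samples = exact_counts(
            2, {("rna", "young"): 100, ("rna", "aged"): 300,
                ("ribo", "young"): 50, ("ribo", "aged"): 150})
        res = ra.TranslationalEfficiencyModel(counts, samples, "young", "aged").fit(
            dispersion=1e-8, size_factors_=pd.Series(1.0, index=counts.columns))
        assert res.table["te_log2fc"].iloc[0] == pytest.approx(0.0, abs=1e-4)

    def test_matches_statsmodels_oracle(self):
        # independent fit of the same NB likelihood
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        samples = design(2)
        counts = pd.DataFrame(
            {sid: rng.integers(20, 400, size=6) for sid in samples.index})
        model = ra.TranslationalEfficiencyModel(counts, samples, "young", "aged")
        alpha = 0.05
        res = model.fit(dispersion=alpha)
        X = model.design_matrix().to_numpy(float)
        sf = res.size_factors_
        for i, gid in enumerate(counts.index):
            y = counts.loc[gid].to_numpy(float)
            sm_fit = sm.GLM(
                y, X, family=sm.families.NegativeBinomial(alpha=alpha),
                offset=np.log(sf.to_numpy(float)),
            ).fit()
            te = sm_fit.params[3] / np.log(2)
            assert res.table["te_log2fc"].loc[gid] == pytest.approx(te, abs=1e-4)

    def test_condition_swap_negates_estimate(self):
        rng = np.random.default_rng(6)
        samples = design(3)
        counts = pd.DataFrame(
            {sid: rng.integers(30, 300, size=20) for sid in samples.index})
        fwd = ra.TranslationalEfficiencyModel(counts, samples, "young", "aged").fit(
            dispersion=0.05)
        rev = ra.TranslationalEfficiencyModel(counts, samples, "aged", "young").fit(
            dispersion=0.05)
        assert np.allclose(fwd.table["te_log2fc"], -rev.table["te_log2fc"],
                           atol=1e-5)
        assert np.allclose(fwd.table["p_value"], rev.table["p_value"], atol=1e-6)

    def test_scaling_invariance(self):
        # noiseless data (identical replicates): rescaling one library and
        # its size factor is an exact symmetry of the fit
        rng = np.random.default_rng(8)
        samples = design(2)
        cell_means = {
            (assay, cond): rng.integers(20, 200, size=15)
            for assay in ("ribo", "rna") for cond in ("young", "aged")
        }
        counts = pd.DataFrame(
            {sid: cell_means[(row["assay"], row["condition"])]
             for sid, row in samples.iterrows()})
        res1 = ra.TranslationalEfficiencyModel(counts, samples, "young", "aged").fit(
            dispersion=1e-10)
        scaled = counts.copy()
        scaled["ribo_aged_r1"] = 2 * scaled["ribo_aged_r1"]
        res2 = ra.TranslationalEfficiencyModel(scaled, samples, "young", "aged").fit(
            dispersion=1e-10)
        # the geometric-mean reference moves too: with S samples in scope the
        # scaled sample's factor grows by c**(1 - 1/S); here S = 4 ribo samples
        assert res2.size_factors_["ribo_aged_r1"] == pytest.approx(
            2 ** (1 - 1 / 4) * res1.size_factors_["ribo_aged_r1"], rel=1e-9)
        # ... and the residual c**(1/S) shifts every normalized count equally,
        # so it lands in the intercept and the TE estimates are unchanged
        assert np.allclose(res1.table["te_log2fc"], res2.table["te_log2fc"],
                           atol=1e-6)

    def test_all_zero_gene_low_count(self):
        counts, samples = exact_counts(
            2, {("rna", "young"): 100, ("rna", "aged"): 100,
                ("ribo", "young"): 100, ("ribo", "aged"): 100}, n_genes=3)
        counts.iloc[1] = 0
        res = ra.TranslationalEfficiencyModel(counts, samples, "young", "aged").fit(
            dispersion=0.05)
        assert res.table["class"].iloc[1] == "low_count"
        assert np.isnan(res.table["p_value"].iloc[1])

    def test_missing_cell_error(self):
        counts, samples = exact_counts(
            2, {("rna", "young"): 10, ("rna", "aged"): 10,
                ("ribo", "young"): 10, ("ribo", "aged"): 10})
        drop = [s for s in counts.columns if not s.startswith("ribo_aged")]
        with pytest.raises(ValueError, match="ribo"):
            ra.TranslationalEfficiencyModel(counts[drop], samples.loc[drop],
                                            "young", "aged")

    def test_bh_monotone_and_dominates_p(self):
        cfg = ra.SimConfig(n_genes=300, n_replicates=3, n_ncrna=0,
                           dispersion=0.05, frac_te_up=0.1, seed=21)
        genes, _ = ra.simulate_transcriptome(cfg)
        truth = ra.simulate_truth(cfg, genes)
        counts, samples = simulate_counts(cfg, genes, truth)
        res = ra.TranslationalEfficiencyModel(counts, samples, "young", "aged").fit()
        t = res.table.dropna(subset=["p_value", "fdr"]).sort_values("p_value")
        assert (t["fdr"] >= t["p_value"] - 1e-12).all()
        assert (np.diff(t["fdr"].to_numpy()) >= -1e-12).all()


class TestAssayLog2fc:
    def test_doubled_means_noiseless(self):
        counts, samples = exact_counts(
            2, {("rna", "young"): 100, ("rna", "aged"): 200,
                ("ribo", "young"): 70, ("ribo", "aged"): 70})
        sf = pd.Series(1.0, index=counts.columns)
        out = assay_log2fc(counts, samples, sf, 1e-8, "rna", "young", "aged")
        assert out["log2fc"].iloc[0] == pytest.approx(1.0, abs=1e-4)

    def test_txn_effect_recovery(self):
        cfg = ra.SimConfig(n_genes=400, n_replicates=3, n_ncrna=0,
                           mean_expression=300.0, dispersion=0.05,
                           frac_txn=0.5, txn_effect_log2=1.0, seed=31)
        genes, _ = ra.simulate_transcriptome(cfg)
        truth = ra.simulate_truth(cfg, genes)
        counts, samples = simulate_counts(cfg, genes, truth)
        sf = size_factors(counts, samples)
        out = assay_log2fc(counts, samples, sf, 0.05, "rna", "young", "aged")
        up = truth.index[truth["txn_log2fc_aged"] == 1.0]
        assert abs(out.loc[up, "log2fc"].mean() - 1.0) < 0.1

    def test_rna_ribo_correlation_under_null_te(self):
        # both assays estimate the same transcription effect
        cfg = ra.SimConfig(n_genes=500, n_replicates=3, n_ncrna=0,
                           mean_expression=300.0, dispersion=0.05,
                           frac_txn=0.6, txn_effect_log2=1.5, seed=32)
        genes, _ = ra.simulate_transcriptome(cfg)
        truth = ra.simulate_truth(cfg, genes)
        counts, samples = simulate_counts(cfg, genes, truth)
        res = ra.TranslationalEfficiencyModel(counts, samples, "young", "aged").fit()
        t = res.table.dropna(subset=["rna_log2fc", "ribo_log2fc"])
        r = np.corrcoef(t["rna_log2fc"], t["ribo_log2fc"])[0, 1]
        assert r >= 0.9


class TestClassification:
    def test_threshold_is_strict(self):
        counts, samples = exact_counts(
            2, {("rna", "young"): 100, ("rna", "aged"): 100,
                ("ribo", "young"): 100, ("ribo", "aged"): 200})
        res = ra.TranslationalEfficiencyModel(counts, samples, "young", "aged").fit(
            dispersion=1e-8, size_factors_=pd.Series(1.0, index=counts.columns))
        # exactly twofold: "greater than twofold" is strict, so unchanged
        assert res.table["te_log2fc"].iloc[0] == pytest.approx(1.0, abs=1e-5)
        assert res.table["class"].iloc[0] == "unchanged"

    def test_all_null_noiseless_no_calls(self):
        counts, samples = exact_counts(
            3, {("rna", "young"): 80, ("rna", "aged"): 80,
                ("ribo", "young"): 90, ("ribo", "aged"): 90}, n_genes=10)
        res = ra.TranslationalEfficiencyModel(counts, samples, "young", "aged").fit(
            dispersion=1e-8)
        assert res.tally == {"n_up": 0, "n_down": 0}

    def test_low_count_gate(self):
        counts, samples = exact_counts(
            2, {("rna", "young"): 1, ("rna", "aged"): 4,
                ("ribo", "young"): 1, ("ribo", "aged"): 1})
        res = ra.TranslationalEfficiencyModel(counts, samples, "young", "aged").fit(
            dispersion=0.05, min_mean_count=5.0)
        assert res.table["class"].iloc[0] == "low_count"

    def test_gene_set_summary_counts(self):
        cfg = ra.SimConfig(n_genes=200, n_replicates=3, n_ncrna=0,
                           mean_expression=500.0, dispersion=0.02,
                           frac_te_up=0.1, frac_te_down=0.1,
                           te_effect_log2=1.8, seed=41)
        genes, _ = ra.simulate_transcriptome(cfg)
        truth = ra.simulate_truth(cfg, genes)
        counts, samples = simulate_counts(cfg, genes, truth)
        res = ra.TranslationalEfficiencyModel(counts, samples, "young", "aged").fit()
        chosen = list(res.table.index[:30])
        summary = res.summarize_gene_set("first30", chosen)
        cls = res.table.loc[chosen, "class"]
        assert summary.n == 30
        assert summary.n_up == int((cls == "up").sum())
        assert summary.n_down == int((cls == "down").sum())
        empty = res.summarize_gene_set("none", ["zzz"])
        assert empty.n == 0 and empty.n_up == 0

    def test_summary_renders(self):
        counts, samples = exact_counts(
            2, {("rna", "young"): 100, ("rna", "aged"): 100,
                ("ribo", "young"): 100, ("ribo", "aged"): 500}, n_genes=3)
        res = ra.TranslationalEfficiencyModel(counts, samples, "young", "aged").fit(
            dispersion=0.01)
        text = res.summary()
        assert "aged vs young" in text and "TE up / down" in text
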