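"""CDS counting rules, read accounting, intron and frameshift analyses."""

import numpy as np
import pandas as pd
import pytest

import riboage as ra
from riboage.quantify import count_cds, count_intron_reads, filter_ncrna, frame_in_window

from conftest import brute_force_count_cds, make_reads


GENE = ra.GeneModel("gA", 200, cds_start=30, cds_end=120)  # 30 codons
NC = ra.GeneModel("ncA", 300, coding=False)
OFF28 = ra.OffsetTable({28: 15})


class TestFilterNcrna:
    def test_all_coding(self):
        reads = make_reads([("gA", 10, 28)] * 4)
        kept, removed = filter_ncrna(reads, [GENE, NC])
        assert removed == 0 and len(kept) == 4

    def test_enumerated_removal(self):
        reads = make_reads([("gA", 10, 28)] * 15 + [("ncA", 5, 28)] * 5)
        kept, removed = filter_ncrna(reads, [GENE, NC])
        assert removed == 5 and len(kept) == 15
        assert (kept["transcript_id"] == "gA").all()

    def test_unknown_transcript_error(self):
        with pytest.raises(KeyError, match="ghost"):
            filter_ncrna(make_reads([("ghost", 0, 28)]), [GENE])

    def test_empty(self):
        kept, removed = filter_ncrna(make_reads([]), [GENE])
        assert removed == 0 and len(kept) == 0


class TestCountCds:
    def test_one_asite_per_codon(self):
        # 30 codons, excl 5 on each side -> 20 counted
        rows = [("gA", GENE.cds_start + 3 * k - 15, 28) for k in range(30)]
        table = count_cds(make_reads(rows), [GENE], OFF28)
        assert table.counts.loc["gA"].sum() == 20
        assert table.accounting_consistent()

    def test_edge_codon_excluded(self):
        read = make_reads([("gA", GENE.cds_start + 3 * 2 - 15, 28)])  # codon 2
        table = count_cds(read, [GENE], OFF28)
        assert table.counts.loc["gA"].sum() == 0
        assert table.sidecar["edge_codon_excluded"].sum() == 1

    def test_no_reads_zero_matrix(self):
        table = count_cds(make_reads([]), [GENE], OFF28)
        assert list(table.counts.index) == ["gA"]
        assert table.counts.to_numpy().sum() == 0

    def test_negative_exclusion_error(self):
        with pytest.raises(ValueError, match="exclude_codons"):
            count_cds(make_reads([]), [GENE], OFF28, exclude_codons=-1)

    def test_rna_uses_fixed_offset(self):
        # length 50 has no ribo offset; RNA counting ignores length
        read = make_reads([("gA", GENE.cds_start + 45 - 15, 50, "s1", "rna")])
        table = count_cds(read, [GENE], OFF28, assay="rna")
        assert table.counts.loc["gA"].sum() == 1

    def test_monotone_in_exclusion(self, rich_dataset, paper_offsets):
        reads, genes = rich_dataset.reads, rich_dataset.genes
        prev = None
        for excl in (0, 2, 5, 8):
            tab = count_cds(reads, genes, paper_offsets, exclude_codons=excl)
            tot = tab.counts.to_numpy()
            if prev is not None:
                assert (tot <= prev).all()
            prev = tot

    def test_accounting_partition(self, rich_dataset, paper_offsets):
        for assay in ("ribo", "rna"):
            tab = count_cds(rich_dataset.reads, rich_dataset.genes, paper_offsets,
                            assay=assay)
            assert tab.accounting_consistent()
            n_assay = (rich_dataset.reads["assay"] == assay).sum()
            assert tab.sidecar["total"].sum() == n_assay

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        offsets = ra.OffsetTable({21: 15, 26: 13, 28: 15, 30: 16})
        for trial in range(30):
            genes = []
            for i in range(rng.integers(2, 8)):
                n_codons = int(rng.integers(8, 60))
                utr = int(rng.integers(0, 40))
                tail = int(rng.integers(20, 60))
                genes.append(ra.GeneModel(
                    f"g{i}", utr + 3 * n_codons + tail, utr, utr + 3 * n_codons))
            genes.append(ra.GeneModel(f"nc{trial}", 150, coding=False))
            rows = []
            ids = [g.gene_id for g in genes]
            for _ in range(int(rng.integers(50, 400))):
                g = genes[rng.integers(0, len(genes))]
                length = int(rng.choice([21, 26, 28, 30, 33]))
                fp = int(rng.integers(0, max(g.length - length, 1)))
                rows.append((g.gene_id, fp, length,
                             f"s{rng.integers(1, 3)}",
                             "ribo" if rng.random() < 0.7 else "rna"))
            reads = make_reads(rows)
            excl = int(rng.integers(0, 7))
            for assay in ("ribo", "rna"):
                table = count_cds(reads, genes, offsets, assay=assay,
                                  exclude_codons=excl)
                oracle = brute_force_count_cds(reads, genes, offsets, assay, excl)
                for (gid, sid), n in oracle.items():
                    assert table.counts.loc[gid, sid] == n
                assert table.counts.to_numpy().sum() == sum(oracle.values())
                assert table.accounting_consistent()


INTRON_GENE = ra.GeneModel("gI", 500, cds_start=30, cds_end=390, intron=(400, 460))


class TestIntronReads:
    def test_read_inside_intron(self):
        reads = make_reads([("gI", 410, 28, "s1", "rna")])
        ic = count_intron_reads(reads, INTRON_GENE)
        assert ic.table.loc["s1", "intron_containing"] == 1

    def test_abutting_half_open_boundary(self):
        # read ends exactly at intron start: zero overlap
        reads = make_reads([("gI", 372, 28, "s1", "rna")])
        ic = count_intron_reads(reads, INTRON_GENE)
        assert ic.table["intron_containing"].sum() == 0

    def test_one_nt_overlap_counts(self):
        reads = make_reads([("gI", 373, 28, "s1", "rna")])
        ic = count_intron_reads(reads, INTRON_GENE)
        assert ic.table.loc["s1", "intron_containing"] == 1

    def test_contained_mode_stricter(self):
        reads = make_reads([("gI", 373, 28, "s1", "rna"), ("gI", 420, 28, "s1", "rna")])
        assert count_intron_reads(reads, INTRON_GENE, "overlap").table[
            "intron_containing"].sum() == 2
        assert count_intron_reads(reads, INTRON_GENE, "contained").table[
            "intron_containing"].sum() == 1

    def test_junction_flag_separates(self):
        reads = make_reads([("gI", 380, 28, "s1", "rna", True)])
        ic = count_intron_reads(reads, INTRON_GENE)
        assert ic.table.loc["s1", "junction_spanning"] == 1
        assert ic.table.loc["s1", "intron_containing"] == 0

    def test_no_intron_error(self):
        with pytest.raises(ValueError, match="intron"):
            count_intron_reads(make_reads([]), GENE)

    def test_generative_fraction(self):
        # intron_containing / (intron_containing + junction_spanning) matches
        # the placement-geometry expectation computed by brute enumeration
        spec = ra.IntronGeneSpec(unspliced_fraction={"young": 0.3})
        cfg = ra.SimConfig(
            n_genes=1, n_replicates=10, conditions=("young",), n_ncrna=0,
            mean_expression=3000.0, mean_expression_log_sd=0.0,
            intron_gene=spec, seed=8,
        )
        ds = ra.simulate_dataset(cfg)
        gene = [g for g in ds.genes if g.intron][0]
        rna = ds.reads[ds.reads["assay"] == "rna"]
        ic = count_intron_reads(rna, gene)
        n_in = int(ic.table["intron_containing"].sum())
        n_j = int(ic.table["junction_spanning"].sum())
        assert n_in + n_j > 1500

        # brute-force enumeration of fragment placements
        i0, i1 = gene.intron
        ilen = i1 - i0
        u = 0.3
        p_hit_u, p_cross_s = 0.0, 0.0
        for length, pl in cfg.length_dist.items():
            npos_u = gene.length - length + 1
            hits = sum(1 for s in range(npos_u) if s < i1 and s + length > i0)
            p_hit_u += pl * hits / npos_u
            ls = gene.length - ilen
            npos_s = ls - length + 1
            crosses = sum(1 for s in range(npos_s) if s < i0 and s + length > i0)
            p_cross_s += pl * crosses / npos_s
        expected = u * p_hit_u / (u * p_hit_u + (1 - u) * p_cross_s)
        frac = n_in / (n_in + n_j)
        se = np.sqrt(expected * (1 - expected) / (n_in + n_j))
        assert abs(frac - expected) < 3 * se + 0.01


class TestFrameInWindow:
    FAM = ra.ElementFamilySpec()
    TY = ra.GeneModel("ty01", FAM.transcript_length(), FAM.orf_a[0], FAM.orf_a[1],
                      family_id="family")

    def _family_reads(self, fidelity):
        cfg = ra.SimConfig(
            n_genes=1, n_replicates=1, conditions=("young",), n_ncrna=0,
            frame_fidelity=fidelity, mean_expression=2000.0,
            mean_expression_log_sd=0.0, element_family=self.FAM, seed=3,
        )
        ds = ra.simulate_dataset(cfg)
        return ds.reads[(ds.reads["assay"] == "ribo")
                        & (ds.reads["transcript_id"] == "ty01")]

    def test_orf_a_window_frame0(self, paper_offsets):
        reads = self._family_reads(fidelity=1.0)
        res = frame_in_window(reads, self.TY, paper_offsets,
                              window=(self.FAM.orf_a[0], self.FAM.frameshift_pos))
        assert res["frame0"] == 1.0 and res["n"] > 100

    def test_downstream_of_shift_frame1(self, paper_offsets):
        reads = self._family_reads(fidelity=1.0)
        res = frame_in_window(reads, self.TY, paper_offsets,
                              window=(self.FAM.orf_a[1], self.FAM.orf_b[1]))
        assert res["frame1"] == 1.0 and res["n"] > 100

    def test_mixture_window(self, paper_offsets):
        reads = self._family_reads(fidelity=1.0)
        res = frame_in_window(reads, self.TY, paper_offsets,
                              window=(self.FAM.orf_a[0], self.FAM.orf_b[1]))
        assert 0 < res["frame0"] < 1 and 0 < res["frame1"] < 1
        assert res["frame0"] + res["frame1"] == pytest.approx(1.0)

    def test_empty_window_error(self, paper_offsets):
        with pytest.raises(ValueError, match="window"):
            frame_in_window(make_reads([]), self.TY, paper_offsets, window=(50, 50))
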