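"""Genetic-model contingency tables and the five differentiation tests."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from sweepscan.genodiff import (
    chisq_2x3,
    cochran_armitage,
    fisher_exact_2x2,
    model_table,
    scan_differentiated_loci,
)

from conftest import make_dataset


def fisher_by_enumeration(table):
    """Two-sided Fisher p by exhaustive fixed-margin enumeration."""
    a, b = table[0]
    c, d = table[1]
    r1, c1, n = a + b, a + c, a + b + c + d
    p_obs = hypergeom.pmf(a, n, r1, c1)
    total = 0.0
    for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        p = hypergeom.pmf(x, n, r1, c1)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(total, 1.0)


class TestModelTable:
    def test_dominant_carriers(self):
        t = model_table((6, 3, 1), (10, 0, 0), "dominant")
        assert t[0].tolist() == [4, 6]
        assert t[1].tolist() == [0, 10]

    def test_allelic_counts(self):
        t = model_table((6, 3, 1), (0, 0, 10), "allelic")
        assert t[0].tolist() == [5, 15]
        assert t[1].tolist() == [20, 0]

    def test_recessive(self):
        t = model_table((0, 0, 10), (10, 0, 0), "recessive")
        assert t[0].tolist() == [10, 0]
        assert t[1].tolist() == [0, 10]

    def test_codominant_and_trend_keep_triples(self):
        for model in ("codominant", "trend"):
            t = model_table((6, 3, 1), (2, 5, 3), model)
            assert t.shape == (2, 3)
            assert t.sum() == 20

    def test_unknown_model(self):
        with pytest.raises(ValueError):
            model_table((1, 1, 1), (1, 1, 1), "overdominant")


class TestFisher:
    def test_symmetric_table_p_one(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_perfect_separation_value(self):
        # only the two extreme tables are as or more extreme: 2 / C(20,10)
        assert fisher_exact_2x2([[10, 0], [0, 10]]) == pytest.approx(2 / 184_756)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(80):
            cells = rng.integers(0, 11, size=4)
            table = cells.reshape(2, 2)
            if table.sum() == 0:
                continue
            assert fisher_exact_2x2(table) == pytest.approx(
                fisher_by_enumeration(table), rel=1e-9
            )

    def test_shape_checked(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, 2, 3], [4, 5, 6]])


class TestChisq:
    def test_identical_rows_p_one(self):
        assert chisq_2x3([[5, 3, 2], [5, 3, 2]]) == pytest.approx(1.0)

    def test_empty_column_dropped_df_one(self):
        # [[10,0,0],[0,0,10]] -> middle column empty -> 2x2, Pearson stat 20
        p = chisq_2x3([[10, 0, 0], [0, 0, 10]])
        from scipy.stats import chi2

        assert p == pytest.approx(chi2.sf(20.0, df=1), rel=1e-9)

    def test_matches_pearson_formula(self):
        rng = np.random.default_rng(13)
        for _ in range(40):
            t = rng.integers(1, 12, size=(2, 3)).astype(float)
            expected = np.outer(t.sum(1), t.sum(0)) / t.sum()
            stat = ((t - expected) ** 2 / expected).sum()
            from scipy.stats import chi2

            assert chisq_2x3(t.astype(int)) == pytest.approx(chi2.sf(stat, df=2), rel=1e-9)

    def test_zero_row_raises(self):
        with pytest.raises(ValueError):
            chisq_2x3([[0, 0, 0], [1, 2, 3]])


class TestCochranArmitage:
    def test_identical_rows_p_one(self):
        assert cochran_armitage([[4, 3, 3], [4, 3, 3]]) == pytest.approx(1.0)

    def test_maximal_trend_closed_form(self):
        # hand/independently verified: chi2 = 20, p = 7.744216e-06
        assert cochran_armitage([[10, 0, 0], [0, 0, 10]]) == pytest.approx(
            7.744216431044088e-06, rel=1e-9
        )

    def test_generic_value_frozen_from_r(self):
        # R prop.trend.test(c(8,4,1), c(10,6,4)): X2 = 3.462439, p = 0.06277764
        assert cochran_armitage([[8, 4, 1], [2, 2, 3]]) == pytest.approx(
            0.06277764, rel=1e-6
        )

    def test_affine_weight_invariance(self):
        t = [[7, 2, 1], [3, 4, 3]]
        p0 = cochran_armitage(t, weights=(0, 1, 2))
        assert cochran_armitage(t, weights=(0, 2, 4)) == pytest.approx(p0, rel=1e-12)
        assert cochran_armitage(t, weights=(5, 6, 7)) == pytest.approx(p0, rel=1e-12)

    def test_zero_trend_variance_p_one(self):
        assert cochran_armitage([[10, 0, 0], [10, 0, 0]]) == pytest.approx(1.0)


class TestScanDifferentiatedLoci:
    @staticmethod
    def _gene_df():
        return pd.DataFrame(
            [{"id": "gA", "chrom": "chr1", "start": 40_000, "end": 42_000,
              "strand": "+", "coverage": np.nan}]
        )

    def test_identical_distributions_not_flagged(self, wf_panel):
        haps = np.tile([[0], [1]], (10, 1)).astype(np.uint8)  # every sample 0|1
        ds = make_dataset(haps, [41_000], n_wild=5)
        out = scan_differentiated_loci(ds, wf_panel(ds), "farm", genes=self._gene_df())
        assert out["p_min"].iloc[0] == pytest.approx(1.0)
        assert not out["differentiating"].iloc[0]

    def test_fixed_difference_flagged_under_every_model(self, wf_panel):
        # wild all homref, farm all homalt, 10+10 diploids, SNP inside gene
        haps = np.vstack([np.zeros((20, 1)), np.ones((20, 1))]).astype(np.uint8)
        ds = make_dataset(haps, [41_000], n_wild=10)
        out = scan_differentiated_loci(ds, wf_panel(ds), "farm", genes=self._gene_df())
        row = out.iloc[0]
        for model in ("dominant", "recessive", "codominant", "allelic", "trend"):
            assert row[f"p_{model}"] < 0.05
        assert row["differentiating"] and row["in_genic_flank"]
        assert row["nearest_gene_id"] == "gA"

    @pytest.mark.parametrize(
        "pos,expected",
        [(34_999, False), (35_000, True), (36_001, True), (47_000, True), (47_001, False)],
    )
    def test_flank_boundary_exactly_5kb(self, wf_panel, pos, expected):
        haps = np.vstack([np.zeros((20, 1)), np.ones((20, 1))]).astype(np.uint8)
        ds = make_dataset(haps, [pos], n_wild=10)
        out = scan_differentiated_loci(ds, wf_panel(ds), "farm", genes=self._gene_df())
        assert bool(out["in_genic_flank"].iloc[0]) is expected
        assert bool(out["differentiating"].iloc[0]) is expected

    def test_monomorphic_sites_skipped(self, wf_panel):
        haps = np.hstack([np.ones((40, 1)), np.zeros((40, 1)),
                          np.vstack([np.zeros((20, 1)), np.ones((20, 1))])]).astype(np.uint8)
        ds = make_dataset(haps, [10, 20, 30], n_wild=10)
        out = scan_differentiated_loci(ds, wf_panel(ds), "farm")
        assert out["pos"].tolist() == [30]

    def test_candidate_bin_membership(self, wf_panel):
        haps = np.vstack([np.zeros((20, 1)), np.ones((20, 1))]).astype(np.uint8)
        ds = make_dataset(haps, [41_000], n_wild=10)
        cand = pd.DataFrame(
            [{"chrom": "chr1", "start": 1, "end": 50_001, "is_candidate": True}]
        )
        out = scan_differentiated_loci(
            ds, wf_panel(ds), "farm", genes=self._gene_df(), candidate_bins=cand
        )
        assert bool(out["in_candidate_bin"].iloc[0])
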