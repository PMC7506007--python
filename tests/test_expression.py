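"""Differential-expression statistics: normalization, NB Wald test, call
rules, dual-reference filter and candidate intersection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hybgen import expression as ex
from hybgen import simulate as sim


class TestSizeFactors:
    def test_hand_worked_example(self):
        counts = pd.DataFrame({"A": [10, 20, 30], "B": [20, 40, 60]})
        sf = ex.size_factors(counts)
        assert np.allclose(sf, [0.7071, 1.4142], atol=1e-4)

    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"A": [5, 9, 2], "B": [5, 9, 2], "C": [5, 9, 2]})
        assert np.allclose(ex.size_factors(counts), 1.0)

    def test_single_sample_unit_factor(self):
        assert ex.size_factors(pd.DataFrame({"A": [3, 4]})).tolist() == [1.0]

    def test_no_common_nonzero_gene_raises_then_fallback_works(self):
        counts = pd.DataFrame({"A": [5, 0], "B": [0, 7]})
        with pytest.raises(ValueError, match="pseudo-reference"):
            ex.size_factors(counts)
        sf = ex.size_factors(counts, fallback=True)
        assert (sf > 0).all()

    def test_normalized_medians_of_ratios_are_one(self, rng):
        arch = sim.RegulatoryArchitecture.build(500, alpha=0.05)
        design = sim.make_design(6, seed=rng)
        counts, _ = sim.simulate_expression(arch, design, rng)
        sf = ex.size_factors(counts)
        m = counts.to_numpy(dtype=float)
        nz = (m > 0).all(axis=1)
        geo = np.exp(np.mean(np.log(m[nz]), axis=1))
        norm_ratios = (m[nz] / sf.to_numpy()[None, :]) / geo[:, None]
        assert np.allclose(np.median(norm_ratios, axis=0), 1.0, atol=1e-8)


class TestGeneMerge:
    def test_fragments_summed(self):
        counts = pd.DataFrame({"s1": [1, 2, 10], "s2": [3, 4, 10]},
                              index=["gA.1", "gA.2", "gB"])
        merged = ex.merge_gene_fragments(
            counts, pd.DataFrame({"fragment": ["gA.1", "gA.2"], "gene": ["gA", "gA"]}))
        assert merged.loc["gA"].tolist() == [3, 7]
        assert merged.loc["gB"].tolist() == [10, 10]


def matrix_from(arch, n_per_group, seed):
    design = sim.make_design(n_per_group)
    counts, design = sim.simulate_expression(arch, design, seed)
    return ex.ExpressionMatrix(counts, design).normalize()


class TestNBDETest:
    def test_null_type_one_error_near_nominal(self):
        arch = sim.RegulatoryArchitecture.build(600, mean_expr=200, alpha=0.05)
        res = ex.nb_de_test(matrix_from(arch, 10, 100), ("group", "mel", "cyd"))
        rate = (res["p"] < 0.05).mean()
        assert 0.02 < rate < 0.09

    def test_swapping_contrast_negates_log2fc(self):
        arch = sim.RegulatoryArchitecture.build(60, alpha=0.05,
                                                trans=np.linspace(-1, 1, 60))
        mat = matrix_from(arch, 6, 101)
        fwd = ex.nb_de_test(mat, ("group", "mel", "cyd"))
        rev = ex.nb_de_test(mat, ("group", "cyd", "mel"))
        assert np.allclose(fwd["log2fc"], -rev["log2fc"], atol=1e-6)

    def test_all_zero_gene_untestable(self):
        arch = sim.RegulatoryArchitecture.build(30, alpha=0.05)
        mat = matrix_from(arch, 5, 102)
        mat.counts.iloc[0] = 0
        res = ex.nb_de_test(mat, ("group", "mel", "cyd"))
        assert np.isnan(res.iloc[0]["p"]) and not res.iloc[0]["called"]

    def test_absent_contrast_level_raises(self):
        arch = sim.RegulatoryArchitecture.build(10)
        with pytest.raises(ValueError):
            ex.nb_de_test(matrix_from(arch, 4, 103), ("group", "mel", "hec"))

    def test_padj_at_least_p_and_bh_monotone(self):
        arch = sim.RegulatoryArchitecture.build(300, alpha=0.05,
                                                trans=np.r_[np.zeros(280), np.full(20, 1.5)])
        res = ex.nb_de_test(matrix_from(arch, 8, 104), ("group", "mel", "cyd"))
        ok = res["p"].notna()
        assert (res.loc[ok, "padj"] >= res.loc[ok, "p"] - 1e-12).all()
        srt = res.loc[ok].sort_values("p")
        assert (np.diff(srt["padj"]) >= -1e-12).all()
        assert srt["padj"].between(0, 1).all()

    def test_recovery_of_true_fold_changes(self):
        tr = np.r_[np.zeros(500), np.full(50, 2.0), np.full(50, -2.0)]
        arch = sim.RegulatoryArchitecture.build(600, mean_expr=200, alpha=0.05, trans=tr)
        res = ex.nb_de_test(matrix_from(arch, 10, 105), ("group", "mel", "cyd"))
        up = res["log2fc"].to_numpy()[500:550]
        dn = res["log2fc"].to_numpy()[550:]
        assert abs(up.mean() - 2.0) < 0.1 and abs(dn.mean() + 2.0) < 0.1
        called = res["called"].to_numpy()
        assert called[500:].mean() >= 0.9


class TestCallRules:
    @pytest.mark.parametrize("padj,lfc,called", [
        (0.01, 0.9, False),   # fails the twofold rule
        (0.06, 2.0, False),   # fails FDR
        (0.01, -1.3, True),
    ])
    def test_twofold_fdr_rule(self, padj, lfc, called):
        res = pd.DataFrame({"gene": ["g"], "log2fc": [lfc], "padj": [padj]})
        assert (("g" in ex.de_call(res)) is called)

    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_bh_adjustment_bounds(self, ps):
        from statsmodels.stats.multitest import multipletests
        padj = multipletests(ps, method="fdr_bh")[1]
        assert np.all(padj >= np.asarray(ps) - 1e-12) and np.all(padj <= 1.0)


class TestReferenceBiasFilter:
    def res(self, gene, lfc, padj):
        return pd.DataFrame({"gene": [gene], "log2fc": [lfc], "padj": [padj]})

    @pytest.mark.parametrize("lfc_b,padj_b,survives", [
        (-0.8, 0.01, False),   # reversal of the fold change
        (1.1, 0.01, True),
        (0.3, 0.01, False),    # not DE under the other reference
        (1.1, 0.2, False),
    ])
    def test_consistency_rules(self, lfc_b, padj_b, survives):
        a = self.res("g", 1.2, 0.01)
        b = self.res("g", lfc_b, padj_b)
        assert (("g" in ex.reference_bias_filter(a, b)) is survives)

    def test_gene_missing_in_second_reference_excluded(self):
        a = self.res("g", 1.2, 0.01)
        b = self.res("other", 1.2, 0.01)
        assert ex.reference_bias_filter(a, b) == set()


class TestCandidateIntersection:
    def setup_method(self):
        self.coords = pd.DataFrame({
            "gene": ["in_both", "species_only", "outside"],
            "chrom": ["chr18", "chr18", "chr18"],
            "pos": [1_400_000, 1_500_000, 4_000_000]})
        self.qtl = ex.Interval("chr18", 1_000_000, 3_750_000)

    def de(self, genes, lfcs, called):
        return pd.DataFrame({"gene": genes, "log2fc": lfcs, "padj": 0.01,
                             "called": called})

    def test_dominance_logic(self):
        species = self.de(["in_both", "species_only", "outside"],
                          [1.5, 1.5, 1.5], [True, True, True])
        f1 = self.de(["in_both", "species_only", "outside"],
                     [1.2, 0.1, 1.2], [True, False, True])
        out = ex.candidate_intersection(species, f1, self.qtl, self.coords)
        assert list(out["gene"]) == ["in_both"]

    def test_opposite_signs_excluded(self):
        species = self.de(["in_both"], [1.5], [True])
        f1 = self.de(["in_both"], [-1.2], [True])
        out = ex.candidate_intersection(species, f1, self.qtl, self.coords)
        assert out.empty

    def test_malformed_interval_rejected(self):
        with pytest.raises(ValueError):
            ex.Interval("chr18", 10, 10)

    def test_bc3_annotation(self):
        species = self.de(["in_both"], [1.5], [True])
        f1 = self.de(["in_both"], [1.2], [True])
        bc3 = self.de(["in_both"], [1.0], [True])
        out = ex.candidate_intersection(species, f1, self.qtl, self.coords, bc3)
        assert bool(out.iloc[0]["called_bc3"])
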