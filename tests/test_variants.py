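"""Variant filters, diagnostic markers and coding-substitution logic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hybgen import simulate as sim
from hybgen import variants as var


def rec(**kw):
    base = dict(sample="s1", chrom="chr1", pos=100, ref="A", alt="T", n_alt=1,
                gt="0/1", dp=20, gq=60, qd=10.0, fs=5.0)
    base.update(kw)
    return base


class TestRecordFilters:
    @pytest.mark.parametrize("kw,kept", [
        (dict(qd=1.5, fs=10.0, dp=20), False),   # fails QD > 2
        (dict(qd=5.0, fs=10.0, dp=4), False),    # DP bound is strict
        (dict(n_alt=2), False),                  # biallelic only
        (dict(qd=2.01, fs=29.9, dp=5), True),
        (dict(fs=30.0), False),                  # FS bound is strict
        (dict(qd=np.nan), False),                # missing field dropped
    ])
    def test_rna_filter_rules(self, kw, kept):
        df = pd.DataFrame([rec(**kw)])
        assert (len(var.filter_rna_genotypes(df)) == 1) is kept

    @pytest.mark.parametrize("kw,kept", [
        (dict(dp=10), False),                    # strict lower bound
        (dict(dp=99, gq=31), True),
        (dict(dp=50, gq=30), False),             # strict GQ > 30
        (dict(dp=100), False),                   # strict upper bound
    ])
    def test_reseq_filter_rules(self, kw, kept):
        df = pd.DataFrame([rec(**kw)])
        assert (len(var.filter_reseq_genotypes(df)) == 1) is kept

    def test_filters_idempotent(self, small_map, small_panel):
        genomes = {"s": sim.pure_genome(small_map, sim.CYD)}
        df = sim.simulate_genotype_records(
            genomes, small_panel, sim.CoverageModel(frac_fail_qd=0.2, frac_fail_fs=0.1), 3)
        once = var.filter_rna_genotypes(df)
        twice = var.filter_rna_genotypes(once)
        pd.testing.assert_frame_equal(once, twice)


def summaries(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "n_called",
                                       "n_carriers", "af"])


class TestFixedAndDiagnostic:
    def test_af_thresholds_strict(self):
        s = summaries([("c", 1, "A", "T", 10, 10, 0.95),
                       ("c", 2, "A", "T", 10, 9, 0.90),
                       ("c", 3, "A", "T", 10, 0, 0.05)])  # ref-fixed
        fixed = var.call_fixed(s)
        assert set(zip(fixed["pos"], fixed["allele"])) == {(1, "T"), (3, "A")}

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            var.call_fixed(summaries([]), af_threshold=0.4)

    def test_same_allele_in_both_species_is_not_diagnostic(self):
        mel = pd.DataFrame({"chrom": ["c"], "pos": [1], "allele": ["A"], "af": [1.0]})
        cyd = pd.DataFrame({"chrom": ["c"], "pos": [1], "allele": ["A"], "af": [1.0]})
        assert len(var.diagnostic_markers(mel, cyd)) == 0

    def test_only_shared_sites_with_opposite_alleles_are_markers(self):
        mel = pd.DataFrame({"chrom": "c", "pos": [1, 2, 3], "allele": ["A", "T", "G"],
                            "af": 1.0})
        cyd = pd.DataFrame({"chrom": "c", "pos": [1, 2], "allele": ["T", "T"],
                            "af": 1.0})
        m = var.diagnostic_markers(mel, cyd)
        assert list(m["pos"]) == [1]
        assert m.iloc[0]["allele_mel"] == "A" and m.iloc[0]["allele_cyd"] == "T"

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_marker_construction_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        def table():
            n = rng.integers(1, 20)
            return pd.DataFrame({
                "chrom": "c", "pos": rng.choice(50, n, replace=False),
                "allele": rng.choice(list("ACGT"), n), "af": 1.0})
        a, b = table(), table()
        ab = var.diagnostic_markers(a, b)
        ba = var.diagnostic_markers(b, a)
        assert len(ab) == len(ba)
        merged = ab.merge(ba, on=["chrom", "pos"], suffixes=("_ab", "_ba"))
        assert (merged["allele_mel_ab"] == merged["allele_cyd_ba"]).all()

    def test_recovers_simulator_diagnostic_sites_exactly(self, small_map, small_panel):
        # species-level summaries straight from the error-free panels
        out = {}
        for sp in (sim.MEL, sim.CYD):
            h = small_panel.haplotypes[sp]
            s = small_panel.sites.copy()
            s["af"] = h.mean(axis=1)
            s["n_called"] = h.shape[1] // 2
            s["n_carriers"] = s["n_called"]
            out[sp] = var.call_fixed(s[["chrom", "pos", "ref", "alt", "n_called",
                                        "n_carriers", "af"]], af_threshold=0.9)
        markers = var.diagnostic_markers(out[sim.MEL], out[sim.CYD])
        truth = small_panel.diagnostic_sites()
        got = set(zip(markers["chrom"], markers["pos"]))
        expect = set(zip(truth["chrom"], truth["pos"]))
        assert got == expect
        merged = markers.merge(truth, on=["chrom", "pos"], suffixes=("", "_t"))
        assert (merged["allele_mel"] == merged["allele_mel_t"]).all()


class TestCodingEffects:
    @pytest.mark.parametrize("ref,alt,effect", [
        ("GAA", "GAG", "synonymous"),    # Glu -> Glu
        ("GAA", "GTA", "missense"),      # Glu -> Val
        ("TGG", "TGA", "stop_gained"),
        ("TAA", "CAA", "stop_lost"),
    ])
    def test_effect_classes(self, ref, alt, effect):
        assert var.classify_coding_effect(ref, alt) == effect

    def test_ambiguous_codon_rejected(self):
        with pytest.raises(ValueError):
            var.classify_coding_effect("GAN", "GAA")

    def test_codon_change_plus_strand(self):
        idx, refc, altc = var.codon_change("ATGGAATTC", 4, "A", "T", "+")
        assert (idx, refc, altc) == (1, "GAA", "GTA")

    def test_codon_change_minus_strand_reverse_complements(self):
        # genomic G>A on the minus strand is C>T on the coding strand
        idx, refc, altc = var.codon_change("ATGCAATTC", 3, "G", "A", "-")
        assert (idx, refc, altc) == (1, "CAA", "TAA")

    def test_reference_mismatch_raises(self):
        with pytest.raises(ValueError):
            var.codon_change("ATGGAATTC", 4, "C", "T", "+")


class TestFixedCodingSubstitutions:
    def make_inputs(self, af=0.85, carriers=7, reseq_called=8, pos=50):
        rna = summaries([("c", pos, "A", "T", 15, carriers, af)])
        reseq = summaries([("c", pos, "A", "T", reseq_called, reseq_called, 1.0)])
        cds = pd.DataFrame({"chrom": ["c"], "start": [10], "end": [100],
                            "strand": ["+"], "gene": ["g1"], "frame": [0]})
        return rna, reseq, cds

    @pytest.mark.parametrize("kw,kept", [
        (dict(), True),
        (dict(carriers=6), False),
        (dict(reseq_called=7), False),
        (dict(af=0.8), False),          # strict AF > 0.8
        (dict(pos=500), False),         # outside CDS -> skipped
    ])
    def test_threshold_rules(self, kw, kept):
        rna, reseq, cds = self.make_inputs(**kw)
        out = var.fixed_coding_substitutions(rna, reseq, cds)
        assert (len(out) == 1) is kept

    def test_provean_filter_strict_threshold(self):
        subs = pd.DataFrame({
            "gene": ["a", "b", "c", "d"],
            "effect": ["missense", "missense", "missense", "synonymous"],
            "provean_score": [-3.1, -2.5, np.nan, -9.0],
        })
        kept = var.provean_filter(subs)
        assert list(kept["gene"]) == ["a"]
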