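"""Generative checks of the cross/expression/behaviour simulator."""

import numpy as np
import pandas as pd
import pytest

from hybgen import simulate as sim
from hybgen.variants import filter_rna_genotypes


def haldane(d_morgans: float) -> float:
    return 0.5 * (1.0 - np.exp(-2.0 * d_morgans))


class TestMeiosis:
    @pytest.mark.parametrize("d", [0.012, 0.1, 0.5])
    def test_recombinant_fraction_matches_haldane_closed_form(self, d):
        gm = sim.GeneticMap([sim.Chromosome("c", 100.0, 1_000_000)])
        a = 100_000
        b = int(gm.cM_to_bp("c", gm.bp_to_cM("c", a) + 100 * d))
        parent = sim.HybridGenome({"c": (sim.Tracts.uniform(1_000_000, sim.MEL),
                                         sim.Tracts.uniform(1_000_000, sim.CYD))})
        rng = np.random.default_rng(7)
        n = 30_000
        rec = 0
        for _ in range(n):
            g = sim.simulate_meiosis(parent, gm, rng)["c"]
            rec += int(g.state_at(a) != g.state_at(b))
        r = haldane(d)
        se = np.sqrt(r * (1 - r) / n)
        assert abs(rec / n - r) < 3 * se

    def test_completely_linked_loci_never_recombine(self):
        # a recombination desert: 400-600 kb collapses to a single cM point
        gm = sim.GeneticMap([sim.Chromosome("c", 50.0, 1_000_000)],
                            loci=[("c", 400_000, 25.0), ("c", 600_000, 25.0)])
        parent = sim.f1_genome(gm)
        rng = np.random.default_rng(0)
        for _ in range(300):
            g = sim.simulate_meiosis(parent, gm, rng)["c"]
            assert g.state_at(450_000) == g.state_at(550_000)

    def test_mean_crossover_count_equals_morgan_length(self):
        gm = sim.GeneticMap([sim.Chromosome("c", 50.0, 1_000_000)])
        parent = sim.f1_genome(gm)
        rng = np.random.default_rng(3)
        # each ancestry switch in an F1 gamete is one crossover
        n = 4000
        switches = [len(sim.simulate_meiosis(parent, gm, rng)["c"].ends) - 1
                    for _ in range(n)]
        se = np.sqrt(0.5 / n)  # Poisson variance = mean
        assert abs(np.mean(switches) - 0.5) < 3 * se

    def test_gamete_tracts_tile_chromosome(self, small_map):
        parent = sim.f1_genome(small_map)
        g = sim.simulate_meiosis(parent, small_map, 5)
        for c in small_map.chromosomes:
            assert g[c.id].ends[-1] == c.length_bp
            assert np.all(np.diff(g[c.id].ends) > 0)

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            sim.GeneticMap([])


class TestPedigree:
    def test_f1_heterozygous_everywhere(self, full_map):
        f1 = sim.f1_genome(full_map)
        assert f1.het_fraction() == 1.0
        pos = np.array([10_000, 2_500_000, 4_999_000])
        for c in full_map.chromosome_ids:
            assert np.all(f1.is_heterozygous_at(c, pos))

    @pytest.mark.parametrize("n_bc", [1, 2, 3, 4])
    def test_heterozygosity_halves_per_backcross_meiosis(self, small_map, n_bc):
        spec = sim.PedigreeSpec(n_bc=n_bc, selected_chrom=small_map.qtl_chrom)
        n = 250
        cohort = sim.simulate_pedigree(spec, small_map, n, seed=n_bc)
        het = np.array([g.het_fraction(exclude_chrom=small_map.qtl_chrom)
                        for g in cohort])
        expect = 2.0 ** (-n_bc)
        assert abs(het.mean() - expect) < 3 * het.std(ddof=1) / np.sqrt(n)

    def test_selection_keeps_marker_heterozygous(self, small_map):
        spec = sim.PedigreeSpec(n_bc=3, selected_chrom=small_map.qtl_chrom)
        chrom, pos = small_map.colour_locus
        for g in sim.simulate_pedigree(spec, small_map, 20, seed=9):
            assert g.is_heterozygous_at(chrom, pos)

    def test_impossible_selection_raises(self, small_map):
        spec = sim.PedigreeSpec(n_bc=1, selected_chrom=small_map.qtl_chrom,
                                required=2, max_retries=5)  # no such ancestry
        with pytest.raises(RuntimeError):
            sim.simulate_pedigree(spec, small_map, 1, seed=0)

    def test_reproducible_given_seed(self, small_map):
        a = sim.simulate_pedigree(sim.PedigreeSpec(selected_chrom=small_map.qtl_chrom),
                                  small_map, 3, seed=42)
        b = sim.simulate_pedigree(sim.PedigreeSpec(selected_chrom=small_map.qtl_chrom),
                                  small_map, 3, seed=42)
        for ga, gb in zip(a, b):
            for c in small_map.chromosome_ids:
                assert np.array_equal(ga.haplotypes[c][0].ends, gb.haplotypes[c][0].ends)
                assert np.array_equal(ga.haplotypes[c][0].state, gb.haplotypes[c][0].state)


class TestExpressionGenerator:
    def test_null_architecture_shares_means_across_groups(self):
        arch = sim.RegulatoryArchitecture.build(300, alpha=0.02)
        counts, design = sim.simulate_expression(arch, sim.make_design(20), 1)
        mel = counts.loc[:, design["group"] == "mel"].mean(axis=1)
        cyd = counts.loc[:, design["group"] == "cyd"].mean(axis=1)
        assert abs(np.log2(mel.mean() / cyd.mean())) < 0.05

    def test_zero_dispersion_gives_poisson_moments(self):
        arch = sim.RegulatoryArchitecture.build(2000, mean_expr=100, alpha=0.0)
        counts, _ = sim.simulate_expression(arch, sim.make_design(15), 2)
        ratio = counts.var(axis=1, ddof=1) / counts.mean(axis=1)
        assert abs(ratio.mean() - 1.0) < 0.05

    def test_nb_moments_match_dispersion(self):
        alpha = 0.2
        arch = sim.RegulatoryArchitecture.build(2000, mean_expr=200, alpha=alpha)
        counts, _ = sim.simulate_expression(arch, sim.make_design(25), 3)
        mu = counts.mean(axis=1)
        v = counts.var(axis=1, ddof=1)
        alpha_hat = ((v - mu) / mu ** 2).mean()
        assert abs(alpha_hat - alpha) < 0.05

    def test_cis_effect_doubles_fold_change_and_allelic_ratio(self):
        arch = sim.RegulatoryArchitecture.build(800, cis=1.0, trans=0.0)
        counts, design = sim.simulate_expression(arch, sim.make_design(10), 4)
        mel = counts.loc[:, design["group"] == "mel"].to_numpy().mean()
        cyd = counts.loc[:, design["group"] == "cyd"].to_numpy().mean()
        assert abs(mel / cyd - 2.0) < 0.1
        allele = sim.simulate_allele_counts(arch, 10, 500, 5)
        ratio = allele["count_mel"].sum() / allele["count_cyd"].sum()
        assert abs(ratio - 2.0) < 0.1

    def test_negative_parameters_rejected(self):
        genes = pd.DataFrame({"q": [-1.0], "cis": [0.0], "trans": [0.0], "alpha": [0.1]})
        with pytest.raises(ValueError):
            sim.RegulatoryArchitecture(genes)


class TestAlleleCounts:
    def test_null_ratio_near_one(self):
        arch = sim.RegulatoryArchitecture.build(400, cis=0.0)
        t = sim.simulate_allele_counts(arch, 10, 1000, 6)
        ratio = t["count_mel"].sum() / t["count_cyd"].sum()
        assert abs(ratio - 1.0) < 0.02

    def test_zero_depth_gives_zero_counts(self):
        arch = sim.RegulatoryArchitecture.build(5)
        t = sim.simulate_allele_counts(arch, 3, 0, 7)
        assert (t[["count_mel", "count_cyd"]].to_numpy() == 0).all()

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            sim.simulate_allele_counts(sim.RegulatoryArchitecture.build(2), 2, -1, 0)


class TestTrials:
    def test_symmetric_null_gives_equal_frequencies(self):
        eff = sim.BehaviourEffects(sigma_male=0.0)
        t = sim.simulate_trials(eff, 2000, 5, 8, p_no_response=0.0)
        tot = t[["n_cyd_only", "n_mel_only", "n_both"]].sum()
        freqs = tot / tot.sum()
        assert np.allclose(freqs, 1 / 3, atol=0.02)

    def test_chr18_effect_shifts_heterozygotes_toward_melpomene(self):
        eff = sim.BehaviourEffects(chr18=(2.0, 0.0), sigma_male=0.0)
        t = sim.simulate_trials(eff, 1500, 5, 9, p_no_response=0.0)
        def mel_rate(sub):
            return sub["n_mel_only"].sum() / sub[["n_cyd_only", "n_mel_only", "n_both"]].sum().sum()
        het = t[t["geno_chr18"] == "cyd/melp"]
        hom = t[t["geno_chr18"] == "cyd/cyd"]
        assert mel_rate(het) > mel_rate(hom) + 0.1

    def test_male_random_intercepts_overdisperse_proportions(self):
        def between_male_var(sigma, seed):
            eff = sim.BehaviourEffects(sigma_male=sigma)
            t = sim.simulate_trials(eff, 600, 20, seed, p_no_response=0.0)
            p = t["n_mel_only"] / t["n_trials_responding"]
            return p.var(ddof=1)
        assert between_male_var(2.0, 10) > 2 * between_male_var(0.0, 11)


class TestGenotypeRecords:
    def test_error_free_records_match_latent_genome(self, small_map, small_panel):
        genomes = {"f1": sim.f1_genome(small_map)}
        rec = sim.simulate_genotype_records(genomes, small_panel,
                                            sim.CoverageModel(p_geno_error=0.0), 12)
        assert (rec["gt"] == rec["true_gt"]).all()
        assert (rec["gt"] == "0/1").all()  # F1 het at every diagnostic site

    def test_qd_failure_fraction_by_construction(self, small_map, small_panel):
        genomes = {"s": sim.pure_genome(small_map, sim.CYD)}
        rec = sim.simulate_genotype_records(
            genomes, small_panel, sim.CoverageModel(frac_fail_qd=0.1), 13)
        frac = (rec["qd"] <= 2).mean()
        assert abs(frac - 0.1) < 0.02

    def test_constant_low_depth_removed_by_rna_filter(self, small_map, small_panel):
        genomes = {"s": sim.pure_genome(small_map, sim.CYD)}
        rec = sim.simulate_genotype_records(
            genomes, small_panel, sim.CoverageModel(constant_dp=3), 14)
        assert len(filter_rna_genotypes(rec)) == 0


class TestZGenotypes:
    def test_female_nearly_homozygous_male_not(self):
        f = sim.simulate_z_genotypes("female", n_sites=2000, seed=1)
        m = sim.simulate_z_genotypes("male", n_sites=2000, seed=2)
        assert (f["gt"] == "0/1").mean() < 0.005
        assert (m["gt"] == "0/1").mean() > 0.02
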