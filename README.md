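# hybgen

A toolkit for dissecting a behavioural QTL in hybridising species — built
around the *Heliconius melpomene* / *H. cydno* system, where a chromosome-18
locus tightly linked to the *optix* wing-pattern gene shifts male courtship
preference.  The package provides, as a tested reusable pipeline:

- **Cross simulation** — forward simulation of F1 and repeated-backcross
  pedigrees under Haldane's map function (crossovers ~ Poisson(map length in
  Morgans), no interference), with phenotypic selection at a linked marker,
  plus generators for species panels, genotype records with VCF-style
  quality annotations, NB expression counts with cis/trans architecture,
  hybrid allele counts, ZZ/ZW genotypes and courtship trials.
- **Genome composition** — species-diagnostic markers (sites with opposite
  fixed alleles, AF > 0.9 after QD/FS/DP/GQ filters), 100-kb window sharing
  fractions matched to F1 / pure-species control profiles, calling windows
  heterozygous (cyd/melp) or homozygous (cyd/cyd); pupal sexing from
  Z-linked heterozygosity (ZZ males ≫ 0%, ZW females ~0%).
- **Differential expression** — per-gene NB log-linear Wald tests with
  median-of-ratios size factors, moment dispersion with trend shrinkage, BH
  adjustment, the twofold + FDR-5% call rule, a dual-reference consistency
  filter and QTL-interval candidate intersection under the dominance
  prediction.
- **Allele-specific expression** — the paired within-individual model
  `~ 0 + individual + allele` with size factors fixed to 1, and the
  cis/trans decision table over the allelic effect A, the parental effect P
  and A − P (pure cis predicts the y = x diagonal).
- **Admixture** — ABBA-BABA D and the fd admixture proportion
  (dynamic-denominator with donor pD = max(p2, p3)) in overlapping windows.
- **Behaviour** — a Bayesian 3-category multinomial logit of courtship
  initiation (cyd-only / mel-only / both) with per-male random intercepts,
  sampled by adaptive Metropolis-within-Gibbs, compared by PSIS-LOO ELPD
  with the |ΔELPD| > 1.96 SE retention rule.
- **Coding substitutions** — fixed-variant filters across RNA and
  resequencing call sets, standard-code effect classes, and filtering on
  externally computed PROVEAN scores (< −2.5).

Everything runs on synthetic data from the built-in simulator; no external
data sets are required.

## Worked example

```python
import numpy as np
from hybgen import simulate as sim, behaviour as bh

gmap = sim.default_map()
cohort = sim.simulate_pedigree(sim.PedigreeSpec(n_bc=4), gmap, 300, seed=1)
het = np.mean([g.het_fraction(exclude_chrom=gmap.qtl_chrom) for g in cohort])
print(f"het fraction outside chr18: {het:.4f}")   # 0.0667 (expected 1/16)

trials = sim.simulate_trials(
    sim.BehaviourEffects(chr18=(1.5, 0.6), sigma_male=0.5), 100, 5, seed=21)
full = bh.fit_multinomial(trials, bh.QTLS, n_draws=800, n_warmup=600,
                          chains=2, seed=22, check_convergence=False)
reduced = bh.fit_multinomial(trials, ("chr1", "chr17"), n_draws=800,
                             n_warmup=600, chains=2, seed=23,
                             check_convergence=False)
cmp_ = bh.compare_models(full, reduced)
print(f"dELPD = {cmp_.delta_elpd:.1f} (SE {cmp_.se_delta:.1f}) "
      f"= {cmp_.se_units:.2f} SE units -> retained: {cmp_.retained}")
# dELPD = -13.9 (SE 6.1) = 2.28 SE units -> retained: True
```

The first number is the mean heterozygous genome fraction of a simulated
four-meiosis backcross cohort outside the chromosome kept heterozygous by
selection — it scatters around the pedigree expectation 2⁻⁴ = 0.0625.  The
second block shows that dropping the chromosome-18 genotype term from the
courtship model worsens leave-one-out predictive density by more than
1.96 standard errors, so the QTL term is retained.

The `examples/` directory holds one short script per capability
(`01_simulate_cross.py` … `07_full_pipeline.py`); each builds a small
synthetic input, runs the method and prints annotated results.  The full
toy study also runs from the shell:

```sh
hybgen run-all --seed 0 --out hybgen_run
```

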