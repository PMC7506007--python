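# Methods

`hybgen` implements the statistical pipeline used to dissect a behavioural
QTL in a pair of hybridising *Heliconius* butterflies: forward simulation of
the crossing design, inference of backcross genome composition from
species-diagnostic variants, negative-binomial differential expression (DE),
allele-specific expression (ASE) with cis/trans decomposition, fixed
protein-coding substitution filters, windowed fd admixture statistics, and a
Bayesian multinomial model of courtship initiation compared by
cross-validated predictive density.  This note records the models, the
defaults and the deliberate design choices.

## Cross simulator

**Recombination.**  Meiosis follows Haldane's model: per chromosome the
crossover count is Poisson with mean equal to the map length in Morgans and
crossover positions are uniform in cM, with no interference.  Map distance d
between two loci then gives a recombinant gamete fraction
r = (1 − e^(−2d))/2, which the simulator reproduces and the tests check in
closed form.  Haldane is the minimal model consistent with knowing only cM
positions; real interference would slightly reduce double crossovers at short
distances but is irrelevant to every downstream statistic used here.

**Genomes and pedigrees.**  A diploid genome is two haplotypes of ancestry
tracts per chromosome.  The default genome is 20 autosomes plus a Z, each
50 cM / 5 Mb with a uniform bp↔cM map; the selected chromosome ("chr18")
carries the preference-QTL peak and a colour-pattern locus 1.2 cM away,
mirroring the tight linkage that lets a dominant red forewing band act as a
visible marker for the preference allele.  The backcross design crosses an F1
to the recurrent species and, at every generation, keeps only offspring whose
hybrid-derived gamete carries the selected (band) allele.  After n backcross
meioses the expected heterozygous genome fraction outside the selected
chromosome is 2^(−n); the default pedigree uses **four** backcross meioses so
the expectation is 1/16 (~6%), the value the third-generation backcross
cohort is described by.  A literal reading of "three generations of
backcrossing" gives 1/8; because the stated expectation is 1/16, four hybrid
meioses from the F1 is taken as the intended design, and `n_bc` is an
explicit parameter rather than a hidden constant.

**Sex chromosome.**  One chromosome is designated Z.  Females (ZW) are
modelled as effectively hemizygous: their Z genotype calls come out
homozygous apart from a small error rate, giving the ZZ/ZW heterozygosity
contrast used for sexing.

**Species panels.**  Two panels of 10 diploid genomes stand in for the
resequenced reference individuals.  A configurable fraction of sites
(default 0.7–0.8) is diagnostic — fixed for opposite alleles between the
species — and the remainder segregates at intermediate frequency in both, so
marker discovery has realistic negatives.  Coalescent history is not
simulated; panels are exchangeable draws, which is all the marker logic
consumes.

**Genotype records.**  Each sample×site record carries DP, GQ, QD and FS.
The coverage model draws DP as Poisson (default mean 20), flips a genotype
with probability `p_geno_error`, and draws QD/FS either in the passing or the
failing range of the QD > 2 / FS < 30 filters with configurable failing
fractions, so filter behaviour is testable by construction.

**Expression.**  Counts are negative binomial:
mean = sf_s · q_g · 2^(c_g·x_cis + t_g·x_trans), dispersion α_g, where c_g
and t_g are log2 cis and trans effects and x_cis/x_trans are the sample's
exposures (both 1 for the non-reference species, both 0 for the reference).
α = 0 degenerates to Poisson.  Allele counts in F1 hybrids split a Poisson
total (default depth = mean informative coverage per gene) binomially with
mel-allele probability 2^c/(1+2^c) — both alleles share the trans
environment, so only cis effects move the ratio; a beta-binomial option adds
extra-multinomial noise.  DE scenarios use a minority of affected genes with
balanced up/down signs; a transcriptome-wide same-direction shift is not
identifiable under median-of-ratios normalization (a known property, not a
bug, and the tests demonstrate it).

**Behaviour trials.**  Each male has QTL genotypes (cyd/cyd or cyd/melp with
frequency 1/2, as in a backcross), a per-category random intercept
u ~ N(0, σ_male), and per-trial outcomes from a 3-category logit
(cyd-only / mel-only / both).  Trials fail to elicit a response with
probability `p_no_response` (default 0.4, giving a median of ~3 responding
trials out of 5); males with zero responding trials stay in the table and are
excluded by the loader, mirroring the analysis rule.

## Variant filters and markers

RNA-derived genotypes keep biallelic calls with QD > 2, FS < 30, DP > 4;
resequencing genotypes keep biallelic calls with 10 < DP < 100, GQ > 30 (all
bounds strict).  Per species, a site allele is called fixed when its
frequency over called alleles exceeds 0.9 (indels excluded); diagnostic
markers are sites fixed for opposite alleles in the two species.  Fixed
coding substitutions additionally require AF > 0.8 with ≥ 7 carrier
individuals in the RNA set per species and a call in ≥ 8 of 10 resequencing
samples, restricted to CDS intervals.  "Present in at least 7 individuals"
is interpreted as carriers of ≥ 1 variant copy, per species.  Effect classes
come from standard-code translation (synonymous / missense / stop gained /
stop lost); externally computed PROVEAN scores are consumed, never computed,
and a substitution is carried forward only with score < −2.5 (strict;
unscored records are excluded with a warning).

## Ancestry windows and sexing

For each sample and non-overlapping 100-kb window, `frac_mel` is the fraction
of informative diagnostic markers at which the sample carries ≥ 1
mel-diagnostic allele (likewise `frac_cyd`); "carries" rather than a zygosity
rule because an F1 control then sits at exactly (1, 1) and a pure recurrent
individual at (0, 1).  Windows need more than 30 informative markers to be
eligible.  Eligible windows are called by the nearest control profile
(Euclidean distance to the F1 and pure-cydno profiles for the same window;
ties and missing controls give NA) — the published analysis compares windows
to those two controls but does not quantify the matching rule, so
nearest-profile is this package's explicit choice.  The genome-wide
heterozygous fraction is the share of called windows that are cyd/melp,
excluding the selected chromosome.

Sexing: the proportion of heterozygous biallelic Z-linked calls is ~0 for ZW
females and an order of magnitude above the error floor for ZZ males.  The
call is female below 1%, male at or above 3× that threshold, ambiguous
between the bands or with < 50 sites.  The guard band keeps borderline
samples unassigned; both bounds are parameters.

## Differential expression

Library sizes are median-of-ratios size factors (geometric-mean reference
over genes expressed in every sample; a positive-count pseudo-reference is an
explicit fallback).  Per gene, counts follow an NB log-linear model with the
contrast indicator and dummy-coded sex/batch covariates and log size factors
as offset.  Sex and batch enter as fixed effects — the original analysis
phrases them as "random factors" in its package's idiom, but with a handful
of levels fixed effects are the statistically equivalent, simpler choice.
Dispersion is per-gene method-of-moments, floored at 1e-8, by default blended
50:50 with a binned-median mean-dispersion trend — a small-sample
stabilisation that pulls the many noisy per-gene estimates toward the
transcriptome trend.  The Wald statistic uses the observed-information SE
with a two-sided normal reference.  BH adjustment runs across testable
genes; a gene is *called* DE only with |log2FC| ≥ 1 (point estimate, not
shrunken) and padj < 0.05.  The dual-reference filter keeps a called gene
only if the other reference genome also yields a call with the same sign;
the candidate intersection keeps QTL-interval genes called in the species
comparison and in the F1-vs-recessive-parent comparison with the same sign
(the dominance prediction), optionally annotating backcross support.

## Allele-specific expression and cis/trans classes

The ASE model is `~ 0 + individual + allele` with size factors fixed to 1 —
the allele comparison is within individuals, so between-sample normalization
would only add noise.  The test fits a Poisson GLM, estimates an NB
dispersion from the Pearson excess (α = (χ²/dof − 1)/mean fitted value,
floored at 0) and refits NB when positive; the Wald p for the allele effect
is reported raw, and a gene is *called* with |allelic log2FC| ≥ 1 and
p < 0.05.  Genes need ≥ 2 individuals with ≥ 10 informative reads.  A paired
binomial GLM on (mel, cyd) counts is provided as an independent cross-check
and agrees with the NB route on simulated data.  Note the call rule's knife
edge: at a true effect of exactly twofold the estimate is centred on the
threshold, so the called fraction converges to 1/2 at any depth, while the
rejection rate (p < 0.05) approaches 1 — the tests assert both properties.

The assignment-bias check pools counts per gene and flags a median allelic
log2FC beyond a tolerance (default 0.1): read misassignment toward one
reference shifts the whole distribution off zero.

cis/trans classes use three two-sided Wald tests at 5%: allelic effect A vs
0, parental effect P vs 0, and A − P vs 0 with pooled SE
sqrt(SE_A² + SE_P²) (the two estimates come from disjoint samples, so the
covariance is zero by design).  A ≠ 0 with A − P ≠ 0 is cis+trans; A ≠ 0,
P ≠ 0 and A − P indistinguishable is cis-only (the y = x diagonal); P ≠ 0
with A ≈ 0 is trans-only; neither significant is conserved; anything else,
or missing inputs, is ambiguous.

## Admixture windows

Site components use the frequency-based ABBA/BABA forms with the dynamic
donor pD = max(p2, p3) substituted for both P2 and P3 in the denominator
components.  Windows (default 100 kb, step = window/5, ≥ 100 sites; 20 for
20-kb windows) report D = Σ(ABBA−BABA)/Σ(ABBA+BABA) and
fd = Σ(ABBA−BABA)/Σ(ABBA_D−BABA_D), with fd undefined when D ≤ 0 or the
denominator is non-positive.  Sites with outgroup frequency above 0.5 are
repolarized.  fd lies in [0, 1] when defined and equals 1 under complete
introgression (p2 = p3 with p1 = pO = 0).

## Courtship-initiation model

Per male, the trial-outcome counts are multinomial with 3-category-logit
probabilities; cyd-only is the reference category.  Fixed effects are
per-category intercepts and 0/1 genotype coefficients for each modelled QTL
(interactions via products); per-male random intercepts share one SD
σ_male.  Priors: normal(0, 2.5) on fixed effects, half-normal(0, 2) on
σ_male — weakly informative on the logit scale.  Sampling is adaptive
random-walk Metropolis-within-Gibbs with a non-centred parametrisation
(u = σ·z) plus an interweaved centred σ update; the non-centred/interweaved
combination is what makes σ mix when the random effects are weakly
identified from ~3 responding trials per male.  Defaults are 4 chains of
4,000 draws after 2,000 warmup with split R-hat < 1.05 enforced; simulation
studies use reduced draws (hundreds) with the convergence gate off, which is
sufficient for sign-recovery and coverage summaries.

ELPD uses PSIS-LOO on the per-male pointwise log-likelihood; SE is
sqrt(n · var(pointwise)).  Random-intercept models often produce high Pareto
k for influential males — the implementation reports them and warns above
10%.  Model comparison is ΔELPD = elpd(reduced) − elpd(full) with SE from
pointwise differences; a dropped term is retained when |ΔELPD| > 1.96 SE.
Feeding the reported summary pairs (−10.9, 5.1) and (−1.7, 0.9) reproduces
2.14 (retained) and 1.89 (not retained) SE units exactly.

## Problem sizes and limitations

The bundled toy study and the acceptance script run everything at desk
scale, chosen as the smallest sizes at which the statistical expectations are
measurably met: 2,000 genomes for the 1/16 backcross expectation, 100,000
meioses for the Haldane check, 20 genomes × 21 chromosomes for ancestry
accuracy, 5,000 null genes for ASE calibration, 2,300 genes for DE recovery,
and 2 × 20 replicate reduced-draw fits for behaviour recovery.

What the synthetic data do not contain: linkage disequilibrium within
species panels, coalescent variance in marker density, read-level alignment
bias (allele counts are drawn at the gene level; the WASP-style mapping
problem is out of scope), expression correlation between genes, and
selection during the pedigree beyond the single marker.  Passing tests
therefore demonstrate the *statistical machinery* — filters, estimators,
call rules, samplers — under the generative model the analyses assume, not
robustness to the full messiness of real sequencing data.
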