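"""Call heterozygous vs homozygous genomic windows in backcross hybrids.

Simulates species panels and genotype records with 1% genotyping error,
builds diagnostic markers (sites fixed for opposite alleles), computes
100-kb window sharing fractions against F1 and pure-species controls, and
reports each hybrid's genome composition.
"""

import numpy as np

from hybgen import ancestry as anc
from hybgen import simulate as sim
from hybgen import variants as var

rng = np.random.default_rng(7)
gmap = sim.default_map(n_autosomes=6)
panel = sim.simulate_species_panels(gmap, sites_per_chrom=2500,
                                    frac_diagnostic=0.8, seed=rng)
markers = panel.diagnostic_sites()
print(f"{len(markers):,} diagnostic markers "
      f"(~{len(markers) / (7 * 50):.0f} per 100 kb window)")

cohort = sim.simulate_pedigree(
    sim.PedigreeSpec(n_bc=4, selected_chrom=gmap.qtl_chrom), gmap, 5, rng)
genomes = {f"bc{i}": g for i, g in enumerate(cohort)}
genomes["f1"] = sim.f1_genome(gmap)
genomes["cyd"] = sim.pure_genome(gmap, sim.CYD)
records = var.filter_rna_genotypes(sim.simulate_genotype_records(
    genomes, panel, sim.CoverageModel(p_geno_error=0.01), rng))

lengths = {c.id: c.length_bp for c in gmap.chromosomes}
profiles = {s: anc.window_share_fractions(sub, markers, 100_000, 30, lengths)
            for s, sub in records.groupby("sample")}
for i in range(len(cohort)):
    calls = anc.classify_windows(profiles[f"bc{i}"], profiles["f1"],
                                 profiles["cyd"])
    frac = anc.genome_het_fraction(calls, exclude_chrom=gmap.qtl_chrom)
    n_het = (calls["call"] == anc.HET).sum()
    print(f"bc{i}: {n_het} heterozygous windows, "
          f"het fraction outside {gmap.qtl_chrom} = {frac:.3f}")
# Each window is assigned to whichever control profile (F1 or pure cydno) it
# is nearer; the het fraction should scatter around the 1/16 expectation.
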