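"""Forward simulation of hybrid crosses, expression counts, allele counts and
behaviour trials.

The generators here produce every input the analysis modules consume, with the
statistical structure those analyses assume:

* two species panels fixed for opposite alleles at diagnostic sites;
* recombinant pedigrees (F1, repeated backcrosses with phenotypic selection at
  a linked colour-pattern marker) under Haldane's no-interference model;
* negative-binomial expression counts driven by a cis/trans regulatory
  architecture;
* per-individual species-allele read counts in hybrids;
* ZZ/ZW heterozygosity contrast on the Z chromosome;
* per-male multinomial courtship-initiation trials with random intercepts;
* genotype records with VCF-style quality annotations (DP, GQ, QD, FS).

Every stochastic operation takes an explicit seed or :class:`numpy.random.Generator`
and is reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MEL = 1  #: ancestry code for the red-banded species (H. melpomene-like)
CYD = 0  #: ancestry code for the recurrent parent species (H. cydno-like)

SPECIES_NAME = {MEL: "mel", CYD: "cyd"}


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Chromosome:
    """One linkage group with a physical and a genetic length."""

    id: str
    length_cM: float
    length_bp: int

    def __post_init__(self):
        if self.length_cM <= 0 or self.length_bp <= 0:
            raise ValueError(f"chromosome {self.id}: lengths must be > 0")


@dataclass
class GeneticMap:
    """Piecewise-linear bp <-> cM interpolation per chromosome.

    ``loci`` are optional anchor points ``(chrom, pos_bp, pos_cM)``; the
    chromosome ends ``(0, 0)`` and ``(length_bp, length_cM)`` are always
    implied.  pos_cM must be non-decreasing in pos_bp.
    """

    chromosomes: list[Chromosome]
    loci: list[tuple[str, int, float]] = field(default_factory=list)

    def __post_init__(self):
        if not self.chromosomes:
            raise ValueError("empty genetic map")
        self._chrom = {c.id: c for c in self.chromosomes}
        self._anchors: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for c in self.chromosomes:
            pts = [(0, 0.0), (c.length_bp, c.length_cM)]
            pts += [(bp, cm) for chrom, bp, cm in self.loci if chrom == c.id]
            pts.sort()
            bp = np.array([p[0] for p in pts], dtype=float)
            cm = np.array([p[1] for p in pts], dtype=float)
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"chromosome {c.id}: pos_cM must be non-decreasing in pos_bp")
            self._anchors[c.id] = (bp, cm)

    def chromosome(self, chrom: str) -> Chromosome:
        return self._chrom[chrom]

    @property
    def chromosome_ids(self) -> list[str]:
        return [c.id for c in self.chromosomes]

    def bp_to_cM(self, chrom: str, pos_bp):
        bp, cm = self._anchors[chrom]
        return np.interp(pos_bp, bp, cm)

    def cM_to_bp(self, chrom: str, pos_cM):
        bp, cm = self._anchors[chrom]
        return np.interp(pos_cM, cm, bp)


#: physical position (bp) of the preference QTL peak used by :func:`default_map`
QTL_PEAK_BP = 1_500_000
#: cM offset of the linked colour-pattern locus from the QTL peak
COLOUR_LOCUS_OFFSET_CM = 1.2


def default_map(n_autosomes: int = 20, length_cM: float = 50.0,
                length_bp: int = 5_000_000) -> GeneticMap:
    """Default genome: ``n_autosomes`` autosomes plus a Z chromosome.

    The selected chromosome ("chr18") carries two named loci: the preference
    QTL peak (at 0 cM relative offset) and the colour-pattern locus 1.2 cM
    away, mirroring the tight optix linkage used for phenotypic selection.
    """
    chroms = [Chromosome(f"chr{i}", length_cM, length_bp) for i in range(1, n_autosomes + 1)]
    chroms.append(Chromosome("chrZ", length_cM, length_bp))
    gm = GeneticMap(chroms)
    qtl_chrom = "chr18" if n_autosomes >= 18 else chroms[n_autosomes - 1].id
    peak_cM = gm.bp_to_cM(qtl_chrom, QTL_PEAK_BP)
    gm.qtl_chrom = qtl_chrom
    gm.qtl_peak = (qtl_chrom, QTL_PEAK_BP)
    gm.colour_locus = (qtl_chrom, int(gm.cM_to_bp(qtl_chrom, peak_cM + COLOUR_LOCUS_OFFSET_CM)))
    return gm


# ---------------------------------------------------------------------------
# Haplotypes, tracts and genomes
# ---------------------------------------------------------------------------

@dataclass
class Tracts:
    """Ancestry tracts of one haploid chromosome copy.

    ``ends[i]`` is the (exclusive, bp) end of tract *i*; the last end equals
    the chromosome length; ``state[i]`` is the ancestor species code.  Tracts
    tile the chromosome without gaps or overlaps by construction.
    """

    ends: np.ndarray
    state: np.ndarray

    @classmethod
    def uniform(cls, length_bp: int, species: int) -> "Tracts":
        return cls(np.array([length_bp], dtype=np.int64),
                   np.array([species], dtype=np.int8))

    def state_at(self, pos):
        """Ancestry code(s) at physical position(s) ``pos``."""
        idx = np.searchsorted(self.ends, np.asarray(pos), side="right")
        return self.state[idx]

    def simplify(self) -> "Tracts":
        """Merge adjacent tracts of identical ancestry."""
        if len(self.state) <= 1:
            return self
        keep = np.append(self.state[1:] != self.state[:-1], True)
        return Tracts(self.ends[keep], self.state[keep])

    def length_in_state(self, species: int) -> int:
        starts = np.concatenate([[0], self.ends[:-1]])
        return int(np.sum((self.ends - starts)[self.state == species]))


@dataclass
class HybridGenome:
    """Diploid genome as two haplotypes of ancestry tracts per chromosome."""

    haplotypes: dict[str, tuple[Tracts, Tracts]]

    def ancestry_at(self, chrom: str, pos):
        a, b = self.haplotypes[chrom]
        return a.state_at(pos), b.state_at(pos)

    def is_heterozygous_at(self, chrom: str, pos):
        a, b = self.ancestry_at(chrom, pos)
        return a != b

    def het_fraction(self, exclude_chrom: str | None = None) -> float:
        """Length-weighted fraction of the genome with differing ancestries."""
        het = tot = 0
        for chrom, (a, b) in self.haplotypes.items():
            if chrom == exclude_chrom:
                continue
            ends = np.union1d(a.ends, b.ends)
            starts = np.concatenate([[0], ends[:-1]])
            lengths = ends - starts
            mid = (starts + ends) // 2
            diff = a.state_at(mid) != b.state_at(mid)
            het += int(lengths[diff].sum())
            tot += int(lengths.sum())
        return het / tot

    def true_windows(self, chrom: str, window_bp: int, length_bp: int) -> np.ndarray:
        """Majority ancestry zygosity per tiled window: True = heterozygous.

        Used as the simulator-truth oracle for windowed ancestry calls: a
        window is heterozygous if differing-ancestry segments cover more than
        half of it.
        """
        a, b = self.haplotypes[chrom]
        ends = np.union1d(a.ends, b.ends).astype(float)
        starts = np.concatenate([[0.0], ends[:-1]])
        mid = ((starts + ends) / 2).astype(np.int64)
        diff = (a.state_at(mid) != b.state_at(mid)).astype(float)
        edges = np.arange(0, length_bp + window_bp, window_bp, dtype=float)
        edges[-1] = max(edges[-1], length_bp)
        het_cov = np.zeros(len(edges) - 1)
        for s, e, d in zip(starts, ends, diff):
            if not d:
                continue
            lo = np.searchsorted(edges, s, side="right") - 1
            hi = np.searchsorted(edges, e, side="left")
            for w in range(lo, hi):
                het_cov[w] += min(e, edges[w + 1]) - max(s, edges[w])
        widths = np.diff(edges)
        return het_cov / widths > 0.5


def f1_genome(gmap: GeneticMap) -> HybridGenome:
    """F1 of the two fixed species: heterozygous mel/cyd everywhere."""
    return HybridGenome({
        c.id: (Tracts.uniform(c.length_bp, MEL), Tracts.uniform(c.length_bp, CYD))
        for c in gmap.chromosomes
    })


def pure_genome(gmap: GeneticMap, species: int) -> HybridGenome:
    return HybridGenome({
        c.id: (Tracts.uniform(c.length_bp, species), Tracts.uniform(c.length_bp, species))
        for c in gmap.chromosomes
    })


def simulate_meiosis(parent: HybridGenome, gmap: GeneticMap, seed) -> dict[str, Tracts]:
    """One meiosis under Haldane's model (no crossover interference).

    Per chromosome the crossover count is Poisson with mean equal to the map
    length in Morgans and crossover positions are uniform in cM.  Returns one
    gamete as a haploid tract list per chromosome.
    """
    rng = _rng(seed)
    if not gmap.chromosomes:
        raise ValueError("empty genetic map")
    gamete: dict[str, Tracts] = {}
    for c in gmap.chromosomes:
        a, b = parent.haplotypes[c.id]
        n_co = rng.poisson(c.length_cM / 100.0)
        if n_co:
            pos_cM = np.sort(rng.uniform(0, c.length_cM, n_co))
            breaks = np.asarray(gmap.cM_to_bp(c.id, pos_cM)).astype(np.int64)
        else:
            breaks = np.empty(0, dtype=np.int64)
        phase = int(rng.integers(2))  # which parental haplotype starts
        haps = (a, b)
        seg_ends: list[np.ndarray] = []
        seg_states: list[np.ndarray] = []
        bounds = np.concatenate([[0], breaks, [c.length_bp]])
        for i in range(len(bounds) - 1)[::1]:
            lo, hi = bounds[i], bounds[i + 1]
            if hi <= lo:
                continue
            h = haps[(phase + i) % 2]
            j0 = int(np.searchsorted(h.ends, lo, side="right"))
            j1 = int(np.searchsorted(h.ends, hi, side="left"))
            ends = np.append(h.ends[j0:j1], hi)
            seg_ends.append(ends)
            seg_states.append(np.append(h.state[j0:j1], h.state[min(j1, len(h.state) - 1)]))
        gamete[c.id] = Tracts(np.concatenate(seg_ends),
                              np.concatenate(seg_states)).simplify()
    return gamete


def _offspring(gamete: dict[str, Tracts], gmap: GeneticMap, other_species: int) -> HybridGenome:
    return HybridGenome({
        c.id: (gamete[c.id], Tracts.uniform(c.length_bp, other_species))
        for c in gmap.chromosomes
    })


@dataclass
class PedigreeSpec:
    """Crossing design: an F1 followed by ``n_bc`` backcross meioses to the
    recurrent parent, with phenotypic selection at a linked marker.

    The default four backcross meioses from the F1 give an expected
    heterozygous genome fraction of 1/16 outside the selected chromosome; the
    hybrid parent of each generation is required to transmit the ``required``
    ancestry at the selected marker (the red-band carrier rule).
    """

    n_bc: int = 4
    recurrent: int = CYD
    selected_chrom: str = "chr18"
    selected_pos: int | None = None  # default: the map's colour locus
    required: int = MEL  # ancestry the hybrid gamete must carry at the marker
    max_retries: int = 1000

    def __post_init__(self):
        if self.n_bc < 0:
            raise ValueError("n_bc must be >= 0")


def simulate_pedigree(spec: PedigreeSpec, gmap: GeneticMap, n_offspring: int,
                      seed) -> list[HybridGenome]:
    """Simulate a cohort of backcross genomes under ``spec``.

    Each lineage starts from the F1 and performs ``spec.n_bc`` successive
    backcrosses to the recurrent parent; at every generation only offspring
    heterozygous (carrying ``spec.required`` ancestry) at the selected marker
    are retained, mirroring selection on the dominant red forewing band.
    """
    rng = _rng(seed)
    if spec.selected_chrom not in gmap.chromosome_ids:
        raise ValueError(f"selected marker chromosome {spec.selected_chrom!r} not in map")
    pos = spec.selected_pos
    if pos is None:
        pos = getattr(gmap, "colour_locus", (None, gmap.chromosome(spec.selected_chrom).length_bp // 2))[1]
    cohort = []
    for _ in range(n_offspring):
        parent = f1_genome(gmap)
        for _gen in range(spec.n_bc):
            for attempt in range(spec.max_retries):
                gamete = simulate_meiosis(parent, gmap, rng)
                if gamete[spec.selected_chrom].state_at(pos) == spec.required:
                    break
            else:
                raise RuntimeError(
                    f"selection at {spec.selected_chrom}:{pos} not achievable in "
                    f"{spec.max_retries} meioses (marker fixed for the wrong allele?)")
            parent = _offspring(gamete, gmap, spec.recurrent)
        cohort.append(parent)
    return cohort


# ---------------------------------------------------------------------------
# Species panels and diagnostic sites
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


@dataclass
class SpeciesPanel:
    """Resequencing-style haplotype panels for the two species.

    ``haplotypes[sp]`` is a (site x haplotype) allele-index matrix (0 = ref,
    1 = alt).  At sites flagged diagnostic, all haplotypes of one species
    carry one allele and all haplotypes of the other species the other.
    """

    sites: pd.DataFrame  # chrom, pos, ref, alt, diagnostic (bool)
    haplotypes: dict[int, np.ndarray]

    def diagnostic_sites(self) -> pd.DataFrame:
        """Diagnostic-marker table: chrom, pos, allele_mel, allele_cyd."""
        d = self.sites[self.sites["diagnostic"]].copy()
        mel_alt = self.haplotypes[MEL][self.sites["diagnostic"].to_numpy(), 0] == 1
        d["allele_mel"] = np.where(mel_alt, d["alt"], d["ref"])
        d["allele_cyd"] = np.where(mel_alt, d["ref"], d["alt"])
        return d[["chrom", "pos", "allele_mel", "allele_cyd"]].reset_index(drop=True)


def simulate_species_panels(gmap: GeneticMap, n_per_species: int = 10,
                            sites_per_chrom: int = 2000,
                            frac_diagnostic: float = 0.7,
                            seed=None) -> SpeciesPanel:
    """Two divergent panels with a mix of diagnostic and shared-polymorphic sites.

    Defaults emulate 10 resequenced genomes per species with most informative
    sites fixed for opposite alleles.  Non-diagnostic sites segregate at
    intermediate frequency in both species (and are useless for ancestry).
    """
    rng = _rng(seed)
    rows = []
    for c in gmap.chromosomes:
        pos = np.sort(rng.choice(np.arange(1, c.length_bp), size=sites_per_chrom, replace=False))
        ref = _BASES[rng.integers(0, 4, sites_per_chrom)]
        alt = _BASES[(np.searchsorted(_BASES, ref) + rng.integers(1, 4, sites_per_chrom)) % 4]
        diag = rng.uniform(size=sites_per_chrom) < frac_diagnostic
        rows.append(pd.DataFrame({"chrom": c.id, "pos": pos, "ref": ref,
                                  "alt": alt, "diagnostic": diag}))
    sites = pd.concat(rows, ignore_index=True)
    n_sites = len(sites)
    haps = {}
    mel_has_alt = rng.integers(0, 2, n_sites).astype(bool)
    shared_freq = rng.uniform(0.2, 0.8, n_sites)
    for sp in (MEL, CYD):
        h = rng.uniform(size=(n_sites, 2 * n_per_species)) < shared_freq[:, None]
        diag = sites["diagnostic"].to_numpy()
        fixed_alt = mel_has_alt if sp == MEL else ~mel_has_alt
        h[diag] = fixed_alt[diag, None]
        haps[sp] = h.astype(np.int8)
    return SpeciesPanel(sites, haps)


# ---------------------------------------------------------------------------
# Genotype records with quality annotations
# ---------------------------------------------------------------------------

@dataclass
class CoverageModel:
    """Read-depth and quality model for simulated genotype records.

    ``frac_fail_qd``/``frac_fail_fs`` are the fractions of records drawn in
    the failing range of the QD>2 / FS<30 filters; ``p_geno_error`` is the
    probability a genotype call differs from the latent genome state.
    """

    mean_dp: float = 20.0
    p_geno_error: float = 0.0
    frac_fail_qd: float = 0.0
    frac_fail_fs: float = 0.0
    mean_gq: float = 80.0
    constant_dp: int | None = None


def simulate_genotype_records(genomes: dict[str, HybridGenome], panel: SpeciesPanel,
                              coverage: CoverageModel, seed,
                              diagnostic_only: bool = True) -> pd.DataFrame:
    """Genotype records (one row per sample x site) with DP/GQ/QD/FS annotations.

    Truth is retained in the ``true_gt`` column for scoring.  Genotypes are
    written with respect to ref/alt allele indices, e.g. ``"0/1"``.
    """
    rng = _rng(seed)
    sites = panel.sites[panel.sites["diagnostic"]] if diagnostic_only else panel.sites
    mel_alt = (panel.haplotypes[MEL][sites.index.to_numpy(), 0] == 1)
    frames = []
    for sample, genome in genomes.items():
        gts = []
        for chrom, sub in sites.groupby("chrom", sort=False):
            a, b = genome.ancestry_at(chrom, sub["pos"].to_numpy())
            sub_mel_alt = mel_alt[sites["chrom"].to_numpy() == chrom]
            # allele index carried by each haplotype at each site
            ai = np.where(a == MEL, sub_mel_alt, ~sub_mel_alt).astype(int)
            bi = np.where(b == MEL, sub_mel_alt, ~sub_mel_alt).astype(int)
            gts.append(np.stack([ai, bi], axis=1))
        gt = np.concatenate(gts)
        gt.sort(axis=1)
        true_gt = np.array([f"{x}/{y}" for x, y in gt])
        obs = gt.copy()
        err = rng.uniform(size=len(obs)) < coverage.p_geno_error
        # an erroneous call flips one allele
        flip = rng.integers(0, 2, size=len(obs))
        obs[err, flip[err]] = 1 - obs[err, flip[err]]
        obs.sort(axis=1)
        obs_gt = np.array([f"{x}/{y}" for x, y in obs])
        n = len(obs)
        if coverage.constant_dp is not None:
            dp = np.full(n, coverage.constant_dp)
        else:
            dp = rng.poisson(coverage.mean_dp, n)
        qd = np.where(rng.uniform(size=n) < coverage.frac_fail_qd,
                      rng.uniform(0.0, 2.0, n), rng.uniform(5.0, 30.0, n))
        fs = np.where(rng.uniform(size=n) < coverage.frac_fail_fs,
                      rng.uniform(31.0, 60.0, n), rng.uniform(0.0, 10.0, n))
        gq = np.clip(rng.normal(coverage.mean_gq, 10.0, n), 1, 99).astype(int)
        frames.append(pd.DataFrame({
            "sample": sample, "chrom": sites["chrom"].to_numpy(),
            "pos": sites["pos"].to_numpy(), "ref": sites["ref"].to_numpy(),
            "alt": sites["alt"].to_numpy(), "n_alt": 1, "gt": obs_gt,
            "dp": dp, "gq": gq, "qd": np.round(qd, 2), "fs": np.round(fs, 2),
            "true_gt": true_gt,
        }))
    return pd.concat(frames, ignore_index=True)


def simulate_z_genotypes(sex: str, n_sites: int = 500, het_rate_male: float = 0.04,
                         error_rate: float = 0.001, seed=None) -> pd.DataFrame:
    """Biallelic genotype calls on the Z for one pupa.

    Males (ZZ) are heterozygous at a few percent of sites; females (ZW) are
    hemizygous, so their calls come out homozygous apart from a small error
    rate.  Returns a frame with chrom/pos/gt columns as used by the sexing rule.
    """
    rng = _rng(seed)
    p_het = het_rate_male if sex == "male" else error_rate
    het = rng.uniform(size=n_sites) < p_het
    gt = np.where(het, "0/1", "0/0")
    return pd.DataFrame({"chrom": "chrZ", "pos": np.arange(1, n_sites + 1) * 1000,
                         "gt": gt})


# ---------------------------------------------------------------------------
# Expression counts
# ---------------------------------------------------------------------------

@dataclass
class RegulatoryArchitecture:
    """Per-gene generative parameters of the cis/trans expression model.

    ``q`` is the baseline mean, ``cis``/``trans`` are log2 effects, ``alpha``
    the NB dispersion.  A sample with cis exposure ``x_cis`` and trans exposure
    ``x_trans`` has mean ``sf * q * 2**(cis*x_cis + trans*x_trans)``.
    """

    genes: pd.DataFrame  # index gene; columns q, cis, trans, alpha

    def __post_init__(self):
        g = self.genes
        if (g["q"] <= 0).any() or (g["alpha"] < 0).any():
            raise ValueError("require q > 0 and alpha >= 0")

    @classmethod
    def build(cls, n_genes: int, mean_expr: float = 200.0, alpha: float = 0.05,
              cis: float | np.ndarray = 0.0, trans: float | np.ndarray = 0.0,
              gene_prefix: str = "g", seed=None) -> "RegulatoryArchitecture":
        rng = _rng(seed)
        q = mean_expr * np.exp(rng.normal(0, 0.5, n_genes)) if seed is not None \
            else np.full(n_genes, mean_expr)
        genes = pd.DataFrame({
            "q": q,
            "cis": np.broadcast_to(np.asarray(cis, dtype=float), (n_genes,)).copy(),
            "trans": np.broadcast_to(np.asarray(trans, dtype=float), (n_genes,)).copy(),
            "alpha": np.full(n_genes, float(alpha)),
        }, index=[f"{gene_prefix}{i:05d}" for i in range(n_genes)])
        return cls(genes)


def nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB(mean, dispersion alpha) deviates; alpha = 0 degenerates to Poisson."""
    mean = np.asarray(mean, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    pois = alpha <= 0
    out[pois] = rng.poisson(mean[pois])
    if (~pois).any():
        size = 1.0 / alpha[~pois]
        p = size / (size + mean[~pois])
        out[~pois] = rng.negative_binomial(size, p)
    return out


def make_design(n_per_group: int, groups=("mel", "cyd"), stage: str = "adult",
                batches: int = 1, seed=None) -> pd.DataFrame:
    """Balanced two-group sample sheet with sex/batch columns and exposures.

    The reference group ("cyd") has ``x_cis = x_trans = 0``; the other group
    carries both the cis and the trans environment (``x_cis = x_trans = 1``),
    which is the parental-species contrast of the generative model.
    """
    rng = _rng(seed)
    rows = []
    for g in groups:
        for i in range(n_per_group):
            rows.append({
                "sample": f"{g}_{stage}_{i:02d}", "group": g, "stage": stage,
                "sex": ["male", "female"][i % 2],
                "batch": f"b{i % batches}",
                "x_cis": 1 if g != groups[-1] else 0,
                "x_trans": 1 if g != groups[-1] else 0,
                "size_factor": float(np.exp(rng.normal(0, 0.15))) if seed is not None else 1.0,
            })
    return pd.DataFrame(rows).set_index("sample")


def simulate_expression(arch: RegulatoryArchitecture, design: pd.DataFrame, seed):
    """Gene x sample NB count matrix under the cis/trans architecture.

    Returns ``(counts, design)`` where ``counts`` is a genes x samples integer
    DataFrame; the architecture itself carries the true effect labels.
    """
    rng = _rng(seed)
    g = arch.genes
    log2fc = (np.outer(g["cis"], design["x_cis"]) +
              np.outer(g["trans"], design["x_trans"]))
    mean = (g["q"].to_numpy()[:, None] * 2.0 ** log2fc *
            design["size_factor"].to_numpy()[None, :])
    counts = nb_draw(rng, mean, g["alpha"].to_numpy()[:, None])
    return pd.DataFrame(counts, index=g.index, columns=design.index), design


def simulate_allele_counts(arch: RegulatoryArchitecture, n_individuals: int,
                           depth: float, seed, overdispersion: float = 0.0,
                           stage: str = "adult", cross: str = "F1") -> pd.DataFrame:
    """Species-allele read counts per gene x hybrid individual.

    In an F1 both alleles share the trans environment, so the expected
    mel:cyd ratio is ``2**cis``.  ``depth`` is the mean total informative
    coverage per gene per individual (Poisson); ``overdispersion`` is a
    beta-binomial rho adding extra-multinomial noise.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    rng = _rng(seed)
    g = arch.genes
    p_mel = 2.0 ** g["cis"].to_numpy() / (1.0 + 2.0 ** g["cis"].to_numpy())
    rows = []
    for i in range(n_individuals):
        total = rng.poisson(depth, len(g))
        if overdispersion > 0:
            rho = overdispersion
            a = p_mel * (1 - rho) / rho
            b = (1 - p_mel) * (1 - rho) / rho
            p = rng.beta(a, b)
        else:
            p = p_mel
        mel = rng.binomial(total, p)
        rows.append(pd.DataFrame({
            "gene": g.index, "individual": f"{cross}_{i:02d}", "stage": stage,
            "cross": cross, "count_mel": mel, "count_cyd": total - mel,
        }))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Behaviour trials
# ---------------------------------------------------------------------------

CATEGORIES = ("cyd_only", "mel_only", "both")


@dataclass
class BehaviourEffects:
    """Generative parameters of the courtship-initiation model.

    ``intercepts`` and each QTL coefficient vector are on the multinomial
    logit scale for the non-reference categories (mel_only, both) relative to
    cyd_only; ``sigma_male`` is the SD of per-male random intercepts.
    """

    intercepts: tuple[float, float] = (0.0, 0.0)
    chr1: tuple[float, float] = (0.0, 0.0)
    chr17: tuple[float, float] = (0.0, 0.0)
    chr18: tuple[float, float] = (0.0, 0.0)
    sigma_male: float = 0.5

    def __post_init__(self):
        if self.sigma_male < 0:
            raise ValueError("sigma_male must be >= 0")


def simulate_trials(effects: BehaviourEffects, n_males: int, trials_per_male: int,
                    seed, p_no_response: float = 0.4,
                    genotype_freq: float = 0.5) -> pd.DataFrame:
    """Per-male courtship-initiation trial counts by QTL genotype.

    Each responding trial falls in one of three categories (initiation toward
    the cydno female only, the melpomene female only, or both) from a
    3-category logit with per-male random intercepts.  Males are backcrosses,
    so each QTL genotype is cyd/cyd or cyd/melp with frequency ~1/2.  Males
    with zero responding trials are kept in the table (downstream loaders
    apply the exclusion rule).
    """
    if trials_per_male < 1:
        raise ValueError("trials_per_male must be >= 1")
    rng = _rng(seed)
    rows = []
    for m in range(n_males):
        geno = {q: int(rng.uniform() < genotype_freq) for q in ("chr1", "chr17", "chr18")}
        u = rng.normal(0, effects.sigma_male, 2) if effects.sigma_male > 0 else np.zeros(2)
        eta = np.array([0.0,
                        effects.intercepts[0] + u[0],
                        effects.intercepts[1] + u[1]])
        for q in ("chr1", "chr17", "chr18"):
            coef = getattr(effects, q)
            eta[1] += coef[0] * geno[q]
            eta[2] += coef[1] * geno[q]
        p = np.exp(eta - eta.max())
        p /= p.sum()
        n_resp = rng.binomial(trials_per_male, 1.0 - p_no_response)
        counts = rng.multinomial(n_resp, p) if n_resp else np.zeros(3, dtype=int)
        rows.append({
            "male": f"m{m:03d}",
            "geno_chr1": "cyd/melp" if geno["chr1"] else "cyd/cyd",
            "geno_chr17": "cyd/melp" if geno["chr17"] else "cyd/cyd",
            "geno_chr18": "cyd/melp" if geno["chr18"] else "cyd/cyd",
            "n_cyd_only": int(counts[0]), "n_mel_only": int(counts[1]),
            "n_both": int(counts[2]), "n_trials_responding": int(n_resp),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Admixture frequencies
# ---------------------------------------------------------------------------

def simulate_frequency_matrix(n_sites: int, length_bp: int = 2_000_000,
                              frac_introgressed: float = 0.0,
                              introgressed_span: tuple[int, int] | None = None,
                              seed=None) -> pd.DataFrame:
    """Four-population derived-allele frequency table for ABBA-BABA statistics.

    Under the null, P2 and P3 frequencies are drawn independently and
    symmetrically with P1 so no excess allele sharing exists.  Sites inside
    ``introgressed_span`` (or a random fraction) get p2 = p3, the signature of
    introgression from P3 into P2.
    """
    rng = _rng(seed)
    pos = np.sort(rng.choice(np.arange(1, length_bp), n_sites, replace=False))
    p1 = rng.beta(0.5, 2.0, n_sites)
    p2 = rng.beta(0.5, 2.0, n_sites)
    p3 = rng.beta(0.5, 2.0, n_sites)
    pO = np.zeros(n_sites)
    intro = np.zeros(n_sites, dtype=bool)
    if introgressed_span is not None:
        intro = (pos >= introgressed_span[0]) & (pos < introgressed_span[1])
    elif frac_introgressed > 0:
        intro = rng.uniform(size=n_sites) < frac_introgressed
    p2[intro] = p3[intro]
    return pd.DataFrame({"chrom": "chr18", "pos": pos, "p1": p1, "p2": p2,
                         "p3": p3, "pO": pO, "introgressed": intro})
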