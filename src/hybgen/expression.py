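"""Negative-binomial differential expression with a twofold + FDR-5% call
rule, dual-reference consistency filtering and candidate-gene intersection.

The test is a per-gene NB log-linear model: counts for gene *g* in sample *s*
are NB with mean ``sf_s * q_g * exp(x_s' beta_g)`` and dispersion ``alpha_g``.
Library sizes enter as median-of-ratios size factors (offset), dispersion is
estimated per gene by the method of moments with a small-sample floor and an
optional shrink toward the mean-dispersion trend, and the contrast coefficient
is tested with a two-sided Wald test followed by Benjamini-Hochberg adjustment
across genes.  A gene is *called* differentially expressed only with
|log2 fold change| >= 1 and adjusted p < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

LN2 = np.log(2.0)


@dataclass
class ExpressionMatrix:
    """Integer gene x sample counts with sample metadata and size factors."""

    counts: pd.DataFrame
    meta: pd.DataFrame
    sf: pd.Series | None = None

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.counts.columns.equals(self.meta.index):
            self.meta = self.meta.loc[self.counts.columns]

    def normalize(self) -> "ExpressionMatrix":
        self.sf = size_factors(self.counts)
        return self


def size_factors(counts: pd.DataFrame, fallback: bool = False) -> pd.Series:
    """Median-of-ratios library size factors.

    For genes with nonzero counts in every sample, each sample's factor is the
    median of ``count / geometric-mean-across-samples``.  With no such gene
    the default is to raise; ``fallback=True`` instead uses per-gene geometric
    means over the positive counts only (a pseudo-reference over expressed
    genes).
    """
    m = counts.to_numpy(dtype=float)
    if m.shape[1] == 1:
        return pd.Series([1.0], index=counts.columns, name="sf")
    all_nonzero = (m > 0).all(axis=1)
    if not all_nonzero.any():
        if not fallback:
            raise ValueError("no gene has nonzero counts in all samples; "
                             "rerun with fallback=True to use a positive-count "
                             "pseudo-reference")
        expressed = (m > 0).any(axis=1)
        logm = np.where(m > 0, np.log(np.where(m > 0, m, 1.0)), np.nan)
        geo = np.exp(np.nanmean(logm[expressed], axis=1))
        ratios = np.where(m[expressed] > 0, m[expressed] / geo[:, None], np.nan)
        sf = np.nanmedian(ratios, axis=0)
    else:
        geo = np.exp(np.mean(np.log(m[all_nonzero]), axis=1))
        sf = np.median(m[all_nonzero] / geo[:, None], axis=0)
    return pd.Series(sf, index=counts.columns, name="sf")


def merge_gene_fragments(counts: pd.DataFrame, merge_map: pd.DataFrame) -> pd.DataFrame:
    """Sum counts of annotated gene fragments into single gene models.

    ``merge_map`` columns: fragment, gene.  Fragmented annotations (several
    gene models that are exons of one gene) otherwise dilute per-gene counts.
    """
    mapping = dict(zip(merge_map["fragment"], merge_map["gene"]))
    idx = counts.index.to_series().map(lambda g: mapping.get(g, g))
    return counts.groupby(idx.to_numpy()).sum()


# ---------------------------------------------------------------------------
# Dispersion
# ---------------------------------------------------------------------------

ALPHA_FLOOR = 1e-8


def moment_dispersions(counts: pd.DataFrame, sf: pd.Series, groups: pd.Series,
                       shrink: bool = True) -> np.ndarray:
    """Per-gene NB dispersions by the method of moments.

    Normalized counts are pooled within group levels; for each gene
    ``alpha = (s2 - mu) / mu**2`` averaged over groups, floored at 1e-8.
    With ``shrink`` the gene estimate is blended 50:50 with a binned-median
    mean-dispersion trend, stabilising the many noisy per-gene estimates that
    a handful of replicates gives.
    """
    norm = counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    alphas = np.zeros(len(counts))
    weights = np.zeros(len(counts))
    for level in groups.unique():
        cols = (groups == level).to_numpy()
        if cols.sum() < 2:
            continue
        mu = norm[:, cols].mean(axis=1)
        v = norm[:, cols].var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(mu > 0, (v - mu) / mu ** 2, 0.0)
        alphas += np.nan_to_num(a)
        weights += 1
    alpha = np.where(weights > 0, alphas / np.maximum(weights, 1), 0.0)
    alpha = np.maximum(alpha, ALPHA_FLOOR)
    if shrink and len(alpha) >= 50:
        mu_all = norm.mean(axis=1)
        order = np.argsort(mu_all)
        nbins = max(5, len(alpha) // 200)
        bins = np.array_split(order, nbins)
        trend = np.empty_like(alpha)
        for b in bins:
            trend[b] = np.median(alpha[b])
        alpha = np.maximum(0.5 * alpha + 0.5 * trend, ALPHA_FLOOR)
    return alpha


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

@dataclass
class DEResult:
    gene: str
    base_mean: float
    log2fc: float
    se: float
    p: float
    padj: float = np.nan
    called: bool = False


def _design_matrix(meta: pd.DataFrame, contrast: tuple[str, str, str],
                   covariates: tuple[str, ...]) -> tuple[np.ndarray, int]:
    """Intercept + contrast indicator + dummy-coded covariates.

    Returns (X, index of the contrast column).  The contrast indicator is 1
    for the first named level, 0 for the second (reference), so the tested
    coefficient is log(level1 / level2).
    """
    factor, level1, level2 = contrast
    levels = set(meta[factor])
    for lv in (level1, level2):
        if lv not in levels:
            raise ValueError(f"contrast level {lv!r} absent from {factor!r}")
    x = (meta[factor] == level1).astype(float).to_numpy()
    cols = [np.ones(len(meta)), x]
    for cov in covariates:
        if cov not in meta.columns:
            continue
        d = pd.get_dummies(meta[cov], drop_first=True, dtype=float)
        for c in d.columns:
            if d[c].nunique() > 1:
                cols.append(d[c].to_numpy())
    return np.column_stack(cols), 1


def nb_de_test(matrix: ExpressionMatrix, contrast: tuple[str, str, str],
               covariates: tuple[str, ...] = ("sex", "batch"),
               shrink_dispersion: bool = True) -> pd.DataFrame:
    """Per-gene NB Wald test of a two-level contrast.

    ``contrast`` is ``(column, level, reference_level)``; covariate columns
    present in the metadata enter as fixed effects.  Samples outside the two
    contrast levels are dropped.  Returns a DataFrame with gene, base_mean,
    log2fc (level vs reference), se, p, padj (BH across testable genes) and
    the twofold + FDR-5% ``called`` flag.  All-zero genes are untestable
    (p = NA, never called).
    """
    factor, level1, level2 = contrast
    keep = matrix.meta[factor].isin([level1, level2])
    if keep.sum() == 0 or (matrix.meta[factor] == level1).sum() < 2 \
            or (matrix.meta[factor] == level2).sum() < 2:
        raise ValueError("need >=2 samples per contrast level")
    meta = matrix.meta[keep]
    counts = matrix.counts.loc[:, keep.to_numpy()]
    sf = matrix.sf[keep.to_numpy()] if matrix.sf is not None else size_factors(counts)
    X, ci = _design_matrix(meta, contrast, covariates)
    offset = np.log(sf.to_numpy())
    alpha = moment_dispersions(counts, sf, meta[factor], shrink=shrink_dispersion)
    rows = []
    y_all = counts.to_numpy(dtype=float)
    base_means = (y_all / sf.to_numpy()[None, :]).mean(axis=1)
    for i, gene in enumerate(counts.index):
        y = y_all[i]
        if y.sum() == 0:
            rows.append((gene, 0.0, np.nan, np.nan, np.nan))
            continue
        fam = sm.families.Poisson() if alpha[i] <= ALPHA_FLOOR \
            else sm.families.NegativeBinomial(alpha=alpha[i])
        try:
            res = sm.GLM(y, X, family=fam, offset=offset).fit()
            beta, se = res.params[ci], res.bse[ci]
            if not np.isfinite(se) or se == 0:
                raise ValueError("degenerate fit")
            z = beta / se
            p = 2 * stats.norm.sf(abs(z))
            rows.append((gene, base_means[i], beta / LN2, se / LN2, p))
        except Exception:
            rows.append((gene, base_means[i], np.nan, np.nan, np.nan))
    out = pd.DataFrame(rows, columns=["gene", "base_mean", "log2fc", "se", "p"])
    testable = out["p"].notna()
    out["padj"] = np.nan
    if testable.any():
        out.loc[testable, "padj"] = multipletests(out.loc[testable, "p"], method="fdr_bh")[1]
    out["called"] = de_called(out)
    return out


def de_called(results: pd.DataFrame, fc: float = 2.0, fdr: float = 0.05) -> pd.Series:
    """Twofold + FDR call rule: |log2FC| >= log2(fc) and padj < fdr."""
    return ((results["log2fc"].abs() >= np.log2(fc)) &
            (results["padj"] < fdr)).fillna(False)


def de_call(results: pd.DataFrame, fc: float = 2.0, fdr: float = 0.05) -> set[str]:
    """The called differentially-expressed gene set under the stated rule."""
    return set(results.loc[de_called(results, fc, fdr), "gene"])


def reference_bias_filter(results_ref_a: pd.DataFrame,
                          results_ref_b: pd.DataFrame,
                          fc: float = 2.0, fdr: float = 0.05) -> set[str]:
    """Genes whose DE call is consistent under both reference genomes.

    Mapping to a single reference can fabricate or invert expression
    differences for genes diverged between species.  A gene called under
    reference A survives only if it is also called under reference B with a
    log2 fold change of the same sign.
    """
    a = results_ref_a.set_index("gene")
    b = results_ref_b.set_index("gene")
    called_a = de_called(results_ref_a, fc, fdr).to_numpy()
    survivors = set()
    missing = 0
    for gene in a.index[called_a]:
        if gene not in b.index:
            missing += 1
            continue
        rb = b.loc[gene]
        called_b = (abs(rb["log2fc"]) >= np.log2(fc)) and (rb["padj"] < fdr)
        if called_b and np.sign(rb["log2fc"]) == np.sign(a.loc[gene, "log2fc"]):
            survivors.add(gene)
    if missing:
        log.warning("reference_bias_filter: %d called genes absent from the "
                    "second reference's results", missing)
    return survivors


@dataclass
class Interval:
    """A genomic interval (0-based half-open), e.g. the QTL candidate region."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("malformed interval: end <= start")

    def contains(self, chrom: pd.Series, pos: pd.Series) -> pd.Series:
        return (chrom == self.chrom) & (pos >= self.start) & (pos < self.end)


def candidate_intersection(species_de: pd.DataFrame, f1_vs_cyd_de: pd.DataFrame,
                           qtl_interval: Interval, gene_coords: pd.DataFrame,
                           bc3_de: pd.DataFrame | None = None) -> pd.DataFrame:
    """Candidate genes under the dominance logic.

    The preference alleles act dominantly, so genes that drive the behaviour
    should differ both between the species and between F1 hybrids (which carry
    one dominant allele) and the recessive parent, in the same direction, and
    lie inside the QTL interval.  ``gene_coords`` columns: gene, chrom, pos
    (representative position).  If ``bc3_de`` is given, candidates are
    annotated with whether they are also called in the backcross comparison.
    """
    coords = gene_coords.set_index("gene")
    in_qtl = coords[qtl_interval.contains(coords["chrom"], coords["pos"])].index
    sp = species_de.set_index("gene")
    f1 = f1_vs_cyd_de.set_index("gene")
    rows = []
    for gene in in_qtl:
        if gene not in sp.index or gene not in f1.index:
            continue
        s, f = sp.loc[gene], f1.loc[gene]
        if not (s["called"] and f["called"]):
            continue
        if np.sign(s["log2fc"]) != np.sign(f["log2fc"]):
            continue
        row = {"gene": gene, "log2fc_species": s["log2fc"], "log2fc_f1": f["log2fc"]}
        if bc3_de is not None:
            b = bc3_de.set_index("gene")
            row["called_bc3"] = bool(b.loc[gene, "called"]) if gene in b.index else False
        rows.append(row)
    cols = ["gene", "log2fc_species", "log2fc_f1"] + (["called_bc3"] if bc3_de is not None else [])
    return pd.DataFrame(rows, columns=cols)
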