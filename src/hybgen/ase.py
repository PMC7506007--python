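"""Allele-specific expression in hybrids and cis/trans regulatory
classification.

In an F1 hybrid, both parental alleles share one trans-acting environment, so
an expression difference between the two alleles within the same individuals
(allele-specific expression, ASE) isolates cis-regulatory divergence.
Comparing the allelic log2 fold change *A* in hybrids with the parental
between-species log2 fold change *P* then decomposes regulatory divergence:
pure cis predicts A = P (the y = x diagonal), pure trans predicts A = 0 with
P != 0, and significant A with A != P indicates a combination of cis- and
trans-acting factors.

The allele test is paired within individuals — the model is
``~ 0 + individual + allele`` with library size factors fixed to 1, i.e. no
between-sample normalization, because the comparison never crosses samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

log = logging.getLogger(__name__)

LN2 = np.log(2.0)


def sum_allele_counts(per_site: pd.DataFrame,
                      gene_map: pd.DataFrame | None = None) -> pd.DataFrame:
    """Sum per-site species-allele read counts into per-gene totals.

    ``per_site`` columns: chrom, pos, gene (optional if ``gene_map`` given),
    individual, count_mel, count_cyd.  ``gene_map`` columns: chrom, pos, gene.
    A site assigned to more than one gene is an error: ambiguity must be
    resolved upstream.  Individuals with zero coverage for a gene keep an
    explicit (0, 0) row.
    """
    df = per_site
    if gene_map is not None:
        dup = gene_map.duplicated(subset=["chrom", "pos"], keep=False)
        if dup.any():
            raise ValueError("gene_map assigns some sites to more than one gene")
        df = df.merge(gene_map, on=["chrom", "pos"], how="inner")
    elif df.duplicated(subset=["chrom", "pos", "individual"], keep=False).any() and \
            df.groupby(["chrom", "pos"])["gene"].nunique().gt(1).any():
        raise ValueError("some sites are assigned to more than one gene")
    out = (df.groupby(["gene", "individual"], as_index=False)
             [["count_mel", "count_cyd"]].sum())
    zero = (out["count_mel"] + out["count_cyd"]) == 0
    if zero.any():
        log.info("sum_allele_counts: %d gene x individual entries with zero coverage",
                 int(zero.sum()))
    return out


# ---------------------------------------------------------------------------
# Paired allele test
# ---------------------------------------------------------------------------

@dataclass
class ASEResult:
    gene: str
    log2fc: float  # allelic log2FC, mel vs cyd allele
    se: float
    p: float
    n_individuals: int
    called: bool = False


def _paired_nb_wald(mel: np.ndarray, cyd: np.ndarray) -> tuple[float, float, float]:
    """Wald test of the allele effect in a paired NB GLM.

    Counts are modelled as NB with log mean = individual effect + a * allele,
    no offset (size factors 1).  Dispersion is pooled per gene from the
    Pearson statistic of the Poisson fit (quasi-likelihood flavour): the
    excess of Pearson chi-square over its dof, divided by the mean fitted
    value, estimates alpha; at or below zero the Poisson fit stands.
    Returns (log2fc, se_log2, p).
    """
    n = len(mel)
    y = np.concatenate([mel, cyd]).astype(float)
    ind = np.tile(np.eye(n), 2).T
    allele = np.concatenate([np.ones(n), np.zeros(n)])
    X = np.column_stack([ind, allele])
    pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    dof = max(2 * n - (n + 1), 1)
    phi = pois.pearson_chi2 / dof
    mu_bar = float(np.mean(pois.mu))
    alpha = max(0.0, (phi - 1.0) / max(mu_bar, 1e-12))
    res = pois if alpha <= 0 else sm.GLM(
        y, X, family=sm.families.NegativeBinomial(alpha=alpha)).fit()
    a, se = res.params[-1], res.bse[-1]
    p = 2 * stats.norm.sf(abs(a / se)) if se > 0 and np.isfinite(se) else np.nan
    return a / LN2, se / LN2, p


def ase_test(table: pd.DataFrame, min_total: int = 10,
             fc: float = 2.0, p_threshold: float = 0.05) -> pd.DataFrame:
    """Per-gene paired test of allele-specific expression.

    For each gene, individuals with total informative coverage below
    ``min_total`` are dropped; genes left with fewer than two individuals are
    untestable (NA).  A gene is *called* allele-specifically expressed only
    with |allelic log2FC| >= log2(fc) and raw Wald p < ``p_threshold`` (raw p,
    matching the within-individual test's reporting convention).
    """
    rows = []
    for gene, sub in table.groupby("gene", sort=True):
        tot = sub["count_mel"] + sub["count_cyd"]
        sub = sub[tot >= min_total]
        if len(sub) < 2:
            rows.append((gene, np.nan, np.nan, np.nan, len(sub), False))
            continue
        a, se, p = _paired_nb_wald(sub["count_mel"].to_numpy(),
                                   sub["count_cyd"].to_numpy())
        called = bool(abs(a) >= np.log2(fc) and p < p_threshold) if np.isfinite(p) else False
        rows.append((gene, a, se, p, len(sub), called))
    return pd.DataFrame(rows, columns=["gene", "log2fc", "se", "p",
                                       "n_individuals", "called"])


def ase_binomial_test(table: pd.DataFrame, min_total: int = 10) -> pd.DataFrame:
    """Paired-binomial cross-check of the allele effect.

    Conditional on each individual's total, the mel count is binomial with a
    shared log-odds equal to the allelic log fold change; an exact-likelihood
    binomial GLM on the pooled pairs provides an independent route to the same
    quantity, used as an oracle against :func:`ase_test`.
    """
    rows = []
    for gene, sub in table.groupby("gene", sort=True):
        tot = (sub["count_mel"] + sub["count_cyd"]).to_numpy()
        keep = tot >= min_total
        if keep.sum() < 2:
            rows.append((gene, np.nan, np.nan, np.nan))
            continue
        y = np.column_stack([sub["count_mel"].to_numpy()[keep],
                             sub["count_cyd"].to_numpy()[keep]])
        res = sm.GLM(y, np.ones((keep.sum(), 1)),
                     family=sm.families.Binomial()).fit()
        a, se = res.params[0], res.bse[0]
        p = 2 * stats.norm.sf(abs(a / se))
        rows.append((gene, a / LN2, se / LN2, p))
    return pd.DataFrame(rows, columns=["gene", "log2fc", "se", "p"])


def assignment_bias_check(table: pd.DataFrame, tolerance: float = 0.1,
                          min_genes: int = 100) -> dict:
    """Genome-wide check that allele assignment is unbiased.

    Pools counts per gene and summarises the distribution of allelic log2
    fold changes; with no assignment bias it is centred at zero.  Returns the
    median and mean and a ``flagged`` bool (|median| > tolerance).  Below
    ``min_genes`` genes the check warns and never flags.
    """
    pooled = table.groupby("gene")[["count_mel", "count_cyd"]].sum()
    a = np.log2((pooled["count_mel"] + 0.5) / (pooled["count_cyd"] + 0.5))
    med, mean = float(a.median()), float(a.mean())
    if len(pooled) < min_genes:
        log.warning("assignment_bias_check: only %d genes (<%d); not flagging",
                    len(pooled), min_genes)
        return {"n_genes": len(pooled), "median": med, "mean": mean, "flagged": False}
    return {"n_genes": len(pooled), "median": med, "mean": mean,
            "flagged": bool(abs(med) > tolerance)}


# ---------------------------------------------------------------------------
# cis/trans classification
# ---------------------------------------------------------------------------

CIS_ONLY = "cis_only"
TRANS_ONLY = "trans_only"
CIS_PLUS_TRANS = "cis_plus_trans"
CONSERVED = "conserved"
AMBIGUOUS = "ambiguous"


@dataclass
class RegulatoryClass:
    gene: str
    parental_log2fc: float
    allelic_log2fc: float
    regulatory_class: str


def cis_trans_classify(gene: str, parental_log2fc: float, parental_se: float,
                       allelic_log2fc: float, allelic_se: float,
                       level: float = 0.05) -> RegulatoryClass:
    """Classify a gene's regulatory divergence from (P, A) and their SEs.

    Three two-sided Wald tests at ``level``: A vs 0, P vs 0 and A - P vs 0
    (pooled SE, the two estimates coming from disjoint sample sets).  The
    decision table:

    ==========  ==========  ==============  ================
    A != 0      P != 0      A - P != 0      class
    ==========  ==========  ==============  ================
    yes         yes         no              cis_only (y = x)
    no          yes         --              trans_only
    yes         --          yes             cis_plus_trans
    no          no          --              conserved
    otherwise                               ambiguous
    ==========  ==========  ==============  ================
    """
    P, A = parental_log2fc, allelic_log2fc
    if any(not np.isfinite(v) for v in (P, parental_se, A, allelic_se)):
        return RegulatoryClass(gene, P, A, AMBIGUOUS)
    zcrit = stats.norm.ppf(1 - level / 2)
    sig_a = abs(A / allelic_se) > zcrit
    sig_p = abs(P / parental_se) > zcrit
    se_diff = np.sqrt(allelic_se ** 2 + parental_se ** 2)
    sig_diff = abs((A - P) / se_diff) > zcrit
    if sig_a and sig_diff:
        cls = CIS_PLUS_TRANS
    elif sig_a and sig_p and not sig_diff:
        cls = CIS_ONLY
    elif sig_p and not sig_a:
        cls = TRANS_ONLY
    elif not sig_p and not sig_a:
        cls = CONSERVED
    else:
        cls = AMBIGUOUS
    return RegulatoryClass(gene, P, A, cls)


def classify_table(de_results: pd.DataFrame, ase_results: pd.DataFrame,
                   level: float = 0.05) -> pd.DataFrame:
    """Vector form of :func:`cis_trans_classify` over shared genes."""
    de = de_results.set_index("gene")
    rows = []
    for _, r in ase_results.iterrows():
        gene = r["gene"]
        if gene not in de.index:
            rows.append((gene, np.nan, r["log2fc"], AMBIGUOUS))
            continue
        d = de.loc[gene]
        rc = cis_trans_classify(gene, d["log2fc"], d["se"], r["log2fc"], r["se"], level)
        rows.append((gene, rc.parental_log2fc, rc.allelic_log2fc, rc.regulatory_class))
    return pd.DataFrame(rows, columns=["gene", "parental_log2fc",
                                       "allelic_log2fc", "regulatory_class"])
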