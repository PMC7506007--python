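"""Windowed inference of hybrid genome composition from diagnostic variants,
and pupal sexing from Z-linked heterozygosity.

A backcross hybrid's genome is a mosaic of heterozygous (mel/cyd) and
homozygous (cyd/cyd) regions.  At sites fixed for opposite alleles in the two
species, the fraction of species-diagnostic alleles a sample carries in a
genomic window separates the two states: a heterozygous window looks like an
F1 (carries both species' alleles everywhere), a homozygous window like a pure
recurrent-parent individual.  Windows are therefore called by comparing their
sharing profile with F1 and pure-species control profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

HET = "cyd/melp"
HOM = "cyd/cyd"
NA = "NA"


def _carries(gt: pd.Series, ref: pd.Series, alt: pd.Series, allele: pd.Series) -> np.ndarray:
    """Whether each genotype carries >=1 copy of ``allele`` (by ref/alt lookup)."""
    parts = gt.astype(str).str.split("/", expand=True).astype(int)
    a0 = np.where(parts[0] == 0, ref, alt)
    a1 = np.where(parts[1] == 0, ref, alt)
    return (a0 == allele.to_numpy()) | (a1 == allele.to_numpy())


def window_share_fractions(sample_genotypes: pd.DataFrame, markers: pd.DataFrame,
                           window_bp: int = 100_000, min_informative: int = 30,
                           chrom_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """Per-window fractions of diagnostic alleles shared with each species.

    ``sample_genotypes``: one sample's filtered records (chrom, pos, ref, alt,
    gt).  ``markers``: diagnostic-marker table (chrom, pos, allele_mel,
    allele_cyd).  For each non-overlapping ``window_bp`` window, ``frac_mel``
    is the fraction of informative markers (markers with a genotype call) at
    which the sample carries at least one mel-diagnostic allele, likewise
    ``frac_cyd``.  Windows with ``n_informative`` <= ``min_informative`` are
    ineligible (call NA); the default reproduces the "more than 30 variants"
    eligibility rule at 100-kb scale.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    g = sample_genotypes.merge(markers, on=["chrom", "pos"], how="inner")
    if g.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_informative",
                                     "frac_mel", "frac_cyd", "call"])
    g = g.sort_values(["chrom", "pos"])
    g["carries_mel"] = _carries(g["gt"], g["ref"], g["alt"], g["allele_mel"])
    g["carries_cyd"] = _carries(g["gt"], g["ref"], g["alt"], g["allele_cyd"])
    g["start"] = ((g["pos"] - 1) // window_bp) * window_bp
    agg = g.groupby(["chrom", "start"], as_index=False).agg(
        n_informative=("pos", "size"),
        frac_mel=("carries_mel", "mean"),
        frac_cyd=("carries_cyd", "mean"))
    agg["end"] = agg["start"] + window_bp
    if chrom_lengths:
        agg["end"] = np.minimum(agg["end"], agg["chrom"].map(chrom_lengths).fillna(agg["end"]))
    agg["call"] = NA
    ineligible = agg["n_informative"] <= min_informative
    agg.loc[ineligible, ["frac_mel", "frac_cyd"]] = agg.loc[ineligible, ["frac_mel", "frac_cyd"]]
    return agg[["chrom", "start", "end", "n_informative", "frac_mel", "frac_cyd", "call"]]


def classify_windows(windows: pd.DataFrame, f1_profile: pd.DataFrame,
                     cydno_profile: pd.DataFrame,
                     min_informative: int = 30) -> pd.DataFrame:
    """Assign each eligible window the nearest control profile.

    Control profiles are ``window_share_fractions`` outputs for an F1 hybrid
    and a pure recurrent-parent individual.  Each eligible window (its own
    and both controls' ``n_informative`` above the floor) is called
    heterozygous if its (frac_mel, frac_cyd) point is nearer (Euclidean) the
    F1 control for the same window, homozygous if nearer the pure-cydno
    control; exact ties and missing controls give NA.
    """
    w = windows.copy()
    key = ["chrom", "start"]
    f1 = f1_profile.set_index(key)[["frac_mel", "frac_cyd", "n_informative"]]
    cy = cydno_profile.set_index(key)[["frac_mel", "frac_cyd", "n_informative"]]
    calls = []
    for _, row in w.iterrows():
        k = (row["chrom"], row["start"])
        if row["n_informative"] <= min_informative or k not in f1.index or k not in cy.index:
            calls.append(NA)
            continue
        c1, c2 = f1.loc[k], cy.loc[k]
        if c1["n_informative"] <= min_informative or c2["n_informative"] <= min_informative:
            calls.append(NA)
            continue
        p = np.array([row["frac_mel"], row["frac_cyd"]])
        d_f1 = np.linalg.norm(p - c1[["frac_mel", "frac_cyd"]].to_numpy(dtype=float))
        d_cy = np.linalg.norm(p - c2[["frac_mel", "frac_cyd"]].to_numpy(dtype=float))
        calls.append(HET if d_f1 < d_cy else HOM if d_cy < d_f1 else NA)
    w["call"] = calls
    return w


def genome_het_fraction(windows: pd.DataFrame, exclude_chrom: str | None = "chr18") -> float:
    """Fraction of called windows that are heterozygous, excluding one chromosome.

    Excluding the chromosome under phenotypic selection, the expectation for
    an n-backcross-meiosis genome is 2**(-n) (1/16 for the default pedigree).
    """
    w = windows[windows["call"] != NA]
    if exclude_chrom is not None:
        w = w[w["chrom"] != exclude_chrom]
    if len(w) == 0:
        raise ValueError("no called windows outside the excluded chromosome")
    return float((w["call"] == HET).mean())


@dataclass
class SexCall:
    """Sex inferred from the proportion of heterozygous biallelic Z-linked calls."""

    sample: str
    z_het_proportion: float
    call: str  # male / female / ambiguous
    n_sites: int = 0


def sex_from_z_heterozygosity(z_records: pd.DataFrame, sample: str = "",
                              threshold: float = 0.01, min_sites: int = 50,
                              male_factor: float = 3.0) -> SexCall:
    """Sex a pupa from Z-chromosome heterozygosity.

    Females are ZW, hence effectively hemizygous on the Z: their biallelic
    calls come out ~0% heterozygous (residual calls are genotyping error).
    Males (ZZ) show real heterozygosity an order of magnitude above that
    error level.  ``female`` below ``threshold``, ``male`` at or above
    ``male_factor * threshold`` (a guard band keeping borderline samples
    unassigned), ``ambiguous`` between the bands or with too few sites.
    """
    gt = z_records["gt"].astype(str)
    called = gt.str.match(r"^\d+/\d+$")
    n = int(called.sum())
    if n < min_sites:
        log.warning("sex_from_z_heterozygosity(%s): only %d Z-linked calls (<%d)",
                    sample, n, min_sites)
        prop = float("nan") if n == 0 else _het_prop(gt[called])
        return SexCall(sample, prop if n else 0.0, "ambiguous", n)
    prop = _het_prop(gt[called])
    if prop < threshold:
        call = "female"
    elif prop >= male_factor * threshold:
        call = "male"
    else:
        call = "ambiguous"
    return SexCall(sample, prop, call, n)


def _het_prop(gt: pd.Series) -> float:
    parts = gt.str.split("/", expand=True)
    return float((parts[0] != parts[1]).mean())
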