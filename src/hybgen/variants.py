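"""Genotype-record filtering, species-fixed allele calling and fixed
protein-coding substitutions.

Records are handled as pandas DataFrames with one row per sample x site and
columns ``sample, chrom, pos, ref, alt, n_alt, gt, dp, gq, qd, fs`` (``gt`` is
an unphased allele-index pair such as ``"0/1"``; ``pos`` is 1-based).  All
filters are total functions: records failing a rule, or missing a required
field, are dropped and counted, never raised on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

log = logging.getLogger(__name__)

RNA_COLUMNS = ["qd", "fs", "dp", "n_alt", "gt"]
RESEQ_COLUMNS = ["dp", "gq", "n_alt", "gt"]


def _called(gt: pd.Series) -> pd.Series:
    return gt.notna() & ~gt.astype(str).str.contains(r"\.")


def _drop_summary(name: str, reasons: dict[str, int]) -> None:
    total = sum(reasons.values())
    log.info("%s: dropped %d records (%s)", name, total,
             ", ".join(f"{k}={v}" for k, v in reasons.items() if v))


def filter_rna_genotypes(records: pd.DataFrame) -> pd.DataFrame:
    """Quality filter for genotypes called from RNA-seq reads.

    Keeps biallelic called genotypes with quality-by-depth QD > 2, strand
    bias FS < 30 and depth DP > 4 (all bounds strict).  Records missing any
    required field are dropped and counted in the log summary.
    """
    r = records
    missing = r[RNA_COLUMNS].isna().any(axis=1)
    ok_call = _called(r["gt"])
    reasons = {
        "missing_field": int(missing.sum()),
        "uncalled": int((~ok_call & ~missing).sum()),
    }
    keep = ~missing & ok_call
    for name, cond in [("qd<=2", r["qd"] > 2), ("fs>=30", r["fs"] < 30),
                       ("dp<=4", r["dp"] > 4), ("multiallelic", r["n_alt"] == 1)]:
        reasons[name] = int((keep & ~cond.fillna(False)).sum())
        keep &= cond.fillna(False)
    _drop_summary("filter_rna_genotypes", reasons)
    return r[keep].copy()


def filter_reseq_genotypes(records: pd.DataFrame) -> pd.DataFrame:
    """Quality filter for genome-resequencing genotypes.

    Keeps biallelic called genotypes with 10 < DP < 100 and GQ > 30.
    """
    r = records
    missing = r[RESEQ_COLUMNS].isna().any(axis=1)
    ok_call = _called(r["gt"])
    reasons = {
        "missing_field": int(missing.sum()),
        "uncalled": int((~ok_call & ~missing).sum()),
    }
    keep = ~missing & ok_call
    for name, cond in [("dp", (r["dp"] > 10) & (r["dp"] < 100)),
                       ("gq<=30", r["gq"] > 30), ("multiallelic", r["n_alt"] == 1)]:
        reasons[name] = int((keep & ~cond.fillna(False)).sum())
        keep &= cond.fillna(False)
    _drop_summary("filter_reseq_genotypes", reasons)
    return r[keep].copy()


def site_summaries(records: pd.DataFrame) -> pd.DataFrame:
    """Per-site allele summaries for one species' filtered records.

    Returns one row per (chrom, pos) with ref/alt, alt-allele frequency
    ``af`` over called alleles, the number of samples called ``n_called`` and
    the number carrying at least one alt allele ``n_carriers``.  Missing
    genotypes never enter the denominator.
    """
    r = records[_called(records["gt"])].copy()
    alleles = r["gt"].astype(str).str.split("/", expand=True).astype(int)
    r["n_alt_alleles"] = (alleles > 0).sum(axis=1)
    grp = r.groupby(["chrom", "pos", "ref", "alt"], sort=True, as_index=False).agg(
        n_called=("sample", "nunique"),
        alt_alleles=("n_alt_alleles", "sum"),
        n_carriers=("n_alt_alleles", lambda s: int((s > 0).sum())),
    )
    grp["af"] = grp["alt_alleles"] / (2 * grp["n_called"])
    return grp.drop(columns="alt_alleles")


def call_fixed(summaries: pd.DataFrame, af_threshold: float = 0.9) -> pd.DataFrame:
    """Sites where one allele is (near-)fixed in the species: AF > threshold.

    Works on either the alt allele (``af`` > threshold) or the ref allele
    (1 - ``af`` > threshold); indels (non-single-base alleles) are excluded.
    Returns chrom, pos, allele, af(the fixed allele's frequency).
    """
    if not (0.5 < af_threshold <= 1.0):
        raise ValueError("af_threshold must lie in (0.5, 1]")
    s = summaries
    snv = (s["ref"].str.len() == 1) & (s["alt"].str.len() == 1)
    alt_fixed = snv & (s["af"] > af_threshold)
    ref_fixed = snv & ((1.0 - s["af"]) > af_threshold)
    out = pd.concat([
        s.loc[alt_fixed, ["chrom", "pos"]].assign(allele=s.loc[alt_fixed, "alt"],
                                                  af=s.loc[alt_fixed, "af"]),
        s.loc[ref_fixed, ["chrom", "pos"]].assign(allele=s.loc[ref_fixed, "ref"],
                                                  af=1.0 - s.loc[ref_fixed, "af"]),
    ], ignore_index=True)
    return out.sort_values(["chrom", "pos"]).reset_index(drop=True)


def diagnostic_markers(fixed_mel: pd.DataFrame, fixed_cyd: pd.DataFrame) -> pd.DataFrame:
    """Sites fixed for opposite alleles in the two species.

    The intersection on (chrom, pos) of the two fixed-allele sets, keeping
    sites whose fixed alleles differ.  Symmetric in its arguments (up to the
    allele column labels).
    """
    m = fixed_mel.merge(fixed_cyd, on=["chrom", "pos"], suffixes=("_mel", "_cyd"))
    m = m[m["allele_mel"] != m["allele_cyd"]]
    return (m[["chrom", "pos", "allele_mel", "allele_cyd"]]
            .sort_values(["chrom", "pos"]).reset_index(drop=True))


# ---------------------------------------------------------------------------
# Fixed protein-coding substitutions
# ---------------------------------------------------------------------------

@dataclass
class CodingSubstitution:
    """A fixed between-species substitution inside a coding sequence."""

    gene: str
    codon_index: int  # 0-based codon within the CDS
    ref_codon: str
    alt_codon: str
    effect: str | None = None  # synonymous / missense / stop_gained / stop_lost
    provean_score: float | None = None
    chrom: str | None = None
    pos: int | None = None


def fixed_coding_substitutions(rna_summaries: pd.DataFrame,
                               reseq_summaries: pd.DataFrame,
                               cds: pd.DataFrame,
                               af_threshold: float = 0.8,
                               min_rna_carriers: int = 7,
                               min_reseq_called: int = 8) -> pd.DataFrame:
    """Substitutions fixed in a species and validated across data sets.

    Keeps variants with AF > ``af_threshold`` and at least ``min_rna_carriers``
    carrier individuals in the RNA-derived summaries, that were also called in
    at least ``min_reseq_called`` resequencing samples, restricted to CDS
    intervals.  ``cds`` columns: chrom, start, end (1-based inclusive),
    strand, gene, frame.  Variants with no CDS annotation are skipped with a
    warning count.
    """
    r = rna_summaries
    keep = (r["af"] > af_threshold) & (r["n_carriers"] >= min_rna_carriers)
    cand = r[keep].merge(
        reseq_summaries[["chrom", "pos", "n_called"]].rename(columns={"n_called": "n_reseq"}),
        on=["chrom", "pos"], how="left")
    cand = cand[cand["n_reseq"].fillna(0) >= min_reseq_called]
    rows, skipped = [], 0
    for _, v in cand.iterrows():
        hit = cds[(cds["chrom"] == v["chrom"]) & (cds["start"] <= v["pos"]) &
                  (v["pos"] <= cds["end"])]
        if hit.empty:
            skipped += 1
            continue
        h = hit.iloc[0]
        rows.append({"chrom": v["chrom"], "pos": v["pos"], "ref": v["ref"],
                     "alt": v["alt"], "af": v["af"], "n_carriers": v["n_carriers"],
                     "n_reseq": int(v["n_reseq"]), "gene": h["gene"],
                     "cds_start": h["start"], "strand": h["strand"]})
    if skipped:
        log.warning("fixed_coding_substitutions: %d variants without CDS annotation skipped", skipped)
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "af",
                                       "n_carriers", "n_reseq", "gene",
                                       "cds_start", "strand"])


_STANDARD = CodonTable.unambiguous_dna_by_name["Standard"]
_VALID = set("ACGT")


def classify_coding_effect(ref_codon: str, alt_codon: str) -> str:
    """Effect class of a codon change under the standard genetic code.

    Returns one of ``synonymous``, ``missense``, ``stop_gained``,
    ``stop_lost``.  Codons must be length-3 over A/C/G/T.
    """
    ref_codon, alt_codon = ref_codon.upper(), alt_codon.upper()
    for c in (ref_codon, alt_codon):
        if len(c) != 3 or not set(c) <= _VALID:
            raise ValueError(f"invalid codon {c!r}")
    ref_stop = ref_codon in _STANDARD.stop_codons
    alt_stop = alt_codon in _STANDARD.stop_codons
    if ref_stop and alt_stop:
        return "synonymous"
    if alt_stop:
        return "stop_gained"
    if ref_stop:
        return "stop_lost"
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    return "synonymous" if ref_aa == alt_aa else "missense"


def codon_change(cds_seq: str, offset_in_cds: int, ref: str, alt: str,
                 strand: str = "+") -> tuple[int, str, str]:
    """Ref and alt codon for a substitution at 0-based ``offset_in_cds``.

    ``cds_seq`` is the coding strand sequence.  For minus-strand genes the
    genomic ref/alt bases are reverse-complemented before substitution.
    Returns (codon_index, ref_codon, alt_codon).
    """
    if strand == "-":
        ref = str(Seq(ref).reverse_complement())
        alt = str(Seq(alt).reverse_complement())
    idx = offset_in_cds // 3
    codon = cds_seq[3 * idx: 3 * idx + 3].upper()
    within = offset_in_cds % 3
    if codon[within] != ref.upper():
        raise ValueError(f"reference base mismatch at CDS offset {offset_in_cds}: "
                         f"codon {codon} vs ref {ref}")
    alt_codon = codon[:within] + alt.upper() + codon[within + 1:]
    return idx, codon, alt_codon


def provean_filter(subs: pd.DataFrame, threshold: float = -2.5) -> pd.DataFrame:
    """Candidate substitutions with externally computed scores below threshold.

    Keeps non-synonymous substitutions (missense or stop) with
    ``provean_score`` < threshold (strict); unscored substitutions are
    excluded and counted.  Scores are consumed, never computed.
    """
    s = subs
    damaging = s["effect"].isin(["missense", "stop_gained", "stop_lost"])
    unscored = s["provean_score"].isna() & damaging
    if int(unscored.sum()):
        log.warning("provean_filter: %d damaging substitutions without a score excluded",
                    int(unscored.sum()))
    keep = damaging & s["provean_score"].notna() & (s["provean_score"] < threshold)
    return s[keep].copy()
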