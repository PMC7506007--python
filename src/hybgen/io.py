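"""Standard-format I/O: TSV tables, a minimal VCF dialect, BED-like
annotations and JSON summaries.

TSV is the canonical interchange format; VCF (v4.2, FORMAT ``GT:DP:GQ``, INFO
keys ``QD`` and ``FS``) and BED are accepted and emitted at the boundaries.
Coordinates: VCF positions are 1-based, BED intervals 0-based half-open;
internal window tables are 0-based half-open.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

GENOTYPE_COLUMNS = ["sample", "chrom", "pos", "ref", "alt", "n_alt", "gt",
                    "dp", "gq", "qd", "fs"]


def read_tsv(path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", **kwargs)
    except pd.errors.ParserError as e:
        raise ValueError(f"malformed TSV {path}: {e}") from e


def write_tsv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_bed(path, columns=("chrom", "start", "end", "strand", "gene", "frame")) -> pd.DataFrame:
    """BED-like annotation (0-based half-open intervals), tab-separated."""
    return pd.read_csv(path, sep="\t", header=None, names=list(columns),
                       comment="#")


def write_genotypes_vcf(records: pd.DataFrame, path,
                        contigs: dict[str, int] | None = None) -> None:
    """Write genotype records as a minimal VCF v4.2.

    One sample per file would be wasteful here; all samples are written as
    VCF sample columns with FORMAT ``GT:DP:GQ``, per-record means of QD/FS in
    INFO (they are record-level annotations in this dialect).
    """
    path = str(path)
    header = pysam.VariantHeader()
    header.add_meta("source", "hybgen")
    if contigs is None:
        contigs = {c: int(records[records["chrom"] == c]["pos"].max()) + 1000
                   for c in records["chrom"].unique()}
    for c, ln in contigs.items():
        header.contigs.add(c, length=ln)
    header.info.add("QD", 1, "Float", "Quality by depth")
    header.info.add("FS", 1, "Float", "Phred-scaled strand bias")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    samples = sorted(records["sample"].unique())
    for s in samples:
        header.add_sample(s)
    vf = pysam.VariantFile(path, "w", header=header)
    for (chrom, pos, ref, alt), site in records.groupby(["chrom", "pos", "ref", "alt"], sort=True):
        rec = vf.new_record(contig=chrom, start=int(pos) - 1, alleles=(ref, alt))
        rec.info["QD"] = float(site["qd"].mean())
        rec.info["FS"] = float(site["fs"].mean())
        by_sample = site.set_index("sample")
        for s in samples:
            if s in by_sample.index:
                row = by_sample.loc[s]
                a, b = (int(x) for x in str(row["gt"]).split("/"))
                rec.samples[s]["GT"] = (a, b)
                rec.samples[s]["DP"] = int(row["dp"])
                rec.samples[s]["GQ"] = int(row["gq"])
            else:
                rec.samples[s]["GT"] = (None, None)
        vf.write(rec)
    vf.close()


def read_genotypes_vcf(path) -> pd.DataFrame:
    """Read a VCF into the genotype-record frame used by the filters."""
    vf = pysam.VariantFile(str(path))
    rows = []
    for rec in vf:
        qd = rec.info.get("QD", np.nan)
        fs = rec.info.get("FS", np.nan)
        alts = rec.alts or ()
        for s, call in rec.samples.items():
            gt = call.get("GT")
            if gt is None or any(a is None for a in gt):
                gt_str = "./."
            else:
                gt_str = "/".join(str(a) for a in sorted(gt))
            rows.append((s, rec.contig, rec.pos, rec.ref,
                         alts[0] if alts else ".", len(alts), gt_str,
                         call.get("DP"), call.get("GQ"), qd, fs))
    vf.close()
    df = pd.DataFrame(rows, columns=GENOTYPE_COLUMNS)
    return df[df["gt"] != "./."].reset_index(drop=True)


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_jsonable)
        fh.write("\n")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serialisable: {type(x)}")


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str)
                          .encode()).hexdigest()[:12]
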