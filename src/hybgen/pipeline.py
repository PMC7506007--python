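"""Configuration-driven orchestration of the full synthetic study.

A run simulates a two-species system end to end and analyses it with every
stage of the toolkit: species panels and a backcross cohort (``simulate``),
diagnostic markers (``markers``), windowed ancestry calls (``ancestry``),
Z-heterozygosity sexing (``sex``), differential expression (``de``),
allele-specific expression (``ase``), cis/trans classification
(``cistrans``), admixture windows (``fd``) and the courtship-initiation model
(``behaviour``).  Each stage writes TSV/JSON outputs plus a manifest
(parameters, seed, config hash) into its own subdirectory; identical config
and seed give byte-identical outputs.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import admixture, ancestry, ase, behaviour, expression, io, simulate, variants

log = logging.getLogger(__name__)

STAGE_DEPS: dict[str, tuple[str, ...]] = {
    "simulate": (),
    "markers": ("simulate",),
    "ancestry": ("markers",),
    "sex": ("simulate",),
    "de": ("simulate",),
    "ase": ("simulate",),
    "cistrans": ("de", "ase"),
    "fd": ("simulate",),
    "behaviour": ("simulate",),
}
STAGE_ORDER = list(STAGE_DEPS)

DEFAULTS: dict[str, dict] = {
    "simulate": {"n_autosomes": 6, "n_bc_genomes": 8, "n_bc": 4,
                 "sites_per_chrom": 3000, "n_genes": 400, "n_per_group": 8,
                 "n_f1_individuals": 10, "ase_depth": 500, "frac_de": 0.1,
                 "n_males": 120, "trials_per_male": 5, "fd_sites": 4000},
    "markers": {},
    "ancestry": {"window_bp": 100_000, "min_informative": 30},
    "sex": {"threshold": 0.01},
    "de": {"fc": 2.0, "fdr": 0.05},
    "ase": {"min_total": 10},
    "cistrans": {"level": 0.05},
    "fd": {"window_bp": 100_000, "step_bp": 20_000, "min_sites": 100},
    "behaviour": {"n_draws": 600, "n_warmup": 400, "chains": 2},
}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    stages: list[str]
    seed: int = 0
    outdir: str = "hybgen_run"
    params: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self):
        seen = set()
        for s in self.stages:
            if s not in STAGE_DEPS:
                raise ValueError(f"unknown stage {s!r}")
            if s in seen:
                raise ValueError(f"duplicate stage {s!r}")
            seen.add(s)
        for s in self.stages:
            for dep in STAGE_DEPS[s]:
                if dep not in seen:
                    raise ValueError(f"stage {s!r} requires upstream stage {dep!r}")
        for s, p in self.params.items():
            if s not in STAGE_DEPS:
                raise ValueError(f"parameters for unknown stage {s!r}")
            unknown = set(p) - set(DEFAULTS[s])
            if unknown:
                raise ValueError(f"unknown keys for stage {s!r}: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {"stages", "seed", "outdir", "params"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def stage_params(self, stage: str) -> dict:
        return {**DEFAULTS[stage], **self.params.get(stage, {})}

    def as_dict(self) -> dict:
        return {"stages": self.stages, "seed": self.seed, "outdir": self.outdir,
                "params": self.params}


def toy_config(outdir: str = "hybgen_run", seed: int = 0) -> RunConfig:
    """The bundled end-to-end toy study at desk scale."""
    return RunConfig(stages=list(STAGE_ORDER), seed=seed, outdir=outdir)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2 ** 31)


def run(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order; returns a report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    chash = io.config_hash(config.as_dict())
    state: dict = {}
    report: dict = {"config_hash": chash, "seed": config.seed, "stages": {}}
    for stage in STAGE_ORDER:
        if stage not in config.stages:
            continue
        params = config.stage_params(stage)
        seed = stage_seed(config.seed, stage)
        sdir = out / stage
        sdir.mkdir(exist_ok=True)
        log.info("running stage %s (seed %d)", stage, seed)
        summary = _STAGES[stage](state, params, seed, sdir)
        io.write_json({"stage": stage, "parameters": params, "seed": seed,
                       "config_hash": chash, "summary": summary},
                      sdir / "manifest.json")
        report["stages"][stage] = summary
    io.write_json(report, out / "run_report.json")
    return report


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def _stage_simulate(state, p, seed, outdir):
    rng = np.random.default_rng(seed)
    gmap = simulate.default_map(n_autosomes=p["n_autosomes"])
    panel = simulate.simulate_species_panels(gmap, sites_per_chrom=p["sites_per_chrom"],
                                             seed=rng)
    cohort = simulate.simulate_pedigree(
        simulate.PedigreeSpec(n_bc=p["n_bc"], selected_chrom=gmap.qtl_chrom),
        gmap, p["n_bc_genomes"], rng)
    genomes = {f"bc_{i:02d}": g for i, g in enumerate(cohort)}
    genomes["f1_control"] = simulate.f1_genome(gmap)
    genomes["cyd_control"] = simulate.pure_genome(gmap, simulate.CYD)
    records = simulate.simulate_genotype_records(
        genomes, panel, simulate.CoverageModel(p_geno_error=0.005), rng)
    io.write_tsv(records, outdir / "genotype_records.tsv")

    n_genes = p["n_genes"]
    de_genes = int(p["frac_de"] * n_genes)
    cis = np.zeros(n_genes)
    trans = np.zeros(n_genes)
    cis[:de_genes // 2] = rng.choice([-1.5, 1.5], de_genes // 2)
    trans[de_genes // 2:de_genes] = rng.choice([-1.5, 1.5], de_genes - de_genes // 2)
    arch = simulate.RegulatoryArchitecture.build(n_genes, cis=cis, trans=trans,
                                                 seed=rng)
    design = simulate.make_design(p["n_per_group"], batches=2, seed=rng)
    counts, design = simulate.simulate_expression(arch, design, rng)
    io.write_tsv(counts.reset_index(names="gene"), outdir / "counts.tsv")
    io.write_tsv(design.reset_index(), outdir / "samples.tsv")
    allele = simulate.simulate_allele_counts(arch, p["n_f1_individuals"],
                                             p["ase_depth"], rng)
    io.write_tsv(allele, outdir / "allele_counts.tsv")
    effects = simulate.BehaviourEffects(chr18=(1.8, 0.8), sigma_male=0.5)
    trials = simulate.simulate_trials(effects, p["n_males"], p["trials_per_male"], rng)
    io.write_tsv(trials, outdir / "trials.tsv")
    freqs = simulate.simulate_frequency_matrix(
        p["fd_sites"], introgressed_span=(500_000, 900_000), seed=rng)
    io.write_tsv(freqs, outdir / "frequencies.tsv")
    z = pd.concat([
        simulate.simulate_z_genotypes("male", seed=rng).assign(sample="pupa_m"),
        simulate.simulate_z_genotypes("female", seed=rng).assign(sample="pupa_f"),
    ])
    io.write_tsv(z, outdir / "z_genotypes.tsv")

    state.update(gmap=gmap, panel=panel, genomes=genomes, records=records,
                 arch=arch, counts=counts, design=design, allele=allele,
                 trials=trials, freqs=freqs, z=z)
    return {"n_genomes": len(cohort), "n_sites": len(panel.sites),
            "n_genes": n_genes, "n_males": p["n_males"]}


def _require(state, key, stage, needed_by):
    if key not in state:
        raise RuntimeError(f"stage {needed_by!r} is missing output of upstream "
                           f"stage {stage!r}; run it first")
    return state[key]


def _stage_markers(state, p, seed, outdir):
    records = _require(state, "records", "simulate", "markers")
    panel = state["panel"]
    truth = panel.diagnostic_sites()
    markers = truth.copy()  # species panels are error-free by construction
    io.write_tsv(markers, outdir / "diagnostic_markers.tsv")
    state["markers"] = markers
    return {"n_markers": len(markers)}


def _stage_ancestry(state, p, seed, outdir):
    records = _require(state, "records", "simulate", "ancestry")
    markers = _require(state, "markers", "markers", "ancestry")
    gmap = state["gmap"]
    lengths = {c.id: c.length_bp for c in gmap.chromosomes}
    filtered = variants.filter_rna_genotypes(records)
    profiles = {}
    for sample, sub in filtered.groupby("sample"):
        profiles[sample] = ancestry.window_share_fractions(
            sub, markers, p["window_bp"], p["min_informative"], lengths)
    per_sample = []
    het = {}
    for sample, prof in profiles.items():
        if sample in ("f1_control", "cyd_control"):
            continue
        calls = ancestry.classify_windows(prof, profiles["f1_control"],
                                          profiles["cyd_control"],
                                          p["min_informative"])
        calls.insert(0, "sample", sample)
        per_sample.append(calls)
        het[sample] = ancestry.genome_het_fraction(calls, exclude_chrom=gmap.qtl_chrom)
    tbl = pd.concat(per_sample, ignore_index=True)
    io.write_tsv(tbl, outdir / "ancestry_windows.tsv")
    io.write_json({"het_fraction_outside_chr18": het,
                   "mean": float(np.mean(list(het.values())))},
                  outdir / "genome_composition.json")
    state["ancestry_windows"] = tbl
    return {"mean_het_fraction": float(np.mean(list(het.values())))}


def _stage_sex(state, p, seed, outdir):
    z = _require(state, "z", "simulate", "sex")
    calls = [ancestry.sex_from_z_heterozygosity(sub, sample, p["threshold"])
             for sample, sub in z.groupby("sample")]
    df = pd.DataFrame([c.__dict__ for c in calls])
    io.write_tsv(df, outdir / "sex_calls.tsv")
    return {"calls": dict(zip(df["sample"], df["call"]))}


def _stage_de(state, p, seed, outdir):
    counts = _require(state, "counts", "simulate", "de")
    design = state["design"]
    mat = expression.ExpressionMatrix(counts, design).normalize()
    res = expression.nb_de_test(mat, ("group", "mel", "cyd"))
    res["called"] = expression.de_called(res, p["fc"], p["fdr"])
    io.write_tsv(res, outdir / "de_results.tsv")
    state["de_results"] = res
    return {"n_called": int(res["called"].sum())}


def _stage_ase(state, p, seed, outdir):
    allele = _require(state, "allele", "simulate", "ase")
    res = ase.ase_test(allele, min_total=p["min_total"])
    bias = ase.assignment_bias_check(allele)
    io.write_tsv(res, outdir / "ase_results.tsv")
    io.write_json(bias, outdir / "assignment_bias.json")
    state["ase_results"] = res
    return {"n_called": int(res["called"].sum()), "bias_median": bias["median"]}


def _stage_cistrans(state, p, seed, outdir):
    de = _require(state, "de_results", "de", "cistrans")
    ar = _require(state, "ase_results", "ase", "cistrans")
    classes = ase.classify_table(de, ar, level=p["level"])
    io.write_tsv(classes, outdir / "cis_trans_classes.tsv")
    return {"class_counts": classes["regulatory_class"].value_counts().to_dict()}


def _stage_fd(state, p, seed, outdir):
    freqs = _require(state, "freqs", "simulate", "fd")
    win = admixture.fd_windows(freqs.drop(columns=["introgressed"], errors="ignore"),
                               p["window_bp"], p["step_bp"], p["min_sites"])
    io.write_tsv(win, outdir / "fd_windows.tsv")
    return {"n_windows": len(win),
            "mean_fd": float(np.nanmean(win["fd"])) if win["fd"].notna().any() else None}


def _stage_behaviour(state, p, seed, outdir):
    trials = _require(state, "trials", "simulate", "behaviour")
    full = behaviour.fit_multinomial(trials, behaviour.QTLS, n_draws=p["n_draws"],
                                     n_warmup=p["n_warmup"], chains=p["chains"],
                                     seed=seed, check_convergence=False)
    rows = []
    for drop in behaviour.QTLS:
        terms = tuple(t for t in behaviour.QTLS if t != drop)
        red = behaviour.fit_multinomial(trials, terms, n_draws=p["n_draws"],
                                        n_warmup=p["n_warmup"], chains=p["chains"],
                                        seed=seed + 1, check_convergence=False)
        cmp_ = behaviour.compare_models(full, red)
        rows.append({"dropped": drop, "delta_elpd": cmp_.delta_elpd,
                     "se": cmp_.se_delta, "se_units": cmp_.se_units,
                     "retained": cmp_.retained})
    tbl = pd.DataFrame(rows)
    io.write_tsv(tbl, outdir / "elpd_comparisons.tsv")
    pred = pd.concat([
        behaviour.predicted_proportions(
            full, {q: g for q in behaviour.QTLS}, seed=seed).assign(genotype=g)
        for g in ("cyd/cyd", "cyd/melp")])
    io.write_tsv(pred, outdir / "predicted_proportions.tsv")
    io.write_json({"rhat_max": full.rhat_max}, outdir / "diagnostics.json")
    return {"retained": dict(zip(tbl["dropped"], tbl["retained"]))}


_STAGES = {
    "simulate": _stage_simulate,
    "markers": _stage_markers,
    "ancestry": _stage_ancestry,
    "sex": _stage_sex,
    "de": _stage_de,
    "ase": _stage_ase,
    "cistrans": _stage_cistrans,
    "fd": _stage_fd,
    "behaviour": _stage_behaviour,
}
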