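"""End-to-end orchestration of the synthetic "paper-shaped" workflow.

Stages: simulate -> ase -> dosage -> single-cell -> modules -> motifs.
Every stage writes TSV/JSON artifacts into the output directory, and a
machine-readable manifest records the package version, parameters, and
SHA-256 checksums of the inputs. The run is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import ase as ase_mod
from . import dosage as dosage_mod
from . import module_trend as mod_mod
from . import motif_enrich as motif_mod
from . import single_cell as sc_mod
from .annotation import write_gene_bed, write_gene_gtf
from .io import (write_allele_counts, write_expression_matrix,
                 write_sample_metadata)
from .simulate import (SimConfig, simulate_allele_counts, simulate_annotation,
                       simulate_bulk_cohort, simulate_module_structure,
                       simulate_promoter_fasta, simulate_single_cell,
                       write_whitelist_vcf)

__all__ = ["default_config", "validate_config", "run_pipeline"]

log = logging.getLogger(__name__)

_SIM_KEYS = {f.name for f in dataclasses.fields(SimConfig)} - {"boundaries", "karyotype_panel"}

_SCHEMA: dict[str, dict] = {
    "seed": {"type": int},
    "simulation": {"type": dict, "keys": _SIM_KEYS},
    "ase": {"type": dict, "keys": {"min_depth", "multiplier_threshold", "min_biallelic"}},
    "dosage": {"type": dict, "keys": {"span", "alpha", "fpkm_cut"}},
    "single_cell": {"type": dict, "keys": {"n_cells_per_sample", "alpha"}},
    "modules": {"type": dict, "keys": {"soft_power", "min_module_size",
                                       "merge_dissimilarity", "anova_alpha"}},
    "motifs": {"type": dict, "keys": {"deficit"}},
}


def default_config(seed: int = 0) -> dict:
    return {
        "seed": seed,
        "simulation": {},
        "ase": {"min_depth": 7, "multiplier_threshold": 2.0, "min_biallelic": 30},
        "dosage": {"span": 0.45, "alpha": 0.05, "fpkm_cut": 0.5},
        "single_cell": {"n_cells_per_sample": 150, "alpha": 0.05},
        "modules": {"soft_power": 20, "min_module_size": 30,
                    "merge_dissimilarity": 0.25, "anova_alpha": 0.05},
        "motifs": {"deficit": 0.15},
    }


def validate_config(config: dict) -> list[str]:
    """Validate a pipeline config, reporting all errors at once."""
    errors: list[str] = []
    if not isinstance(config, dict):
        return ["config must be a mapping"]
    for key in config:
        if key not in _SCHEMA:
            errors.append(f"unknown key {key!r}")
    for key, spec in _SCHEMA.items():
        if key not in config:
            continue
        value = config[key]
        if not isinstance(value, spec["type"]):
            errors.append(f"{key}: expected {spec['type'].__name__}")
            continue
        if spec["type"] is dict:
            for sub in value:
                if sub not in spec["keys"]:
                    errors.append(f"{key}.{sub}: unknown key")
    span = config.get("dosage", {}).get("span")
    if span is not None and not (isinstance(span, (int, float)) and 0 < span <= 1):
        errors.append("dosage.span: span must be in (0,1]")
    deficit = config.get("motifs", {}).get("deficit")
    if deficit is not None and not (isinstance(deficit, (int, float)) and 0 <= deficit <= 1):
        errors.append("motifs.deficit: must be in [0,1]")
    return errors


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    errors = validate_config(raw)
    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    merged = default_config(raw.get("seed", 0))
    for key, value in raw.items():
        if isinstance(value, dict):
            merged[key].update(value)
        else:
            merged[key] = value
    return merged


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict | None = None, outdir: str | Path = "xdosage_out") -> dict:
    """Run the whole synthetic workflow; returns the manifest dict.

    Deterministic given ``config['seed']``: rerunning into a fresh
    directory yields byte-identical data artifacts.
    """
    config = config or default_config()
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    seed = int(config.get("seed", 0))
    stage_times: dict[str, float] = {}
    manifest: dict = {"version": __version__, "seed": seed, "config": config,
                      "stages": [], "checksums": {}}

    def finish_stage(name: str, t_start: float) -> None:
        stage_times[name] = round(time.time() - t_start, 3)
        manifest["stages"].append(name)
        log.info("stage %-12s done in %.1fs", name, stage_times[name])

    # ---- simulate -------------------------------------------------------
    t = time.time()
    sim_kwargs = dict(config.get("simulation", {}))
    sim = SimConfig(seed=seed, **sim_kwargs)
    if not sim.eroded_samples:
        sim = dataclasses.replace(sim, eroded_samples={"47_XXY_r1": 2.5})
    annotation = simulate_annotation(sim)
    matrix, metas, truth = simulate_bulk_cohort(sim, annotation)
    records, ase_truth = simulate_allele_counts(sim, annotation, metas)
    write_gene_gtf(annotation, outdir / "annotation.gtf")
    write_gene_bed(annotation, outdir / "annotation.bed")
    write_expression_matrix(matrix, outdir / "expression_fpkm.tsv")
    write_sample_metadata(metas, outdir / "samples.yaml")
    write_allele_counts(records, outdir / "allele_counts.tsv")
    write_whitelist_vcf(records, outdir / "variants.vcf")
    truth["law"].to_frame().to_csv(outdir / "truth_bulk_laws.tsv", sep="\t")
    ase_truth.to_csv(outdir / "truth_ase.tsv", sep="\t", index=False)
    finish_stage("simulate", t)

    # ---- ase ------------------------------------------------------------
    t = time.time()
    ase_cfg = config.get("ase", {})
    whitelist = ase_mod.filter_variant_whitelist(str(outdir / "variants.vcf"))
    kept, _filtered = ase_mod.filter_sites(records, whitelist,
                                           min_depth=ase_cfg.get("min_depth", 7))
    gene_calls = ase_mod.call_genes(kept, annotation)
    summaries = ase_mod.summarize_ase(gene_calls, annotation)
    flags = ase_mod.flag_erosion(
        summaries,
        multiplier_threshold=ase_cfg.get("multiplier_threshold", 2.0),
        min_biallelic=ase_cfg.get("min_biallelic", 30))
    pd.DataFrame([{"gene_id": c.gene_id, "sample_id": c.sample_id,
                   "n_informative": c.n_informative, "n_biallelic": c.n_biallelic,
                   "status": c.status,
                   "region_class": c.region_class.value if c.region_class else ""}
                  for c in gene_calls]).to_csv(outdir / "ase_gene_calls.tsv",
                                               sep="\t", index=False)
    summary_rows = []
    for sid in sorted(summaries):
        s = summaries[sid]
        xist_status = ase_mod.xist_allelic_check([r for r in kept if r.sample_id == sid])
        summary_rows.append({"sample_id": sid,
                             "biallelic_nonpar_x": s.biallelic_nonpar_x,
                             "biallelic_par1": s.count("PAR1", "biallelic"),
                             "monoallelic_nonpar_x": s.count("X_NONPAR", "monoallelic"),
                             "xist_status": xist_status,
                             "eroded": flags[sid]})
    pd.DataFrame(summary_rows).to_csv(outdir / "ase_summary.tsv", sep="\t", index=False)
    (outdir / "erosion_report.json").write_text(
        json.dumps({"flags": flags}, indent=2, sort_keys=True) + "\n")
    finish_stage("ase", t)

    # ---- dosage ---------------------------------------------------------
    t = time.time()
    d_cfg = config.get("dosage", {})
    expressed = dosage_mod.filter_expressed(matrix, cut=d_cfg.get("fpkm_cut", 0.5))
    ratios = [dosage_mod.x_a_ratio(expressed, annotation, s) for s in expressed.samples]
    pd.DataFrame([{"sample_id": r.sample_id, "mf_x": r.mf_x,
                   "mf_autosome_mean": r.mf_autosome_mean, "x_a_ratio": r.ratio}
                  for r in ratios]).to_csv(outdir / "xa_ratios.tsv", sep="\t", index=False)
    refs = [m.sample_id for m in metas if m.cohort_role == "control_male"]
    track = dosage_mod.male_median_fc(expressed, annotation, refs)
    track.fc.to_csv(outdir / "fold_change_track.tsv", sep="\t")
    curve_frames = []
    for m in metas:
        if m.cohort_role == "control_male":
            continue
        curve = dosage_mod.moving_average_x(track, m.sample_id,
                                            span=d_cfg.get("span", 0.45))
        curve_frames.append(pd.DataFrame({"sample_id": m.sample_id,
                                          "position": curve.positions,
                                          "smoothed_log2_fc": curve.smoothed}))
    pd.concat(curve_frames).to_csv(outdir / "moving_average_curves.tsv",
                                   sep="\t", index=False)
    trends = dosage_mod.classify_dosage_trend(expressed, metas, annotation,
                                              alpha=d_cfg.get("alpha", 0.05))
    pd.DataFrame([dataclasses.asdict(tr) for tr in trends]).to_csv(
        outdir / "dosage_trends.tsv", sep="\t", index=False)
    xxy = [m.sample_id for m in metas if m.karyotype.label == "47,XXY"]
    hga = [m.sample_id for m in metas if m.karyotype.n_x >= 3]
    deg_a = dosage_mod.call_degs(dosage_mod.welch_degs(expressed, xxy, refs))
    deg_b = dosage_mod.call_degs(dosage_mod.welch_degs(expressed, hga, refs))
    shared = dosage_mod.intersect_degs(deg_a, deg_b)
    categories = dosage_mod.categorize_x_degs(
        [c for c in deg_b if c.gene_id in set(shared)], annotation)
    pd.DataFrame([dataclasses.asdict(c) for c in deg_b]).to_csv(
        outdir / "degs_hga_vs_xy.tsv", sep="\t", index=False)
    (outdir / "deg_categories.json").write_text(
        json.dumps({"shared_degs": shared, "x_categories": categories},
                   indent=2, sort_keys=True) + "\n")
    finish_stage("dosage", t)

    # ---- single cell ----------------------------------------------------
    t = time.time()
    sc_cfg = config.get("single_cell", {})
    adata, sc_truth = simulate_single_cell(
        sim, annotation, metas[:1] + [m for m in metas if m.karyotype.n_x >= 2][:6],
        n_cells_per_sample=sc_cfg.get("n_cells_per_sample", 150))
    norm = sc_mod.normalize_cells(adata)
    xist_report = sc_mod.xist_by_karyotype(norm)
    escape_genes = [g for g in adata.var_names
                    if adata.var.loc[g, "law"] in ("escape", "par1")][:30]
    correlations = sc_mod.correlate_with_xist(norm, escape_genes)
    phase = sc_mod.phase_independence(norm, escape_genes + ["XIST"])
    pd.DataFrame([dataclasses.asdict(c) for c in correlations]).to_csv(
        outdir / "xist_correlations.tsv", sep="\t", index=False)
    phase.to_csv(outdir / "phase_independence.tsv", sep="\t")
    (outdir / "sc_report.json").write_text(
        json.dumps({"xist_by_karyotype": xist_report}, indent=2, sort_keys=True) + "\n")
    finish_stage("single_cell", t)

    # ---- modules --------------------------------------------------------
    t = time.time()
    m_cfg = config.get("modules", {})
    mod_matrix, mod_truth, mod_metas = simulate_module_structure(seed=seed)
    net_cfg = mod_mod.NetworkConfig(
        soft_power=m_cfg.get("soft_power", 20),
        min_module_size=m_cfg.get("min_module_size", 30),
        merge_dissimilarity=m_cfg.get("merge_dissimilarity", 0.25),
        anova_alpha=m_cfg.get("anova_alpha", 0.05))
    module_set = mod_mod.build_modules(mod_matrix, net_cfg)
    eigs = mod_mod.compute_eigengenes(mod_matrix, module_set)
    passing = mod_mod.anova_filter(eigs, mod_metas, alpha=net_cfg.anova_alpha)
    supermodules = mod_mod.select_dosage_supermodules(
        module_set, mod_metas, passing,
        merge_dissimilarity=net_cfg.merge_dissimilarity)
    module_set.labels.rename("module").to_frame().to_csv(
        outdir / "module_assignment.tsv", sep="\t")
    eigs.to_csv(outdir / "module_eigengenes.tsv", sep="\t")
    universe = set(mod_matrix.genes)
    term_sets = {f"TRUE_M{mi}": set(mod_truth.index[mod_truth["module"] == mi])
                 for mi in sorted(mod_truth["module"].unique())}
    enrich_rows = []
    for sm, members in supermodules.items():
        query = set().union(*(module_set.genes_in(m) for m in members))
        for res in mod_mod.hypergeom_enrich(query, term_sets, universe):
            enrich_rows.append({"supermodule": sm, **dataclasses.asdict(res)})
    pd.DataFrame(enrich_rows).to_csv(outdir / "module_enrichment.tsv",
                                     sep="\t", index=False)
    (outdir / "supermodule_report.json").write_text(json.dumps(
        {"supermodules": supermodules, "trend": module_set.trend,
         "anova_passing": sorted(passing)}, indent=2, sort_keys=True) + "\n")
    finish_stage("modules", t)

    # ---- motifs ---------------------------------------------------------
    t = time.time()
    deficit = config.get("motifs", {}).get("deficit", 0.15)
    consensus = "TGCGCATGCGCA"
    counts = np.zeros((4, len(consensus)))
    for i, b in enumerate(consensus):
        counts["ACGT".index(b), i] = 20
        counts[:, i] += 1
    pwm = motif_mod.Pwm.from_counts("SYN1:PLANTED", counts)
    gene_ids = matrix.genes[:200]
    query = set(gene_ids[:60])
    background = set(gene_ids[100:200])
    seqs = simulate_promoter_fasta(gene_ids, planted_genes=set(list(query)[:45]),
                                   consensus=consensus, seed=seed,
                                   path=outdir / "promoters.fa")
    bound = {g: len(motif_mod.scan_pwm(s, pwm, deficit)) > 0 for g, s in seqs.items()}
    enr = motif_mod.coverage_fisher(bound, query, background, tf_id=pwm.tf_id)
    (outdir / "motif_enrichment.json").write_text(
        json.dumps(dataclasses.asdict(enr), indent=2, sort_keys=True) + "\n")
    finish_stage("motifs", t)

    # ---- manifest -------------------------------------------------------
    for p in sorted(outdir.iterdir()):
        if p.name not in ("manifest.json", "run.log") and p.is_file():
            manifest["checksums"][p.name] = _sha256(p)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    (outdir / "run.log").write_text(
        "".join(f"{name}\t{secs}s\n" for name, secs in stage_times.items())
        + f"total\t{round(time.time() - t0, 3)}s\n")
    return manifest
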