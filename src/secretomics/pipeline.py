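"""End-to-end orchestration of the secretome-profiling stages.

A single config dict (YAML on disk) drives the run: synthetic designs or
input paths per stage, stage toggles, the selection thresholds (DAve 0.4,
DCI 5, F 4.5, p 0.001, Bonferroni alpha 0.05, BH FDR 0.05, frequency 2,
top 15 — the printed defaults of the analysis), one seed, and an output
directory. Every stage writes its tabular outputs under the output
directory and contributes headline statistics to a versioned summary JSON.
"""

from __future__ import annotations

import json
import logging
from copy import deepcopy
from pathlib import Path

import numpy as np

from . import (assay_summaries, bioenergetics, enrichment, maproma_differential,
               mirna_cargo, psm_matrix, synthetic_data)

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline", "validate_summary",
           "SUMMARY_SCHEMA_VERSION"]

log = logging.getLogger(__name__)

SUMMARY_SCHEMA_VERSION = "1.0"

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "secretomics_out",
    "stages": {"proteomics": True, "mirna": True, "bioenergetics": True,
               "assays": True},
    "thresholds": {"dave": 0.4, "dci": 5.0, "f_ratio": 4.5, "f_p": 0.001,
                   "alpha": 0.05, "fdr": 0.05, "min_freq": 2, "top_n": 15},
    "proteome_design": {},       # overrides for synthetic_data.ProteomeDesign
    "mirna_design": {},          # overrides for synthetic_data.MirnaDesign
    "respiration": {"noise_cv": 0.02, "n_replicates": 4},
    "contrast": {"a": "f-CM-hypo", "b": "p-CM-hypo"},
}

# required summary keys per stage, for schema validation
_SCHEMA = {
    "proteomics": ["n_runs", "n_proteins", "n_selected", "venn_shared_fraction",
                   "n_retained_screen", "top_split", "n_enriched_terms"],
    "mirna": ["n_samples", "mirna_percent_mean", "top_n_coverage_min",
              "top_n_coverage_mean", "n_modulated", "shared_core_size"],
    "bioenergetics": ["po_pm", "po_succ", "glycolytic_yield"],
    "assays": ["max_fold_change", "ev_pooled_mean_nm",
               "particles_per_1e6_cells", "senescence_percent_mean"],
}


def load_config(path: str | Path | None = None, **overrides) -> dict:
    """Default config, optionally updated from a YAML file and overrides."""
    cfg = deepcopy(DEFAULT_CONFIG)
    if path is not None:
        import yaml
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    for key, val in overrides.items():
        if val is None:
            continue
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _stage_proteomics(cfg: dict, outdir: Path, seed: int) -> dict:
    thr = cfg["thresholds"]
    design = synthetic_data.ProteomeDesign(**{"seed": seed,
                                              **cfg["proteome_design"]})
    runs, truth = synthetic_data.generate_psm_runs(design)
    matrix = psm_matrix.build_apsm_matrix(runs)
    psm_matrix.write_matrix_tsv(matrix, outdir / "apsm_matrix.tsv")

    cond_a, cond_b = cfg["contrast"]["a"], cfg["contrast"]["b"]
    records = maproma_differential.pairwise_compare(
        matrix, cond_a, cond_b, dave_thr=thr["dave"], dci_thr=thr["dci"])
    maproma_differential.write_comparison_tsv(records,
                                              outdir / "comparison.tsv")

    sets = psm_matrix.frequency_filter(matrix, min_freq=thr["min_freq"])
    cm_sets = {c: s for c, s in sets.items() if "-CM-" in c} or sets
    venn = psm_matrix.venn_partition(dict(list(cm_sets.items())[:4]))
    psm_matrix.write_venn_json(venn, outdir / "venn.json")

    screen = maproma_differential.f_ratio_screen(matrix, f_thr=thr["f_ratio"],
                                                 p_thr=thr["f_p"])
    retained = screen.index[screen["retained"]]
    n_top = min(len(retained), 500)
    tree = maproma_differential.ward_cluster(
        matrix.apsm.loc[retained] if n_top >= 2 else matrix.apsm)
    (outdir / "condition_dendrogram.nwk").write_text(tree.to_newick() + "\n")
    left, right = tree.top_split()

    universe = set().union(*sets.values())
    query = set(records.index[records["selected"]]) & universe
    annotation = synthetic_data.generate_annotation(
        sorted(universe), planted_term="TERM:planted",
        planted_members=sorted(query)[: max(len(query) // 2, 5)],
        seed=seed + 1)
    enrichment.write_gmt(annotation, outdir / "annotation.gmt")
    enr = enrichment.hypergeom_enrich(query, annotation, universe,
                                      alpha=thr["alpha"]) if query else None
    if enr is not None:
        enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)

    n_truth = len(truth.differential_proteins)
    return {
        "n_runs": len(runs),
        "n_proteins": len(matrix.accessions),
        "n_spiked_truth": n_truth,
        "n_selected": int(records["selected"].sum()),
        "venn_shared_fraction": round(venn["shared_fraction"], 6),
        "n_retained_screen": int(screen["retained"].sum()),
        "top_split": [sorted(left), sorted(right)],
        "n_enriched_terms": int(enr["enriched"].sum()) if enr is not None else 0,
    }


def _stage_mirna(cfg: dict, outdir: Path, seed: int) -> dict:
    thr = cfg["thresholds"]
    design = synthetic_data.MirnaDesign(**{"seed": seed, **cfg["mirna_design"]})
    pools, samples, truth = synthetic_data.generate_mirna_reads(design)
    kept_pools = {}
    discards = {"no_adapter": 0, "short_insert": 0, "short_umi": 0}
    for sample, pool in pools.items():
        kept, d = mirna_cargo.qc_filter(pool)
        kept_pools[sample] = kept
        for k in discards:
            discards[k] += d[k]
    matrix = mirna_cargo.umi_collapse(kept_pools, samples=samples)
    comp = mirna_cargo.rna_composition(matrix)
    comp.to_csv(outdir / "rna_composition.csv", float_format="%.4f")

    mir = matrix.subset_class("miRNA")
    cov = mirna_cargo.top_n_coverage(mir, n=thr["top_n"])
    cov[["coverage"]].to_csv(outdir / "top_coverage.csv", float_format="%.6f")

    stage_groups = samples.groupby("stage")["sample"].apply(list)
    diff = mirna_cargo.differential_enrichment(
        mir, stage_groups["f"], stage_groups["p"], fdr=thr["fdr"], seed=seed)
    diff.to_csv(outdir / "differential_mirna.tsv", sep="\t",
                float_format="%.6g")
    mirna_cargo.plot_volcano(diff, outdir / "volcano.svg", fdr=thr["fdr"])

    core = mirna_cargo.stable_core(mir)
    with open(outdir / "stable_core.json", "w") as fh:
        json.dump({"shared_core": sorted(core["shared_core"])}, fh, indent=1)

    return {
        "n_samples": int(len(pools)),
        "discards": discards,
        "mirna_percent_mean": round(float(comp.loc["miRNA"].mean()), 4),
        "top_n_coverage_min": round(float(cov["coverage"].min()), 6),
        "top_n_coverage_mean": round(float(cov["coverage"].mean()), 6),
        "n_modulated": int(diff["modulated"].sum()),
        "n_modulated_truth": len(truth.modulated_mirnas),
        "shared_core_size": len(core["shared_core"]),
        "planted_core_in_shared": sorted(
            set(truth.stable_mirnas) & core["shared_core"]),
    }


def _stage_bioenergetics(cfg: dict, outdir: Path, seed: int) -> dict:
    out = {}
    for key, preset in (("po_pm", "pm_coupled"), ("po_succ", "succ_coupled")):
        design = synthetic_data.RespirationDesign(
            substrate_preset=preset, seed=seed, **cfg["respiration"])
        exp, truth = synthetic_data.generate_respiration(design)
        res = bioenergetics.analyze_respiration(exp)
        out[key] = round(res["po_mean"], 6)
        out[key + "_truth"] = truth.true_po
        synthetic_data.write_trace_csv(exp.o2_traces[0],
                                       outdir / f"o2_{preset}.csv")
    glyc_data, glyc_truth = synthetic_data.generate_glycolysis(seed=seed)
    glyc = bioenergetics.glycolysis_assays(
        glyc_data["delta_a340_glucose"], glyc_data["delta_a340_lactate"],
        cell_count=glyc_data["cell_count"],
        sample_fraction=glyc_data["sample_fraction"])
    out["glycolytic_yield"] = round(glyc["yield_lactate_per_glucose"], 6)
    out["glucose_consumed_mm_per_1e6"] = round(
        glyc["glucose_consumed_mm_per_1e6"], 6)
    return out


def _stage_assays(cfg: dict, outdir: Path, seed: int) -> dict:
    spots, truth = synthetic_data.generate_spot_tables(
        folds={"IGFBP2": 3.5, "OPN": 3.8}, seed=seed)
    quant = assay_summaries.quantify_spots(spots)
    quant.to_csv(outdir / "spot_intensities.csv", float_format="%.4f")
    folds = {}
    for analyte in spots["analyte"].unique():
        a = spots.query("sample == 'A' and analyte == @analyte")
        b = spots.query("sample == 'B' and analyte == @analyte")
        fc = assay_summaries.fold_change(
            a.groupby("replicate")["intensity"].mean().to_numpy(),
            b.groupby("replicate")["intensity"].mean().to_numpy())
        folds[analyte] = round(fc["ratio"], 4)

    fields, _ = synthetic_data.generate_ev_diameters(seed=seed)
    sizes = assay_summaries.bin_sizes(fields)
    sizes["bin_counts"].to_csv(outdir / "ev_size_bins.csv")

    particles = assay_summaries.nta_normalize(
        raw_concentration_per_ml=2.4e6, dilution_factor=1000.0,
        volume_ml=1.0, cell_count=1e6)
    rng = np.random.default_rng(seed)
    field_counts = [(int(rng.binomial(t, 0.04)), t)
                    for t in rng.integers(80, 160, size=5)]
    senescence = assay_summaries.fields_summary(field_counts)

    return {
        "fold_changes": folds,
        "max_fold_change": max(folds.values()),
        "ev_pooled_mean_nm": round(sizes["pooled_mean"], 4),
        "particles_per_1e6_cells": particles,
        "senescence_percent_mean": round(senescence["mean"], 4),
    }


def validate_summary(summary: dict) -> None:
    """Check the summary JSON against the versioned schema; raises on a
    missing stage key or wrong top-level layout."""
    if summary.get("schema_version") != SUMMARY_SCHEMA_VERSION:
        raise ValueError("missing or wrong schema_version")
    if "seed" not in summary or "stages_run" not in summary:
        raise ValueError("summary must record seed and stages_run")
    for stage in summary["stages_run"]:
        block = summary.get(stage)
        if not isinstance(block, dict):
            raise ValueError(f"stage {stage!r} ran but has no summary block")
        missing = [k for k in _SCHEMA.get(stage, []) if k not in block]
        if missing:
            raise ValueError(f"stage {stage!r} summary missing {missing}")


def run_pipeline(config: dict) -> dict:
    """Run all enabled stages in dependency order and write the report.

    Returns the summary dict; writes ``summary.json`` (machine-readable,
    schema-validated) and ``report.txt`` (human-readable) into the output
    directory. A stage failure propagates after partial outputs are kept.
    """
    cfg = load_config(None, **(config or {}))
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    summary: dict = {"schema_version": SUMMARY_SCHEMA_VERSION, "seed": seed,
                     "thresholds": cfg["thresholds"], "stages_run": []}
    stage_fns = {"proteomics": _stage_proteomics, "mirna": _stage_mirna,
                 "bioenergetics": _stage_bioenergetics, "assays": _stage_assays}
    for i, (stage, fn) in enumerate(stage_fns.items()):
        if not cfg["stages"].get(stage, False):
            log.info("stage %s disabled, skipping", stage)
            continue
        log.info("running stage %s (thresholds=%s)", stage, cfg["thresholds"])
        summary[stage] = fn(cfg, outdir, seed + 1000 * i)
        summary["stages_run"].append(stage)
    validate_summary(summary)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    lines = [f"secretomics pipeline summary (seed={seed})"]
    for stage in summary["stages_run"]:
        lines.append(f"\n[{stage}]")
        for k, v in sorted(summary[stage].items()):
            lines.append(f"  {k}: {v}")
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")
    return summary
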