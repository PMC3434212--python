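"""Pipeline orchestration: simulate -> preprocess -> normalize -> DE ->
threshold grids -> clustering -> heterogeneity -> qPCR.

Each stage is a function reading its inputs from the run directory and
writing tab-separated artifacts back, so any stage can be re-run from the
on-disk outputs of the previous one.  ``run_pipeline`` chains all stages and
writes a manifest (config hash, seed, per-stage row counts, artifact
checksums); two runs with the same config produce identical manifests.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import beadproc, clusterhet, diffexpr, qpcrval, simdata
from .beadproc import ExpressionMatrix
from .diffexpr import CybertConfig
from .io import (RunConfig, read_bead_array, read_tabular, sha256_file,
                 write_bead_array, write_tabular)

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "STAGES", "stage_simulate", "stage_preprocess",
           "stage_normalize", "stage_de", "stage_grid", "stage_cluster",
           "stage_heterogeneity", "stage_qpcr", "load_matrix"]

META_SCHEMA = {"sample_id": str, "subject_id": str, "group": str,
               "timepoint": str, "treated": int, "crp": float}


def _sim_config(config: RunConfig) -> simdata.SimConfig:
    return simdata.SimConfig(rng_seed=config.seed, **config.sim)


def _read_meta(outdir: Path) -> pd.DataFrame:
    return read_tabular(outdir / "samples.tsv", META_SCHEMA)


def load_matrix(outdir: Path, which: str = "raw") -> ExpressionMatrix:
    """Rebuild an :class:`ExpressionMatrix` from run-directory artifacts."""
    outdir = Path(outdir)
    name = {"raw": "expression_raw.tsv",
            "log2-quantile": "expression_log2q.tsv"}[which]
    values = pd.read_csv(outdir / name, sep="\t", index_col="probe_id")
    presence = pd.read_csv(outdir / "presence.tsv", sep="\t",
                           index_col="probe_id").astype(bool)
    meta = _read_meta(outdir).set_index("sample_id")
    return ExpressionMatrix(values=values, sample_meta=meta,
                            presence=presence, scale=which)


def _baseline_groups(meta: pd.DataFrame) -> dict[str, list[str]]:
    m = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    return {
        "control": list(m.index[(m.group == "control") & (m.timepoint == "baseline")]),
        "patient": list(m.index[(m.group == "patient") & (m.timepoint == "baseline")]),
    }


def _paired_samples(meta: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Subject-aligned (baseline, post) sample lists of treated patients."""
    m = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    post = m[(m.timepoint == "post")]
    pre_by_subject = m[(m.timepoint == "baseline")].reset_index().set_index(
        "subject_id")["sample_id"]
    subjects = sorted(post["subject_id"])
    pre = [pre_by_subject[s] for s in subjects]
    post_by_subject = post.reset_index().set_index("subject_id")["sample_id"]
    return pre, [post_by_subject[s] for s in subjects]


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def stage_simulate(config: RunConfig, outdir: Path) -> dict[str, int]:
    sim = _sim_config(config)
    arrays, meta, truth = simdata.generate_cohort(sim)
    beads_dir = outdir / "beads"
    for arr in arrays:
        write_bead_array(arr, beads_dir / f"{arr.sample_id}.tsv")
    write_tabular(meta, outdir / "samples.tsv")

    genes = truth.true_log2_fc.index
    truth_genes = pd.DataFrame({
        "probe_id": genes,
        "expressed": [int(g in truth.expressed_gene_ids) for g in genes],
        "de": [int(g in truth.de_gene_ids) for g in genes],
        "true_log2_fc": truth.true_log2_fc.to_numpy(),
        "treatment_responsive": [int(g in truth.treatment_responsive_ids)
                                 for g in genes],
        "crp_linked": [int(g in truth.crp_linked_gene_ids) for g in genes],
    })
    write_tabular(truth_genes, outdir / "truth_genes.tsv")
    write_tabular(
        pd.DataFrame({"subject_id": sorted(truth.heterogeneous_patient_ids)}),
        outdir / "truth_subjects.tsv")

    study = simdata.generate_qpcr(sim, truth)
    rec = study.records.copy()
    rec["is_housekeeping"] = rec["gene"].isin(
        study.housekeeping_candidates).astype(int)
    write_tabular(rec, outdir / "qpcr_raw.tsv")
    return {"arrays": len(arrays), "samples": len(meta),
            "qpcr_records": len(rec)}


def stage_preprocess(config: RunConfig, outdir: Path) -> dict[str, int]:
    meta = _read_meta(outdir)
    beads_dir = outdir / "beads"
    arrays = [read_bead_array(beads_dir / f"{sid}.tsv", sid)
              for sid in meta["sample_id"]]
    calls = {arr.sample_id: beadproc.process_bead_array(
        arr, config.mad_multiplier, config.detection_alpha,
        config.mad_zero_policy) for arr in arrays}
    call_rows = []
    for sid, c in calls.items():
        c2 = c.reset_index()
        c2.insert(1, "sample_id", sid)
        call_rows.append(c2)
    write_tabular(pd.concat(call_rows, ignore_index=True),
                  outdir / "probe_calls.tsv")
    matrix = beadproc.build_expression_matrix(
        arrays, meta, config.mad_multiplier, config.detection_alpha,
        config.mad_zero_policy, calls=calls)
    write_tabular(matrix.values, outdir / "expression_raw.tsv", index=True)
    write_tabular(matrix.presence.astype(int), outdir / "presence.tsv",
                  index=True)
    return {"probes": matrix.values.shape[0],
            "samples": matrix.values.shape[1]}


def stage_normalize(config: RunConfig, outdir: Path) -> dict[str, int]:
    matrix = load_matrix(outdir, "raw")
    norm = diffexpr.log2_quantile_normalize(matrix)
    write_tabular(norm.values, outdir / "expression_log2q.tsv", index=True)
    return {"probes": norm.values.shape[0]}


def stage_de(config: RunConfig, outdir: Path) -> dict[str, int]:
    matrix = load_matrix(outdir, "log2-quantile")
    meta = matrix.sample_meta
    cfg = CybertConfig(config.window_size, config.confidence)
    groups = _baseline_groups(meta)
    assessed = matrix.assessed_probes(groups, config.presence_table,
                                      config.detection_alpha)
    cfg_eff = cfg if cfg.window_size <= len(assessed) else CybertConfig(
        max(1, (len(assessed) // 2) * 2 + 1), cfg.confidence)
    if cfg_eff is not cfg:
        logger.warning("window_size reduced to %d for %d assessed genes",
                       cfg_eff.window_size, len(assessed))
    de_base = diffexpr.de_table(matrix, groups["patient"], groups["control"],
                                "cybert_unpaired", assessed, cfg_eff)
    write_tabular(de_base.rename_axis("gene_id"), outdir / "de_baseline.tsv",
                  index=True)

    pre, post = _paired_samples(meta)
    rows = {"de_baseline": len(de_base)}
    if pre:
        paired_groups = {"pre": pre, "post": post}
        assessed_p = matrix.assessed_probes(paired_groups,
                                            config.presence_table,
                                            config.detection_alpha)
        de_paired = diffexpr.de_table(matrix, post, pre, "paired_t",
                                      assessed_p, cfg_eff)
        write_tabular(de_paired.rename_axis("gene_id"),
                      outdir / "de_paired.tsv", index=True)
        rows["de_paired"] = len(de_paired)
    return rows


def stage_grid(config: RunConfig, outdir: Path) -> dict[str, int]:
    de_base = pd.read_csv(outdir / "de_baseline.tsv", sep="\t",
                          index_col="gene_id")
    grid = diffexpr.threshold_count_table(de_base)
    write_tabular(grid.rename_axis("cell").reset_index(),
                  outdir / "grid_baseline.tsv")

    matrix = load_matrix(outdir, "log2-quantile")
    cfg = CybertConfig(min(config.window_size,
                           (len(de_base) // 2) * 2 + 1), config.confidence)
    low, high = diffexpr.crp_tertile_contrast(matrix, de_base.index, cfg)
    write_tabular(low.rename_axis("cell").reset_index(),
                  outdir / "grid_crp_low.tsv")
    write_tabular(high.rename_axis("cell").reset_index(),
                  outdir / "grid_crp_high.tsv")
    return {"grid_cells": len(grid)}


def stage_cluster(config: RunConfig, outdir: Path) -> dict[str, int]:
    matrix = load_matrix(outdir, "log2-quantile")
    meta = matrix.sample_meta
    pre, post = _paired_samples(meta)
    if not pre:
        logger.warning("no treated subjects; skipping clustering")
        return {}
    de_paired = pd.read_csv(outdir / "de_paired.tsv", sep="\t",
                            index_col="gene_id")
    subset = de_paired.index[de_paired["p_value"] < 0.05]
    if len(subset) < 2:
        logger.warning("fewer than 2 significantly modulated genes; "
                       "clustering on all assessed genes")
        subset = de_paired.index
    sub = ExpressionMatrix(matrix.values[pre + post],
                           matrix.sample_meta,
                           matrix.presence[pre + post],
                           scale=matrix.scale)
    ratios = clusterhet.build_ratio_matrix(sub, pre, subset)
    result = clusterhet.hierarchical_cluster(ratios)
    subjects = meta.loc[pre, "subject_id"]
    pairs = {subj: (pre[i], post[i]) for i, subj in enumerate(subjects)}
    frac = clusterhet.adjacency_score(result, pairs)

    write_tabular(result.distance_matrix.rename_axis("sample_id"),
                  outdir / "distance.tsv", index=True)
    write_tabular(pd.DataFrame(result.merges,
                               columns=["left", "right", "height"]),
                  outdir / "merges.tsv")
    write_tabular(pd.DataFrame({"leaf_order": result.leaf_order}),
                  outdir / "leaf_order.tsv")
    adj = pd.DataFrame(
        {"subject_id": list(result.adjacency),
         "adjacent": [int(v) for v in result.adjacency.values()]})
    adj["adjacency_fraction"] = frac
    write_tabular(adj, outdir / "adjacency.tsv")
    return {"cluster_genes": len(subset), "cluster_samples": len(pre) * 2}


def stage_heterogeneity(config: RunConfig, outdir: Path) -> dict[str, int]:
    matrix = load_matrix(outdir, "log2-quantile")
    meta = matrix.sample_meta
    groups = _baseline_groups(meta)
    de_base = pd.read_csv(outdir / "de_baseline.tsv", sep="\t",
                          index_col="gene_id")
    if config.heterogeneity_gene_set == "de":
        genes = de_base.index[de_base["p_value"] < 0.05]
    else:
        genes = de_base.index  # the assessed set
    report = clusterhet.per_sample_heterogeneity(
        matrix, groups["control"], groups["patient"], config.flag_k, genes)
    out = report.sample_sds.rename_axis("sample_id").reset_index()
    out["is_control"] = out["sample_id"].isin(groups["control"]).astype(int)
    out["flagged"] = out["sample_id"].isin(report.flagged).astype(int)
    out["threshold"] = report.threshold
    write_tabular(out, outdir / "heterogeneity.tsv")
    return {"heterogeneity_samples": len(out),
            "flagged": len(report.flagged)}


def stage_qpcr(config: RunConfig, outdir: Path) -> dict[str, int]:
    rec = read_tabular(outdir / "qpcr_raw.tsv",
                       {"sample_id": str, "gene": str, "replicate": int,
                        "ct": float, "quality": float,
                        "is_housekeeping": int})
    meta = _read_meta(outdir).set_index("sample_id")
    hk = sorted(rec.loc[rec["is_housekeeping"] == 1, "gene"].unique())
    study = qpcrval.QpcrStudy(
        records=rec.drop(columns=["is_housekeeping"]),
        housekeeping_candidates=hk, groups=meta)
    ranking = qpcrval.select_reference(study, config.quality_threshold)
    stab = pd.DataFrame({"gene": ranking.genorm_m.index,
                         "genorm_m": ranking.genorm_m.to_numpy(),
                         "normfinder": ranking.normfinder_stability.reindex(
                             ranking.genorm_m.index).to_numpy()})
    stab["selected"] = (stab["gene"] == ranking.selected_reference).astype(int)
    write_tabular(stab, outdir / "stability.tsv")

    agg = qpcrval.qc_and_aggregate(study, config.quality_threshold)
    groups = _baseline_groups(meta)
    pre, post = _paired_samples(meta)
    rows = []
    for target in study.target_genes:
        res = qpcrval.ddct(agg, target, ranking.selected_reference,
                           groups["patient"], groups["control"])
        rows.append((target, "patient_vs_control", res.ddct,
                     res.fold_change, res.p_value, int(res.low_confidence)))
        if pre:
            res_t = qpcrval.ddct(agg, target, ranking.selected_reference,
                                 post, pre, paired=True)
            rows.append((target, "post_vs_pre", res_t.ddct, res_t.fold_change,
                         res_t.p_value, int(res_t.low_confidence)))
    ddct_df = pd.DataFrame(rows, columns=["gene", "contrast", "ddct",
                                          "fold_change", "p_value",
                                          "low_confidence"])
    write_tabular(ddct_df, outdir / "ddct.tsv")
    return {"qpcr_targets": len(study.target_genes),
            "ddct_rows": len(ddct_df)}


STAGES = [
    ("simulate", stage_simulate),
    ("preprocess", stage_preprocess),
    ("normalize", stage_normalize),
    ("de", stage_de),
    ("grid", stage_grid),
    ("cluster", stage_cluster),
    ("heterogeneity", stage_heterogeneity),
    ("qpcr", stage_qpcr),
]


def run_pipeline(config: RunConfig, outdir: str | Path | None = None,
                 stages: list[str] | None = None) -> Path:
    """Run the selected stages (default: all) and write a manifest.

    Returns the run directory.  The manifest records the config hash, seed,
    per-stage row counts and a checksum per artifact; it is identical across
    runs with the same config and seed.
    """
    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    wanted = set(stages) if stages is not None else {n for n, _ in STAGES}
    unknown = wanted - {n for n, _ in STAGES}
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    counts: dict[str, dict[str, int]] = {}
    for name, fn in STAGES:
        if name not in wanted:
            continue
        logger.info("stage %s", name)
        counts[name] = fn(config, outdir)
    artifacts = sorted(p for p in outdir.rglob("*.tsv"))
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_counts": counts,
        "artifacts": {str(p.relative_to(outdir)): sha256_file(p)
                      for p in artifacts},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8")
    return outdir
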