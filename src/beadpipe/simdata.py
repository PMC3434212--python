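"""Synthetic bead-level cohorts and qPCR plates with known ground truth.

The generator emulates a two-group monocyte transcriptome study: healthy
controls sampled once at baseline, cardiorenal patients sampled at baseline,
and a treated subset of the patients resampled after short-term treatment.
Defaults mirror the study design constants (12 controls, 18 patients, 12
treated; about half the probes expressed above background; small linear fold
changes in 0.3-1.7; a minority of patients with markedly more variable
baselines; a couple of contamination-driven genes that respond to treatment).

Gene model (log2 scale), per probe g and sample s:

    level(g, s) = mu_g                       baseline probe level
                + fc_g        * [patient]    group shift for DE genes
                + sig_subj(g)                per-subject signature, shared by
                                             both timepoints of a subject
                + tau_g       * [post]       treatment shift (fixed
                                             +log2(1.5) for contamination
                                             genes, random otherwise)
                + crp_g       * [high CRP]   optional CRP-linked shift

Bead intensities are 2**(level + N(0, measurement_sd^2)) with a fraction of
beads hit by a multiplicative gross error (x4 or x1/4); negative-control
probes draw from the background distribution only.  The per-subject signature
and any extra heterogeneity noise apply to expressed genes (background probes
carry no biology).  All randomness derives from one seed sequence split per
sample by counter, so output is bit-reproducible and independent of
generation order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .beadproc import BeadArray
from .qpcrval import QpcrStudy

logger = logging.getLogger(__name__)

__all__ = ["SimConfig", "SimConfigError", "GroundTruth", "generate_cohort",
           "generate_qpcr", "sample_frame"]

#: log2 intensity of the array background (negative-control level).
BACKGROUND_LOG2_MEAN = 7.0
#: per-probe spread of the background level.
BACKGROUND_PROBE_SD = 0.1
#: expressed-gene baseline levels are drawn uniformly from this log2 range.
EXPRESSED_LOG2_RANGE = (8.5, 13.0)
#: deterministic post-treatment shift of contamination genes (log2 units).
CONTAMINATION_SHIFT_LOG2 = math.log2(1.5)
#: per-sample qPCR loading spread in cycles (cancelled by the reference gene).
QPCR_LOADING_SD = 0.3


class SimConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass(frozen=True)
class SimConfig:
    """Study-design and noise parameters of the synthetic cohort.

    The cohort layout defaults are the study constants (12 controls, 18
    patients of whom 12 are treated and resampled); probe-scale defaults are
    desk-scale (2,000 probes) but scale to full-array size.
    """

    n_probes: int = 2000
    n_neg_controls: int = 100
    beads_per_probe: int = 30
    n_controls: int = 12
    n_patients: int = 18
    n_treated: int = 12
    frac_expressed: float = 0.5
    n_de_genes: int = 100
    de_fc_range: tuple[float, float] = (0.3, 1.7)
    patient_effect_sd: float = 1.0
    treatment_effect_sd: float = 0.02
    n_heterogeneous_patients: int = 4
    hetero_extra_sd: float = 1.0
    outlier_bead_rate: float = 0.02
    measurement_sd: float = 0.5
    contamination_gene_ids: tuple[str, ...] | None = None
    rng_seed: int = 0
    # CRP-linked expression (off by default; used for tertile-contrast checks)
    n_crp_linked_genes: int = 0
    crp_linked_log2fc: float = 0.6
    # qPCR plate parameters
    qpcr_n_targets: int = 6
    qpcr_replicate_sd: float = 0.15
    qpcr_biological_sd: float = 0.2
    qpcr_fail_rate: float = 0.05
    qpcr_hk_sds: tuple[float, float, float, float] = (0.05, 0.5, 0.55, 0.6)
    qpcr_hk_group_shifts: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)

    def validate(self) -> None:
        positive = ["n_probes", "n_neg_controls", "beads_per_probe"]
        for name in positive:
            if getattr(self, name) < 1:
                raise SimConfigError(f"{name} must be a positive count")
        nonneg_counts = ["n_controls", "n_patients", "n_treated", "n_de_genes",
                         "n_heterogeneous_patients", "n_crp_linked_genes",
                         "qpcr_n_targets"]
        for name in nonneg_counts:
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be >= 0")
        if self.n_treated > self.n_patients:
            raise SimConfigError("n_treated must not exceed n_patients")
        if self.n_de_genes > self.n_probes:
            raise SimConfigError("n_de_genes must not exceed n_probes")
        if self.n_heterogeneous_patients > self.n_patients:
            raise SimConfigError(
                "n_heterogeneous_patients must not exceed n_patients")
        if not (0.0 < self.frac_expressed <= 1.0):
            raise SimConfigError("frac_expressed must be in (0, 1]")
        if not (0.0 <= self.outlier_bead_rate < 1.0):
            raise SimConfigError("outlier_bead_rate must be in [0, 1)")
        if not (0.0 <= self.qpcr_fail_rate <= 1.0):
            raise SimConfigError("qpcr_fail_rate must be in [0, 1]")
        lo, hi = self.de_fc_range
        if lo <= 0 or hi < lo:
            raise SimConfigError(
                "de_fc_range must be an increasing pair of positive ratios")
        for name in ["patient_effect_sd", "treatment_effect_sd",
                     "hetero_extra_sd", "qpcr_replicate_sd",
                     "qpcr_biological_sd"]:
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be >= 0")
        if self.measurement_sd <= 0:
            raise SimConfigError("measurement_sd must be positive")


@dataclass
class GroundTruth:
    """Truth labels of one simulated cohort, for parameter-recovery tests."""

    de_gene_ids: frozenset[str]
    true_log2_fc: pd.Series  # indexed by gene probe id, 0 for non-DE genes
    heterogeneous_patient_ids: frozenset[str]
    expressed_gene_ids: frozenset[str]
    treatment_responsive_ids: frozenset[str]
    crp_linked_gene_ids: frozenset[str] = frozenset()


# ---------------------------------------------------------------------------
# Deterministic cohort layout
# ---------------------------------------------------------------------------


def _gene_ids(config: SimConfig) -> tuple[list[str], list[str]]:
    width = max(5, len(str(config.n_probes)))
    genes = [f"GENE{i:0{width}d}" for i in range(1, config.n_probes + 1)]
    negs = [f"NEG{i:04d}" for i in range(1, config.n_neg_controls + 1)]
    return genes, negs


def sample_frame(config: SimConfig) -> pd.DataFrame:
    """Sample metadata (without CRP), deterministic given the config.

    Controls are sampled once at baseline; every patient is sampled at
    baseline and the first ``n_treated`` patients are resampled post
    treatment.  Sample ids are ``C01 .. C12``, ``P01_b .. P18_b`` and
    ``P01_p .. P12_p``.
    """
    rows = []
    for i in range(1, config.n_controls + 1):
        sid = f"C{i:02d}"
        rows.append((sid, sid, "control", "baseline", 0))
    for i in range(1, config.n_patients + 1):
        subj = f"P{i:02d}"
        treated = int(i <= config.n_treated)
        rows.append((f"{subj}_b", subj, "patient", "baseline", treated))
    for i in range(1, config.n_treated + 1):
        subj = f"P{i:02d}"
        rows.append((f"{subj}_p", subj, "patient", "post", 1))
    return pd.DataFrame(
        rows, columns=["sample_id", "subject_id", "group", "timepoint", "treated"]
    )


#: spread of DE effect sizes: log2 fold changes are drawn from a normal with
#: this sd truncated to the configured range, so most effects sit near a fold
#: change of 1 and the range endpoints are rare extremes.
DE_LOG2FC_SD = 0.25


def _draw_log2_fold_changes(
    fc_range: tuple[float, float], n: int, rng: np.random.Generator
) -> np.ndarray:
    """Log2 fold changes concentrated near 0 inside the given linear range."""
    lo, hi = math.log2(fc_range[0]), math.log2(fc_range[1])
    if n == 0:
        return np.zeros(0)
    if hi == lo:
        return np.full(n, lo)
    from scipy.stats import truncnorm

    a, b = lo / DE_LOG2FC_SD, hi / DE_LOG2FC_SD
    return truncnorm.rvs(a, b, scale=DE_LOG2FC_SD, size=n, random_state=rng)


def _streams(config: SimConfig) -> list[np.random.SeedSequence]:
    """One child seed per consumer: 0 = gene model, 1 = qPCR, 2+ = samples."""
    n_samples = config.n_controls + config.n_patients + config.n_treated
    return np.random.SeedSequence(config.rng_seed).spawn(2 + n_samples)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def generate_cohort(
    config: SimConfig,
) -> tuple[list[BeadArray], pd.DataFrame, GroundTruth]:
    """Generate one bead-level cohort: arrays, sample metadata, ground truth."""
    config.validate()
    genes, negs = _gene_ids(config)
    streams = _streams(config)
    g = np.random.default_rng(streams[0])

    n_genes = config.n_probes
    all_probes = genes + negs

    # Baseline probe levels: background everywhere, expressed genes drawn high.
    mu = g.normal(BACKGROUND_LOG2_MEAN, BACKGROUND_PROBE_SD, len(all_probes))
    n_expr = max(1, round(config.frac_expressed * n_genes))
    expr_idx = np.sort(g.choice(n_genes, size=n_expr, replace=False))
    mu[expr_idx] = g.uniform(*EXPRESSED_LOG2_RANGE, size=n_expr)
    expressed = [genes[i] for i in expr_idx]

    # DE genes: a subset of expressed genes with linear fold changes in range.
    n_de = min(config.n_de_genes, n_expr)
    if n_de < config.n_de_genes:
        logger.warning("only %d expressed genes; n_de_genes reduced", n_expr)
    de_pos = np.sort(g.choice(n_expr, size=n_de, replace=False))
    de_genes = [expressed[i] for i in de_pos]
    de_log2fc = _draw_log2_fold_changes(config.de_fc_range, n_de, g)
    log2_fc = pd.Series(0.0, index=pd.Index(genes, name="probe_id"))
    log2_fc.loc[de_genes] = de_log2fc

    # Contamination genes: expressed, treatment-responsive with a fixed shift.
    if config.contamination_gene_ids is None:
        candidates = [p for p in expressed if p not in set(de_genes)]
        n_cont = min(2, len(candidates))
        cont_genes = list(
            g.choice(np.array(candidates), size=n_cont, replace=False)
        ) if n_cont else []
    else:
        cont_genes = list(config.contamination_gene_ids)
        unknown = set(cont_genes) - set(expressed)
        if unknown:
            raise SimConfigError(
                f"contamination_gene_ids not expressed genes: {sorted(unknown)}")

    # CRP-linked genes (optional planted signal in the high-CRP patients).
    pool = [p for p in expressed if p not in set(de_genes) | set(cont_genes)]
    n_crp = min(config.n_crp_linked_genes, len(pool))
    crp_genes = list(
        g.choice(np.array(pool), size=n_crp, replace=False)) if n_crp else []

    meta = sample_frame(config)
    patients = [f"P{i:02d}" for i in range(1, config.n_patients + 1)]
    hetero = (
        sorted(g.choice(np.array(patients),
                        size=config.n_heterogeneous_patients, replace=False))
        if config.n_heterogeneous_patients
        else []
    )

    # CRP levels: lognormal, patients skewed high (mg/l).
    crp_control = np.exp(g.normal(math.log(1.0), 0.5, config.n_controls))
    crp_patient = np.exp(g.normal(math.log(4.0), 1.1, config.n_patients))
    crp = {}
    for i, sid in enumerate(meta.loc[meta.group == "control", "sample_id"]):
        crp[sid] = round(float(crp_control[i]), 2)
    for i, subj in enumerate(patients):
        val = round(float(crp_patient[i]), 2)
        crp[f"{subj}_b"] = val
        if i < config.n_treated:
            crp[f"{subj}_p"] = val
    meta["crp"] = meta["sample_id"].map(crp)

    high_crp_subjects: set[str] = set()
    if crp_genes:
        order = np.argsort(crp_patient, kind="stable")
        top = max(1, config.n_patients // 3)
        high_crp_subjects = {patients[i] for i in order[-top:]}

    # Per-subject signatures on expressed genes, identical at both timepoints.
    subjects = list(meta["subject_id"].unique())
    signatures = {
        subj: g.normal(0.0, config.patient_effect_sd, n_expr) for subj in subjects
    }
    for subj in hetero:
        signatures[subj] = signatures[subj] + g.normal(
            0.0, config.hetero_extra_sd, n_expr)

    # Treatment shift per expressed gene, shared across treated subjects.
    tau = g.normal(0.0, config.treatment_effect_sd, n_expr)
    expr_pos = {p: i for i, p in enumerate(expressed)}
    for p in cont_genes:
        tau[expr_pos[p]] = CONTAMINATION_SHIFT_LOG2

    de_expr_pos = np.array([expr_pos[p] for p in de_genes], dtype=int)
    crp_expr_pos = np.array([expr_pos[p] for p in crp_genes], dtype=int)
    expr_global = expr_idx  # positions of expressed genes among all probes

    arrays: list[BeadArray] = []
    neg_set = frozenset(negs)
    for row_idx, row in enumerate(meta.itertuples(index=False)):
        rng = np.random.default_rng(streams[2 + row_idx])
        level = mu.copy()
        adjust = signatures[row.subject_id].copy()
        if row.group == "patient":
            adjust[de_expr_pos] += de_log2fc
            if row.subject_id in high_crp_subjects:
                adjust[crp_expr_pos] += config.crp_linked_log2fc
        if row.timepoint == "post":
            adjust += tau
        level[expr_global] += adjust

        beads = 2.0 ** (
            level[:, None]
            + rng.normal(0.0, config.measurement_sd,
                         (len(all_probes), config.beads_per_probe))
        )
        if config.outlier_bead_rate > 0:
            hit = rng.random(beads.shape) < config.outlier_bead_rate
            factor = np.where(rng.random(beads.shape) < 0.5, 4.0, 0.25)
            beads = np.where(hit, beads * factor, beads)
        arrays.append(
            BeadArray(
                sample_id=row.sample_id,
                beads={p: beads[i] for i, p in enumerate(all_probes)},
                negative_control_ids=neg_set,
            )
        )

    truth = GroundTruth(
        de_gene_ids=frozenset(de_genes),
        true_log2_fc=log2_fc,
        heterogeneous_patient_ids=frozenset(hetero),
        expressed_gene_ids=frozenset(expressed),
        treatment_responsive_ids=frozenset(cont_genes),
        crp_linked_gene_ids=frozenset(crp_genes),
    )
    return arrays, meta, truth


# ---------------------------------------------------------------------------
# qPCR plate generation
# ---------------------------------------------------------------------------

HOUSEKEEPING_CANDIDATES = ("GAPDH", "RPL13A", "ACTB", "RRN18S")


def generate_qpcr(config: SimConfig, truth: GroundTruth) -> QpcrStudy:
    """Triplicate Cts for validation targets plus 4 housekeeping candidates.

    Targets are the strongest planted DE genes (largest absolute log2 fold
    change, the genes an array study would pick for validation).  The Ct of a
    gene is its baseline Ct minus the sample's log2 relative expression, plus
    a per-sample loading term shared by all genes of the sample (cancelled by
    delta-Ct normalization) and replicate noise.  Housekeeping candidates
    differ in designed stability; the first (lowest noise, no group shift) is
    the designed most-stable reference.  Quality scores put a configurable
    fraction of replicates below the 0.65 QC threshold.
    """
    config.validate()
    rng = np.random.default_rng(_streams(config)[1])
    meta = sample_frame(config)

    de_sorted = sorted(
        truth.de_gene_ids,
        key=lambda p: (-abs(truth.true_log2_fc[p]), p),
    )
    targets = de_sorted[: config.qpcr_n_targets]
    hk = list(HOUSEKEEPING_CANDIDATES)
    all_genes = targets + hk

    n_s = len(meta)
    base_ct = {p: c for p, c in zip(all_genes,
                                    rng.uniform(18.0, 28.0, len(all_genes)))}
    loading = rng.normal(0.0, QPCR_LOADING_SD, n_s)

    is_patient = (meta["group"] == "patient").to_numpy()

    # log2 relative expression per sample per gene
    expr: dict[str, np.ndarray] = {}
    for p in targets:
        expr[p] = truth.true_log2_fc[p] * is_patient + rng.normal(
            0.0, config.qpcr_biological_sd, n_s)
    for j, h in enumerate(hk):
        expr[h] = rng.normal(0.0, config.qpcr_hk_sds[j], n_s)
        expr[h] = expr[h] + config.qpcr_hk_group_shifts[j] * is_patient

    records = []
    for si in range(n_s):
        sid = meta.at[si, "sample_id"]
        for p in all_genes:
            cts = (
                base_ct[p]
                + loading[si]
                - expr[p][si]
                + rng.normal(0.0, config.qpcr_replicate_sd, 3)
            )
            fail = rng.random(3) < config.qpcr_fail_rate
            qual = np.where(fail, rng.uniform(0.0, 0.65, 3),
                            rng.uniform(0.65, 1.0, 3))
            for r in range(3):
                records.append((sid, p, r + 1, float(cts[r]), float(qual[r])))

    rec = pd.DataFrame(
        records, columns=["sample_id", "gene", "replicate", "ct", "quality"]
    )
    return QpcrStudy(
        records=rec,
        housekeeping_candidates=hk,
        groups=meta.set_index("sample_id"),
        designed_reference=hk[0],
    )
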