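"""qPCR validation arm: replicate QC, reference-gene stability, delta-delta-Ct.

Workflow: triplicate Cts per (sample, gene) are filtered by an amplification
quality threshold (default 0.65) and averaged; candidate housekeeping genes
are ranked by geNorm's M value and by a NormFinder-style model-based
stability; relative quantification then uses the classic 2**(-ddCt) model
with the selected reference gene, and group differences are tested on the
delta-Ct scale (Student's t, or a paired t for matched timepoints).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "QpcrStudy",
    "StabilityRanking",
    "DdctResult",
    "qc_and_aggregate",
    "relative_quantities",
    "genorm_m",
    "normfinder_stability",
    "select_reference",
    "ddct",
    "QUALITY_THRESHOLD",
]

QUALITY_THRESHOLD = 0.65


@dataclass
class QpcrStudy:
    """Replicate-level qPCR measurements with QC scores and sample labels.

    ``records`` columns: sample_id, gene, replicate, ct (cycles, > 0),
    quality (score in [0, 1]).  ``groups`` is a sample-indexed metadata frame
    carrying at least a ``group`` column (and ``timepoint``/``subject_id``
    for paired designs).  ``designed_reference`` names the housekeeping
    candidate a simulation designed to be most stable (None for real data).
    """

    records: pd.DataFrame
    housekeeping_candidates: list[str]
    groups: pd.DataFrame
    designed_reference: str | None = None

    def __post_init__(self) -> None:
        required = {"sample_id", "gene", "replicate", "ct", "quality"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"qPCR records missing columns: {sorted(missing)}")
        if (self.records["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")

    @property
    def target_genes(self) -> list[str]:
        hk = set(self.housekeeping_candidates)
        return [g for g in self.records["gene"].unique() if g not in hk]


@dataclass
class StabilityRanking:
    """Housekeeping-candidate stability under both criteria (lower = stabler)."""

    genorm_m: pd.Series
    normfinder_stability: pd.Series
    selected_reference: str


@dataclass
class DdctResult:
    """Relative quantification of one target gene against a reference group."""

    target: str
    reference_gene: str
    delta_ct: pd.Series  # per included sample, cycles
    ddct: float
    fold_change: float
    p_value: float
    test: str
    low_confidence: bool = False


# ---------------------------------------------------------------------------
# Replicate QC and aggregation
# ---------------------------------------------------------------------------


def qc_and_aggregate(
    study: QpcrStudy, quality_threshold: float = QUALITY_THRESHOLD
) -> pd.DataFrame:
    """Mean Ct per (sample, gene) over replicates passing the QC threshold.

    Replicates with ``quality < quality_threshold`` are dropped; a
    (sample, gene) cell with no surviving replicate is NaN (missing) and is
    excluded downstream.  Returns a samples x genes frame.
    """
    rec = study.records
    passing = rec[rec["quality"] >= quality_threshold]
    n_dropped = len(rec) - len(passing)
    if n_dropped:
        logger.info("QC dropped %d of %d replicates", n_dropped, len(rec))
    agg = passing.pivot_table(
        index="sample_id", columns="gene", values="ct", aggfunc="mean"
    )
    # keep cells measured but fully failed as explicit NaN rows/cols
    all_samples = rec["sample_id"].unique()
    all_genes = rec["gene"].unique()
    agg = agg.reindex(index=all_samples, columns=all_genes)
    n_missing = int(agg.isna().sum().sum())
    if n_missing:
        logger.warning("%d (sample, gene) cells unmeasurable after QC", n_missing)
    return agg


# ---------------------------------------------------------------------------
# Reference-gene stability
# ---------------------------------------------------------------------------


def relative_quantities(agg_ct: pd.DataFrame) -> pd.DataFrame:
    """Ct values to relative quantities: 2**-(ct - min ct per gene).

    The per-gene minimum Ct (most abundant sample) becomes quantity 1; this is
    the standard input transform for geNorm.
    """
    return 2.0 ** (-(agg_ct - agg_ct.min(axis=0)))


def genorm_m(quantities: pd.DataFrame, min_shared: int = 3) -> pd.Series:
    """geNorm expression-stability M per candidate (lower = more stable).

    ``quantities`` is samples x candidates, positive relative quantities.
    M_j is the mean over the other candidates k of the standard deviation
    across samples of log2(q_j / q_k).  Missing values are handled pairwise-
    complete; a candidate sharing fewer than ``min_shared`` samples with some
    partner is excluded (NaN, logged).
    """
    cols = list(quantities.columns)
    if len(cols) < 2:
        raise ValueError("geNorm needs at least 2 candidates")
    logq = np.log2(quantities)
    sparse = {j for j in cols if logq[j].notna().sum() < min_shared}
    for j in sorted(sparse):
        logger.warning("geNorm: candidate %s has fewer than %d measured "
                       "samples; excluded", j, min_shared)
    m = {}
    for j in cols:
        if j in sparse:
            m[j] = np.nan
            continue
        sds = []
        for k in cols:
            if k == j or k in sparse:
                continue
            ratio = (logq[j] - logq[k]).dropna()
            if len(ratio) < min_shared:
                logger.warning("geNorm: candidates %s/%s share only %d "
                               "samples; pair skipped", j, k, len(ratio))
                continue
            sds.append(ratio.std(ddof=1))
        m[j] = float(np.mean(sds)) if sds else np.nan
    return pd.Series(m, name="genorm_m")


def normfinder_stability(
    log_quantities: pd.DataFrame, groups: Sequence[str] | pd.Series
) -> pd.Series:
    """Model-based stability per candidate (lower = more stable).

    ``log_quantities`` is samples x candidates on a log scale (e.g. -Ct or
    log2 quantities).  Each sample is first centered on its candidate mean,
    removing sample-specific loading.  The centered values of candidate i are
    decomposed into a group effect and within-group variation; the intergroup
    difference d_i is shrunk toward 0 by its sampling variance v_i against
    the across-candidate spread of true differences (empirical Bayes):

        d_shrunk_i = d_i * gamma2 / (gamma2 + v_i),
        gamma2 = max(0, var_i(d_i) - mean_i(v_i)),

    and the stability combines the shrunken bias with the intragroup
    variance:  sqrt((d_shrunk/2)**2 + intra / mean group size).  Without the
    shrinkage a noisy candidate whose group-difference estimate happens to
    cancel the common offset would spuriously beat a genuinely stable one.
    With a single group only the variance term is used (logged).
    """
    x = log_quantities
    if x.shape[1] < 3:
        raise ValueError("NormFinder needs at least 3 candidates")
    groups = pd.Series(np.asarray(groups), index=x.index)
    labels = list(groups.unique())
    if len(labels) < 2:
        logger.warning("NormFinder: single group; intragroup-only variant")
    else:
        sizes = groups.value_counts()
        if (sizes < 2).any():
            raise ValueError("NormFinder needs >= 2 samples per group")

    centered = x.sub(x.mean(axis=1), axis=0)
    cands = list(x.columns)
    mean_n = float(np.mean([np.sum(groups == lab) for lab in labels]))

    intra = {}
    if len(labels) >= 2:
        a, b = labels[0], labels[1]
        if len(labels) > 2:
            logger.warning(
                "NormFinder: %d groups; using the first two (%s, %s)",
                len(labels), a, b)
        d = {}
        v = {}
        for cand in cands:
            va = centered.loc[groups == a, cand].dropna()
            vb = centered.loc[groups == b, cand].dropna()
            d[cand] = float(va.mean() - vb.mean())
            s2a = va.var(ddof=1) if len(va) > 1 else 0.0
            s2b = vb.var(ddof=1) if len(vb) > 1 else 0.0
            v[cand] = float(s2a / len(va) + s2b / len(vb))
            intra[cand] = float(
                (s2a * (len(va) - 1) + s2b * (len(vb) - 1))
                / max(len(va) + len(vb) - 2, 1))
        d_arr = np.array([d[c] for c in cands])
        v_arr = np.array([v[c] for c in cands])
        gamma2 = max(0.0, float(np.var(d_arr, ddof=1)) - float(v_arr.mean()))
        out = {}
        for i, cand in enumerate(cands):
            shrunk = d_arr[i] * gamma2 / (gamma2 + v_arr[i]) if (
                gamma2 + v_arr[i]) > 0 else 0.0
            out[cand] = float(np.sqrt((shrunk / 2.0) ** 2
                                      + intra[cand] / mean_n))
    else:
        out = {}
        for cand in cands:
            vals = centered[cand].dropna()
            s2 = vals.var(ddof=1) if len(vals) > 1 else 0.0
            out[cand] = float(np.sqrt(s2 / mean_n))
    return pd.Series(out, name="normfinder_stability")


def select_reference(
    study: QpcrStudy,
    quality_threshold: float = QUALITY_THRESHOLD,
    baseline_only: bool = True,
) -> StabilityRanking:
    """Rank housekeeping candidates by both criteria and pick the reference.

    The geNorm winner is selected; if NormFinder disagrees a warning is
    logged (agreement of the two criteria is the expected, well-behaved case).
    By default stability is assessed on baseline samples (the two-group
    control/patient design); set ``baseline_only=False`` to use all samples.
    """
    agg = qc_and_aggregate(study, quality_threshold)
    samples = agg.index
    if baseline_only and "timepoint" in study.groups.columns:
        keep = study.groups.loc[samples, "timepoint"] == "baseline"
        samples = samples[np.asarray(keep)]
    hk = study.housekeeping_candidates
    sub = agg.loc[samples, hk]
    q = relative_quantities(sub)
    m = genorm_m(q)
    nf = normfinder_stability(np.log2(q), study.groups.loc[samples, "group"])
    genorm_winner = m.idxmin()
    nf_winner = nf.idxmin()
    if genorm_winner != nf_winner:
        logger.warning(
            "reference-gene criteria disagree (geNorm: %s, NormFinder: %s); "
            "selecting the geNorm winner", genorm_winner, nf_winner)
    return StabilityRanking(
        genorm_m=m, normfinder_stability=nf, selected_reference=genorm_winner
    )


# ---------------------------------------------------------------------------
# Relative quantification
# ---------------------------------------------------------------------------


def ddct(
    agg_ct: pd.DataFrame,
    target: str,
    reference_gene: str,
    group_a: Sequence[str],
    group_b_reference: Sequence[str],
    paired: bool = False,
) -> DdctResult:
    """2**-ddCt relative quantification of ``target`` in A vs reference group B.

    delta-Ct(s) = Ct_target(s) - Ct_reference(s); ddCt is the difference of
    group mean delta-Cts (A minus B); fold change is 2**-ddCt.  The p-value
    comes from a two-sided Student t-test on the delta-Ct values (paired when
    ``paired=True``, in which case A and B must be aligned subject-wise).
    Samples with a missing target Ct are dropped; if more than half of a
    group is missing the result is flagged low-confidence.  A missing
    reference-gene Ct in any included sample is an error.
    """
    group_a = list(group_a)
    group_b = list(group_b_reference)
    for sid in group_a + group_b:
        if sid not in agg_ct.index:
            raise ValueError(f"sample {sid!r} not in aggregated Ct table")
        if pd.isna(agg_ct.at[sid, reference_gene]):
            raise ValueError(
                f"reference gene {reference_gene!r} unmeasured in sample {sid!r}")

    dct_all = agg_ct[target] - agg_ct[reference_gene]
    a = dct_all.loc[group_a]
    b = dct_all.loc[group_b]
    if paired:
        ok = (~a.isna().to_numpy()) & (~b.isna().to_numpy())
        a, b = a[ok], b[ok]
    else:
        a, b = a.dropna(), b.dropna()
    low_conf = len(a) < (len(group_a) + 1) // 2 or len(b) < (len(group_b) + 1) // 2
    if low_conf:
        logger.warning(
            "target %s missing in more than half of a group; low confidence",
            target)
    if len(a) == 0 or len(b) == 0:
        return DdctResult(target, reference_gene, dct_all.loc[group_a + group_b],
                          np.nan, np.nan, np.nan,
                          "paired_t" if paired else "student_t", True)

    ddct_val = float(a.mean() - b.mean())
    fold = float(2.0 ** (-ddct_val))
    if paired:
        diffs = a.to_numpy() - b.to_numpy()
        if np.allclose(diffs.var(), 0.0):
            p = 1.0 if np.isclose(diffs.mean(), 0.0) else 0.0
            logger.info("degenerate paired ddCt test for %s", target)
        else:
            p = float(stats.ttest_rel(a.to_numpy(), b.to_numpy()).pvalue)
        test = "paired_t"
    else:
        if a.var(ddof=0) == 0.0 and b.var(ddof=0) == 0.0:
            p = 1.0 if np.isclose(ddct_val, 0.0) else 0.0
        else:
            p = float(stats.ttest_ind(a.to_numpy(), b.to_numpy(),
                                      equal_var=True).pvalue)
        test = "student_t"
    return DdctResult(
        target=target,
        reference_gene=reference_gene,
        delta_ct=pd.concat([a, b]),
        ddct=ddct_val,
        fold_change=fold,
        p_value=p,
        test=test,
        low_confidence=low_conf,
    )
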