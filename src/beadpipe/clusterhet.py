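"""Ratio-based hierarchical clustering and per-sample heterogeneity scoring.

For the pre/post treatment analysis, each gene's signal in each sample is
expressed relative to the average baseline signal of that gene (linear
scale).  Samples are then clustered by average linkage (UPGMA) on Euclidean
distances between their ratio vectors, with a deterministic leaf ordering
(at every merge the subtree containing the lexicographically smallest sample
id goes left).  A subject whose baseline and post-treatment samples sit next
to each other in the leaf order "self-clusters"; the adjacency fraction over
subjects summarizes how strongly individual signatures dominate treatment
effects.

Per-sample heterogeneity compares the spread of a sample's log2 ratios
(relative to the mean of the control samples; leave-self-out for controls)
against the distribution of control-sample spreads: a patient is flagged when
its SD exceeds the control mean by more than ``flag_k`` control SDs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

from .beadproc import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "RatioMatrix",
    "ClusterResult",
    "HeterogeneityReport",
    "build_ratio_matrix",
    "hierarchical_cluster",
    "adjacency_score",
    "per_sample_heterogeneity",
    "flag_threshold",
]


@dataclass
class RatioMatrix:
    """Genes x samples relative expression ratios against a baseline mean."""

    ratios: pd.DataFrame
    baseline_reference: pd.Series

    def __post_init__(self) -> None:
        if (self.baseline_reference <= 0).any():
            raise ValueError("baseline reference must be positive")


@dataclass
class ClusterResult:
    """UPGMA clustering of samples with a deterministic leaf order."""

    distance_matrix: pd.DataFrame
    merges: list[tuple[int, int, float]]
    leaf_order: list[str]
    adjacency: dict[str, bool] | None = None
    adjacency_fraction: float | None = None


@dataclass
class HeterogeneityReport:
    """Per-sample log2-ratio SDs and the patients flagged as heterogeneous."""

    sample_sds: pd.Series
    control_sd_mean: float
    control_sd_sd: float
    threshold: float
    flagged: frozenset[str]


def build_ratio_matrix(
    matrix: ExpressionMatrix,
    baseline_samples: Sequence[str],
    gene_subset: Sequence[str] | pd.Index | None = None,
) -> RatioMatrix:
    """Relative expression of every sample against the baseline mean signal.

    The per-gene reference is the arithmetic mean over ``baseline_samples`` of
    the linear-scale signal (log2-scale matrices are linearized as 2**value).
    Ratios are computed for all samples, baseline included.
    """
    baseline_samples = list(baseline_samples)
    if not baseline_samples:
        raise ValueError("baseline_samples must be non-empty")
    values = matrix.values
    if matrix.scale.startswith("log2"):
        values = 2.0 ** values
    if gene_subset is not None:
        gene_subset = list(gene_subset)
        missing = set(gene_subset) - set(values.index)
        if missing:
            raise ValueError(f"genes not in matrix: {sorted(missing)[:5]}")
        values = values.loc[gene_subset]
    reference = values[baseline_samples].mean(axis=1)
    if (reference <= 0).any():
        raise ValueError("zero baseline reference signal")
    return RatioMatrix(ratios=values.div(reference, axis=0),
                       baseline_reference=reference)


def hierarchical_cluster(ratios: RatioMatrix) -> ClusterResult:
    """Average-linkage (UPGMA) clustering on Euclidean sample distances.

    Leaf ordering is deterministic: at each merge, the subtree whose minimum
    sample id (lexicographic) is smaller goes left, so the result does not
    depend on input column order.
    """
    samples = list(ratios.ratios.columns)
    if len(samples) < 2:
        raise ValueError("need >= 2 samples to cluster")
    x = ratios.ratios.to_numpy().T
    dist = pdist(x, metric="euclidean")
    z = linkage(dist, method="average")
    dmat = pd.DataFrame(squareform(dist), index=samples, columns=samples)

    n = len(samples)
    min_id: dict[int, str] = {i: samples[i] for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    merges: list[tuple[int, int, float]] = []
    for k, (left, right, height, _) in enumerate(z):
        left, right = int(left), int(right)
        node = n + k
        children[node] = (left, right)
        min_id[node] = min(min_id[left], min_id[right])
        merges.append((left, right, float(height)))

    def _leaves(node: int) -> list[int]:
        stack, out = [node], []
        while stack:
            cur = stack.pop()
            if cur < n:
                out.append(cur)
                continue
            a, b = children[cur]
            first, second = (a, b) if min_id[a] <= min_id[b] else (b, a)
            # stack is LIFO: push the right subtree first
            stack.append(second)
            stack.append(first)
        return out

    leaf_order = [samples[i] for i in _leaves(n + len(z) - 1)] if len(z) else samples
    return ClusterResult(distance_matrix=dmat, merges=merges, leaf_order=leaf_order)


def adjacency_score(
    result: ClusterResult, pairs: Mapping[str, tuple[str, str]]
) -> float:
    """Fraction of subjects whose two samples are adjacent leaves.

    ``pairs`` maps subject id to its (baseline, post) sample ids; both must
    appear in the leaf order.  The per-subject booleans and the fraction are
    also stored on ``result``.
    """
    position = {sid: i for i, sid in enumerate(result.leaf_order)}
    adjacency: dict[str, bool] = {}
    for subject, (pre, post) in pairs.items():
        if pre not in position or post not in position:
            raise ValueError(f"samples of subject {subject!r} not in leaf order")
        adjacency[subject] = abs(position[pre] - position[post]) == 1
    fraction = sum(adjacency.values()) / len(adjacency) if adjacency else 0.0
    result.adjacency = adjacency
    result.adjacency_fraction = fraction
    return fraction


def flag_threshold(control_sds: Sequence[float], flag_k: float = 2.0) -> float:
    """Heterogeneity cutoff: mean + flag_k * sd of the control-sample SDs."""
    sds = np.asarray(control_sds, dtype=float)
    if sds.size < 3:
        raise ValueError("need >= 3 control SDs")
    return float(sds.mean() + flag_k * sds.std(ddof=1))


def per_sample_heterogeneity(
    matrix: ExpressionMatrix,
    controls: Sequence[str],
    patients: Sequence[str],
    flag_k: float = 2.0,
    genes: Sequence[str] | pd.Index | None = None,
) -> HeterogeneityReport:
    """Per-sample log2-ratio SDs against the control mean, with flagging.

    The per-gene reference is the mean log2 value over the controls
    (leave-self-out when scoring a control sample, to avoid self-bias).  Each
    sample's score is the SD of its log2 ratios over the gene set; a patient
    is flagged when its SD exceeds ``flag_threshold`` of the control SDs.
    """
    controls = list(controls)
    patients = list(patients)
    if len(controls) < 3:
        raise ValueError("need >= 3 control samples")
    if not matrix.scale.startswith("log2"):
        raise ValueError("heterogeneity scoring expects a log2-scale matrix")
    values = matrix.values if genes is None else matrix.values.loc[list(genes)]

    ctrl = values[controls]
    ctrl_sum = ctrl.sum(axis=1)
    n_ctrl = len(controls)
    sds: dict[str, float] = {}
    for sid in controls:
        loo_ref = (ctrl_sum - ctrl[sid]) / (n_ctrl - 1)
        sds[sid] = float((ctrl[sid] - loo_ref).std(ddof=1))
    full_ref = ctrl_sum / n_ctrl
    for sid in patients:
        sds[sid] = float((values[sid] - full_ref).std(ddof=1))

    sample_sds = pd.Series(sds, name="sd_log2_ratio")
    ctrl_sds = sample_sds.loc[controls]
    threshold = flag_threshold(ctrl_sds.to_numpy(), flag_k)
    flagged = frozenset(sid for sid in patients if sample_sds[sid] > threshold)
    if flagged:
        logger.info("flagged %d heterogeneous patients: %s",
                    len(flagged), sorted(flagged))
    return HeterogeneityReport(
        sample_sds=sample_sds,
        control_sd_mean=float(ctrl_sds.mean()),
        control_sd_sd=float(ctrl_sds.std(ddof=1)),
        threshold=threshold,
        flagged=flagged,
    )
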