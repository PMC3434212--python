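"""Bead-level preprocessing for Illumina-style bead arrays.

A BeadChip measures each probe with many beads per array.  This module
implements the preprocessing chain that turns raw per-bead intensities into a
probes x samples expression matrix:

1. per-probe bead outlier removal (median +/- k * unscaled MAD),
2. probe summarization (arithmetic mean of retained beads),
3. a per-array detection call: the probe's log2 summarized intensity is
   tested one-sided against the distribution of the array's negative-control
   probe summaries (a bead-level Welch variant, :func:`detection_call`, is
   also provided for direct two-sample use),
4. a group-level "transcriptionally active" call (a probe is active in a
   group of n samples when present in at least k(n) of them), and
5. assembly into an :class:`ExpressionMatrix` with presence masks.

The presence thresholds k(12) = 8 and k(18) = 13 are hard-coded lookup values;
for other group sizes the smallest count whose one-sided Z-test against a null
proportion of 0.5 reaches p < 0.05 is used (see :func:`presence_threshold`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "BeadArray",
    "ProbeCall",
    "ExpressionMatrix",
    "remove_bead_outliers",
    "summarize_probe",
    "detection_call",
    "detection_call_summary",
    "presence_threshold",
    "group_presence",
    "process_bead_array",
    "build_expression_matrix",
    "PRESENCE_TABLE",
]

#: Printed presence thresholds: at least 8 of 12, at least 13 of 18.
PRESENCE_TABLE: dict[int, int] = {12: 8, 18: 13}

DETECTION_ALPHA = 0.05
MAD_MULTIPLIER = 2.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class BeadArray:
    """One sample's raw bead-level intensities grouped by probe.

    Parameters
    ----------
    sample_id:
        Identifier of the hybridized sample.
    beads:
        Mapping ``probe_id -> 1-d array of raw bead intensities`` (arbitrary
        units, strictly positive).  Every probe must carry at least one bead.
    negative_control_ids:
        Probe ids of the negative-control bead types; must be a subset of the
        probes present.
    """

    sample_id: str
    beads: dict[str, np.ndarray]
    negative_control_ids: frozenset[str]

    def __post_init__(self) -> None:
        self.beads = {p: np.asarray(v, dtype=float) for p, v in self.beads.items()}
        for probe, values in self.beads.items():
            if values.size < 1:
                raise ValueError(f"probe {probe!r} has no beads")
        missing = set(self.negative_control_ids) - set(self.beads)
        if missing:
            raise ValueError(
                f"negative-control probes absent from array: {sorted(missing)[:5]}"
            )
        self.negative_control_ids = frozenset(self.negative_control_ids)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.beads)

    @property
    def gene_probe_ids(self) -> list[str]:
        return [p for p in self.beads if p not in self.negative_control_ids]


@dataclass(frozen=True)
class ProbeCall:
    """Summary of one probe on one array after outlier removal."""

    probe_id: str
    mean_intensity: float
    n_beads_retained: int
    n_beads_removed: int
    detection_p: float
    present: bool


@dataclass
class ExpressionMatrix:
    """Probes x samples expression values with metadata and presence masks.

    ``values`` holds summarized intensities (probe rows, sample columns) on the
    scale named by ``scale`` (``raw``, ``log2`` or ``log2-quantile``).
    ``presence`` is a boolean grid of per-array detection calls aligned with
    ``values``.  ``sample_meta`` is indexed by sample id and carries at least
    ``subject_id``, ``group``, ``timepoint``, ``treated`` and ``crp``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    presence: pd.DataFrame
    scale: str = "raw"
    negative_control_summary: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.scale not in {"raw", "log2", "log2-quantile"}:
            raise ValueError(f"unknown scale tag {self.scale!r}")
        if list(self.values.columns) != list(self.presence.columns) or not (
            self.values.index.equals(self.presence.index)
        ):
            raise ValueError("values and presence grids are not aligned")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing cells")
        missing_meta = set(self.values.columns) - set(self.sample_meta.index)
        if missing_meta:
            raise ValueError(f"samples without metadata: {sorted(missing_meta)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    def samples_where(self, **conditions) -> list[str]:
        """Sample ids whose metadata matches all ``column=value`` conditions."""
        meta = self.sample_meta.loc[self.sample_ids]
        mask = pd.Series(True, index=meta.index)
        for col, val in conditions.items():
            mask &= meta[col] == val
        return list(meta.index[mask])

    def group_active(
        self,
        groups: Mapping[str, Sequence[str]],
        presence_table: Mapping[int, int] | None = None,
        alpha: float = 0.05,
    ) -> pd.DataFrame:
        """Per-group transcriptional-activity calls for every probe.

        ``groups`` maps a group name to the sample ids forming that group.
        A probe is active in a group when its presence count reaches the
        group-size threshold (see :func:`group_presence`).
        """
        table = PRESENCE_TABLE if presence_table is None else presence_table
        out = {}
        for name, samples in groups.items():
            samples = list(samples)
            k = presence_threshold(len(samples), table, alpha)
            out[name] = self.presence[samples].sum(axis=1) >= k
        return pd.DataFrame(out, index=self.presence.index)

    def assessed_probes(
        self,
        groups: Mapping[str, Sequence[str]],
        presence_table: Mapping[int, int] | None = None,
        alpha: float = 0.05,
    ) -> pd.Index:
        """Probes active in at least one of the compared groups (union rule)."""
        active = self.group_active(groups, presence_table, alpha)
        return self.values.index[active.any(axis=1)]


# ---------------------------------------------------------------------------
# Bead-level operations
# ---------------------------------------------------------------------------


def remove_bead_outliers(
    intensities: Sequence[float],
    mad_multiplier: float = MAD_MULTIPLIER,
    mad_zero_policy: str = "strict",
) -> tuple[list[float], list[float]]:
    """Split bead intensities into retained and removed by the MAD rule.

    A bead is removed when its intensity lies strictly outside
    ``[median - m * MAD, median + m * MAD]`` where MAD is the unscaled median
    absolute deviation (no 1.4826 consistency factor); boundary values are
    retained.  When MAD is 0 the strict rule keeps only beads equal to the
    median; ``mad_zero_policy="retain_all"`` keeps everything instead (the
    degenerate case is logged either way).  Input order is preserved.
    """
    values = np.asarray(intensities, dtype=float)
    if values.size == 0:
        raise ValueError("cannot filter an empty bead list")
    if mad_zero_policy not in {"strict", "retain_all"}:
        raise ValueError(f"unknown mad_zero_policy {mad_zero_policy!r}")
    median = float(np.median(values))
    mad = float(np.median(np.abs(values - median)))
    if mad == 0.0 and values.size > 1 and not np.all(values == median):
        logger.warning(
            "MAD is 0 for a %d-bead probe; policy=%s", values.size, mad_zero_policy
        )
        if mad_zero_policy == "retain_all":
            return list(values), []
    lo = median - mad_multiplier * mad
    hi = median + mad_multiplier * mad
    keep = (values >= lo) & (values <= hi)
    return list(values[keep]), list(values[~keep])


def summarize_probe(retained: Sequence[float]) -> float:
    """Arithmetic mean of the retained bead intensities."""
    values = np.asarray(retained, dtype=float)
    if values.size == 0:
        raise ValueError("all beads removed; probe has no retained intensities")
    return float(values.mean())


def detection_call(
    probe_beads_retained: Sequence[float],
    negcontrol_values: Sequence[float],
    alpha: float = DETECTION_ALPHA,
) -> tuple[float, bool]:
    """One-sided Welch t-test of probe beads against negative-control beads.

    Returns ``(detection_p, present)`` with ``present`` true when the probe
    mean is significantly higher than the negative-control mean (p < alpha).
    If both samples are degenerate (zero variance) the call falls back to the
    sign of the mean difference: equal means give p = 1.
    """
    probe = np.asarray(probe_beads_retained, dtype=float)
    neg = np.asarray(negcontrol_values, dtype=float)
    if probe.size < 2 or neg.size < 2:
        raise ValueError("detection_call needs at least 2 values per sample")
    if probe.var(ddof=1) == 0.0 and neg.var(ddof=1) == 0.0:
        diff = probe.mean() - neg.mean()
        p = 0.0 if diff > 0 else 1.0
        return p, p < alpha
    t, p = stats.ttest_ind(probe, neg, equal_var=False, alternative="greater")
    return float(p), bool(p < alpha)


def detection_call_summary(
    probe_mean: float,
    negcontrol_means: Sequence[float],
    alpha: float = DETECTION_ALPHA,
) -> tuple[float, bool]:
    """Detection against the distribution of negative-control probe means.

    One-sided predictive t-test of a single probe's log2 summarized intensity
    against the log2 summarized intensities of the negative-control probes:
    t = (x - mean(y)) / (sd(y) * sqrt(1 + 1/m)) with m - 1 degrees of
    freedom.  This is the calibrated companion to MAD-trimmed summarization:
    the spread of the control probe means empirically captures the sampling
    variance of a trimmed mean, which the within-probe bead variance
    understates (outlier trimming concentrates the retained beads around the
    sample median).  Used per array by :func:`process_bead_array`.
    """
    y = np.log2(np.asarray(negcontrol_means, dtype=float))
    if y.size < 3:
        raise ValueError("need >= 3 negative-control probe means")
    if np.isnan(probe_mean):
        return 1.0, False
    s = y.std(ddof=1)
    diff = np.log2(probe_mean) - y.mean()
    if s == 0.0:
        p = 0.0 if diff > 0 else 1.0
        return p, bool(p < alpha)
    t = diff / (s * math.sqrt(1.0 + 1.0 / y.size))
    p = float(stats.t.sf(t, y.size - 1))
    return p, bool(p < alpha)


def presence_threshold(
    n: int,
    presence_table: Mapping[int, int] | None = None,
    alpha: float = 0.05,
) -> int:
    """Minimum presence count for a probe to be active in a group of size n.

    Lookup values (8 of 12, 13 of 18) take precedence.  Otherwise the
    threshold is the smallest k whose one-sided Z-test of the observed
    proportion k/n against p0 = 0.5 (no continuity correction) gives p < 0.05.
    If no count reaches significance the threshold is n + 1 (never active).
    """
    if n < 1:
        raise ValueError("group size must be >= 1")
    table = PRESENCE_TABLE if presence_table is None else presence_table
    if n in table:
        return table[n]
    se = math.sqrt(0.25 / n)
    for k in range(1, n + 1):
        z = (k / n - 0.5) / se
        if stats.norm.sf(z) < alpha:
            return k
    return n + 1


def group_presence(
    presence_flags: Sequence[bool],
    presence_table: Mapping[int, int] | None = None,
    alpha: float = 0.05,
) -> bool:
    """Whether a probe is transcriptionally active in one group.

    ``presence_flags`` holds the per-sample detection calls of one probe for
    the samples of one group.
    """
    flags = np.asarray(presence_flags, dtype=bool)
    k = presence_threshold(flags.size, presence_table, alpha)
    return bool(flags.sum() >= k)


# ---------------------------------------------------------------------------
# Per-array processing (vectorized over probes)
# ---------------------------------------------------------------------------


def _filter_block(
    block: np.ndarray, mad_multiplier: float, mad_zero_policy: str
) -> np.ndarray:
    """Boolean keep-mask for a (probes, beads) block under the MAD rule."""
    med = np.median(block, axis=1, keepdims=True)
    mad = np.median(np.abs(block - med), axis=1, keepdims=True)
    keep = (block >= med - mad_multiplier * mad) & (block <= med + mad_multiplier * mad)
    if mad_zero_policy == "retain_all":
        degenerate = (mad == 0.0).ravel()
        keep[degenerate, :] = True
    return keep


def process_bead_array(
    array: BeadArray,
    mad_multiplier: float = MAD_MULTIPLIER,
    alpha: float = DETECTION_ALPHA,
    mad_zero_policy: str = "strict",
) -> pd.DataFrame:
    """Outlier removal, summarization and detection calls for one array.

    Returns a DataFrame indexed by probe id with columns ``mean_intensity``,
    ``n_beads_retained``, ``n_beads_removed``, ``detection_p``, ``present``.
    Detection uses :func:`detection_call_summary`: each probe's log2 trimmed
    mean is tested against the distribution of the array's negative-control
    probe means.  Probes whose beads are all removed get NaN mean, are called
    absent, and are logged.
    """
    if mad_zero_policy not in {"strict", "retain_all"}:
        raise ValueError(f"unknown mad_zero_policy {mad_zero_policy!r}")
    probe_ids = np.array(array.probe_ids)
    lengths = np.array([array.beads[p].size for p in probe_ids])

    n_probes = probe_ids.size
    means = np.full(n_probes, np.nan)
    n_ret = np.zeros(n_probes, dtype=int)
    n_rem = np.zeros(n_probes, dtype=int)

    neg_mask = np.isin(probe_ids, list(array.negative_control_ids))

    # Group probes by bead count so each group is a dense (probes, beads) block.
    for L in np.unique(lengths):
        sel = np.flatnonzero(lengths == L)
        block = np.stack([array.beads[p] for p in probe_ids[sel]])
        if L == 1:
            keep = np.ones_like(block, dtype=bool)
        else:
            keep = _filter_block(block, mad_multiplier, mad_zero_policy)
        k = keep.sum(axis=1)
        s = np.where(keep, block, 0.0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            m = np.where(k > 0, s / np.maximum(k, 1), np.nan)
        means[sel] = m
        n_ret[sel] = k
        n_rem[sel] = L - k

    detection_p = np.ones(n_probes)
    present = np.zeros(n_probes, dtype=bool)
    neg_means = means[neg_mask]
    neg_means = neg_means[~np.isnan(neg_means) & (neg_means > 0)]
    if neg_means.size >= 3:
        y = np.log2(neg_means)
        ybar, s_y, m_neg = y.mean(), y.std(ddof=1), y.size
        ok = ~np.isnan(means) & (means > 0)
        if s_y == 0.0:
            detection_p[ok] = np.where(np.log2(means[ok]) > ybar, 0.0, 1.0)
        else:
            with np.errstate(invalid="ignore"):
                tstat = (np.log2(means[ok]) - ybar) / (
                    s_y * math.sqrt(1.0 + 1.0 / m_neg))
            detection_p[ok] = stats.t.sf(tstat, m_neg - 1)
        present = detection_p < alpha
        present[~ok] = False
    else:
        logger.warning(
            "array %s: fewer than 3 usable negative-control probes; "
            "all probes called absent", array.sample_id,
        )

    n_missing = int(np.isnan(means).sum())
    logger.info(
        "array %s: %d beads removed, %d probes present, %d probes lost all beads",
        array.sample_id,
        int(n_rem.sum()),
        int(present[~neg_mask].sum()),
        n_missing,
    )
    return pd.DataFrame(
        {
            "mean_intensity": means,
            "n_beads_retained": n_ret,
            "n_beads_removed": n_rem,
            "detection_p": detection_p,
            "present": present,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )


def build_expression_matrix(
    arrays: Iterable[BeadArray],
    meta: pd.DataFrame,
    mad_multiplier: float = MAD_MULTIPLIER,
    alpha: float = DETECTION_ALPHA,
    mad_zero_policy: str = "strict",
    calls: Mapping[str, pd.DataFrame] | None = None,
) -> ExpressionMatrix:
    """Assemble per-array probe calls into a raw-scale expression matrix.

    All arrays must share the same probe universe (an error lists offending
    probes otherwise).  Negative-control probes are summarized separately and
    excluded from the gene rows.  A probe that lost all its beads on one array
    is imputed with that array's minimum summarized gene intensity (logged) so
    the matrix has no missing cells.  ``calls`` may supply precomputed
    per-array probe-call frames (from :func:`process_bead_array`) to avoid
    reprocessing.
    """
    arrays = list(arrays)
    if not arrays:
        raise ValueError("no arrays given")
    universe = set(arrays[0].beads)
    neg_ids = set(arrays[0].negative_control_ids)
    for arr in arrays[1:]:
        if set(arr.beads) != universe:
            offending = sorted(set(arr.beads) ^ universe)
            raise ValueError(
                f"probe universe mismatch for array {arr.sample_id!r}: "
                f"{offending[:10]}{'...' if len(offending) > 10 else ''}"
            )

    if calls is None:
        calls = {arr.sample_id: process_bead_array(
            arr, mad_multiplier, alpha, mad_zero_policy) for arr in arrays}
    gene_index = pd.Index(
        [p for p in arrays[0].probe_ids if p not in neg_ids], name="probe_id"
    )
    values = pd.DataFrame(
        {sid: c["mean_intensity"].reindex(gene_index) for sid, c in calls.items()}
    )
    presence = pd.DataFrame(
        {sid: c["present"].reindex(gene_index) for sid, c in calls.items()}
    ).astype(bool)
    neg_summary = pd.DataFrame(
        {
            sid: c["mean_intensity"].reindex(sorted(neg_ids))
            for sid, c in calls.items()
        }
    )

    for sid in values.columns:
        col = values[sid]
        if col.isna().any():
            fill = col.min()
            n_imputed = int(col.isna().sum())
            logger.warning(
                "array %s: imputing %d probes with array minimum %.4g",
                sid,
                n_imputed,
                fill,
            )
            values[sid] = col.fillna(fill)
            presence.loc[col.isna(), sid] = False

    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    return ExpressionMatrix(
        values=values,
        sample_meta=meta,
        presence=presence,
        scale="raw",
        negative_control_summary=neg_summary,
    )
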