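"""Normalization and differential expression for small two-group designs.

Log2-quantile normalization forces every sample onto the common (mean)
empirical distribution.  Differential expression between independent groups
uses a Bayesian-regularized t statistic in the Cyber-T family: the pooled
per-gene variance is shrunk toward a local background variance estimated from
the genes with similar average expression (a sliding window in rank order).
With small samples this stabilizes the denominator of the t statistic, the
reason the approach is preferred over the ordinary t at n of order 10.
Matched pre/post comparisons use the standard paired t-test.  Fold changes
are reported as 2**(difference of group mean log2 values).  A threshold-grid
counter tallies genes at the significance/fold-change cutoffs used for
tertile subanalyses.

The regularized variance is

    s2_reg = (c * sigma0^2 + nu * sp^2) / (c + nu),   nu = n1 + n2 - 2,

with sp^2 the pooled two-sample variance, sigma0^2 the window-average pooled
variance and c the prior confidence (pseudo-observations).  As c -> 0 the
statistic reduces exactly to the ordinary pooled two-sample t.  P-values use
a t distribution with n1 + n2 - 2 + 2c - 2 degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .beadproc import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CybertConfig",
    "log2_quantile_normalize",
    "cybert_unpaired",
    "paired_t",
    "fold_change",
    "de_table",
    "threshold_count_table",
    "crp_tertile_contrast",
    "GRID_CELLS",
]


@dataclass(frozen=True)
class CybertConfig:
    """Hyperparameters of the regularized t-test.

    window_size: odd count of rank-neighbouring genes over which the
        background variance is averaged (truncated at the ends of the rank
        range).  Genes are ranked by mean log2 expression.
    confidence: weight of the background variance in pseudo-observations.
    """

    window_size: int = 101
    confidence: float = 10.0

    def validate(self, n_genes: int) -> None:
        if self.window_size < 1 or self.window_size % 2 == 0:
            raise ValueError("window_size must be an odd positive count")
        if self.window_size > n_genes:
            raise ValueError(
                f"window_size ({self.window_size}) exceeds the number of "
                f"tested genes ({n_genes}); lower window_size")
        if self.confidence <= 0:
            raise ValueError("confidence must be > 0")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def log2_quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Log2-transform then quantile-normalize a raw expression matrix.

    Each sample's sorted log2 values are replaced by the across-sample mean of
    the values at the same rank; tied values within a sample receive the mean
    of the reference values their tied ranks span.  Afterwards every sample
    holds the same multiset of values (exactly, absent ties).
    """
    if matrix.scale != "raw":
        raise ValueError(f"expected a raw-scale matrix, got {matrix.scale!r}")
    values = matrix.values
    bad = values <= 0
    if bad.any().any():
        probe = bad.any(axis=1).idxmax()
        sample = bad.loc[probe].idxmax()
        raise ValueError(
            f"nonpositive intensity at probe {probe!r}, sample {sample!r}")

    arr = np.log2(values.to_numpy(dtype=float))
    n, s = arr.shape
    order = np.argsort(arr, axis=0, kind="stable")
    ref = np.take_along_axis(arr, order, axis=0).mean(axis=1)

    out = np.empty_like(arr)
    for j in range(s):
        idx = order[:, j]
        col_sorted = arr[idx, j]
        # mean of reference values over each tied run
        _, inverse, counts = np.unique(
            col_sorted, return_inverse=True, return_counts=True)
        tie_mean = np.bincount(inverse, weights=ref) / counts
        out[idx, j] = tie_mean[inverse]

    normalized = pd.DataFrame(out, index=values.index, columns=values.columns)
    return ExpressionMatrix(
        values=normalized,
        sample_meta=matrix.sample_meta,
        presence=matrix.presence,
        scale="log2-quantile",
        negative_control_summary=matrix.negative_control_summary,
    )


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------


def _window_mean(values: np.ndarray, half: int) -> np.ndarray:
    """Mean of each element's rank-window, truncated at the ends."""
    n = values.size
    cs = np.concatenate([[0.0], np.cumsum(values)])
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (cs[hi] - cs[lo]) / (hi - lo)


def cybert_unpaired(
    values_a: np.ndarray | pd.DataFrame,
    values_b: np.ndarray | pd.DataFrame,
    cfg: CybertConfig = CybertConfig(),
) -> tuple[np.ndarray, np.ndarray]:
    """Regularized two-sample t-test per gene (rows).

    ``values_a`` and ``values_b`` are genes x samples log2 matrices of the two
    groups, row-aligned.  Returns ``(t_reg, p)`` arrays; the sign of t is
    groupA minus groupB.  Degenerate all-zero windows fall back to the
    smallest positive gene variance (logged).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.ndim == 1:
        a = a[None, :]
    if b.ndim == 1:
        b = b[None, :]
    if a.shape[0] != b.shape[0]:
        raise ValueError("group matrices must have the same genes (rows)")
    n_genes, na = a.shape
    nb = b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("need >= 2 samples per group")
    cfg.validate(n_genes)

    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    nu = na + nb - 2
    sp2 = ((na - 1) * a.var(axis=1, ddof=1) + (nb - 1) * b.var(axis=1, ddof=1)) / nu

    rank_stat = np.concatenate([a, b], axis=1).mean(axis=1)
    order = np.argsort(rank_stat, kind="stable")
    half = (cfg.window_size - 1) // 2
    sigma0 = np.empty(n_genes)
    sigma0[order] = _window_mean(sp2[order], half)

    if np.any(sigma0 <= 0):
        positive = sp2[sp2 > 0]
        if positive.size:
            fallback = positive.min()
            logger.warning(
                "cybert: %d zero background variances replaced by the "
                "smallest positive gene variance", int((sigma0 <= 0).sum()))
            sigma0 = np.where(sigma0 <= 0, fallback, sigma0)

    c = cfg.confidence
    s2_reg = (c * sigma0 + nu * sp2) / (c + nu)
    se = np.sqrt(s2_reg * (1.0 / na + 1.0 / nb))
    diff = mean_a - mean_b
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0),
                     np.where(diff == 0, 0.0, np.inf * np.sign(diff)))
    df = max(na + nb - 2 + 2 * c - 2, 1.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, p


def paired_t(
    values_pre: np.ndarray | pd.DataFrame,
    values_post: np.ndarray | pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray]:
    """Standard paired t-test per gene on subject-matched columns.

    Returns ``(t, p)``; the sign of t is post minus pre.  Zero-variance
    differences give p = 1 when the mean difference is 0 and p = 0 otherwise
    (degenerate, logged).
    """
    pre = np.asarray(values_pre, dtype=float)
    post = np.asarray(values_post, dtype=float)
    if pre.ndim == 1:
        pre = pre[None, :]
    if post.ndim == 1:
        post = post[None, :]
    if pre.shape != post.shape:
        raise ValueError("pre and post matrices must be subject-aligned")
    n = pre.shape[1]
    if n < 2:
        raise ValueError("need >= 2 matched pairs")
    d = post - pre
    mean_d = d.mean(axis=1)
    sd_d = d.std(axis=1, ddof=1)
    t = np.zeros(d.shape[0])
    p = np.ones(d.shape[0])
    regular = sd_d > 0
    t[regular] = mean_d[regular] / (sd_d[regular] / np.sqrt(n))
    p[regular] = 2.0 * stats.t.sf(np.abs(t[regular]), n - 1)
    degenerate = (~regular) & (mean_d != 0)
    if degenerate.any():
        logger.info("paired_t: %d degenerate zero-variance genes with "
                    "nonzero mean difference", int(degenerate.sum()))
        t[degenerate] = np.inf * np.sign(mean_d[degenerate])
        p[degenerate] = 0.0
    return t, p


def fold_change(mean_log2_a, mean_log2_b):
    """Linear fold change 2**(mean_log2_a - mean_log2_b)."""
    return 2.0 ** (np.asarray(mean_log2_a) - np.asarray(mean_log2_b))


# ---------------------------------------------------------------------------
# DE tables and threshold grids
# ---------------------------------------------------------------------------


def de_table(
    matrix: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    test: str = "cybert_unpaired",
    genes: pd.Index | Sequence[str] | None = None,
    cfg: CybertConfig = CybertConfig(),
    add_fdr: bool = False,
) -> pd.DataFrame:
    """Per-gene fold change and p-value for one contrast, sorted by p.

    ``test`` is ``cybert_unpaired`` (independent groups, A vs B) or
    ``paired_t`` (A = post, B = pre, columns subject-aligned).  ``genes``
    restricts testing to a subset (typically the assessed probes).  The
    returned frame has columns fold_change, p_value, test, mean_log2_groupA,
    mean_log2_groupB (and fdr_bh when requested); fold_change is
    2**(meanA - meanB) on the matrix's log2 scale.
    """
    if not matrix.scale.startswith("log2"):
        raise ValueError("DE testing expects a log2-scale matrix")
    sub = matrix.values if genes is None else matrix.values.loc[list(genes)]
    a = sub[list(group_a)].to_numpy()
    b = sub[list(group_b)].to_numpy()
    if test == "cybert_unpaired":
        _, p = cybert_unpaired(a, b, cfg)
    elif test == "paired_t":
        _, p = paired_t(b, a)  # sign convention: A (post) minus B (pre)
    else:
        raise ValueError(f"unknown test {test!r}")
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    out = pd.DataFrame(
        {
            "fold_change": fold_change(mean_a, mean_b),
            "p_value": p,
            "test": test,
            "mean_log2_groupA": mean_a,
            "mean_log2_groupB": mean_b,
        },
        index=sub.index,
    )
    if add_fdr:
        out["fdr_bh"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out.sort_values("p_value", kind="stable")


#: (label, p cutoff, fold-change band or None) -- strict inequalities.
GRID_CELLS: list[tuple[str, float, tuple[float, float] | None]] = [
    ("p<0.05", 0.05, None),
    ("p<0.01", 0.01, None),
    ("p<0.001", 0.001, None),
    ("p<0.0001", 0.0001, None),
    ("p<0.05 & FC<0.74 or >1.35", 0.05, (0.74, 1.35)),
    ("p<0.001 & FC<0.82 or >1.2", 0.001, (0.82, 1.2)),
    ("p<0.0001 & FC<0.91 or >1.1", 0.0001, (0.91, 1.1)),
]


def threshold_count_table(de: pd.DataFrame) -> pd.Series:
    """Gene counts at the significance/fold-change threshold grid.

    All inequalities are strict, exactly as the cell labels read; a gene with
    p equal to a cutoff is not counted in that cell.
    """
    p = de["p_value"]
    fc = de["fold_change"]
    counts = {}
    for label, p_cut, band in GRID_CELLS:
        mask = p < p_cut
        if band is not None:
            lo, hi = band
            mask &= (fc < lo) | (fc > hi)
        counts[label] = int(mask.sum())
    return pd.Series(counts, name="n_genes")


def crp_tertile_contrast(
    matrix: ExpressionMatrix,
    genes: pd.Index | Sequence[str] | None = None,
    cfg: CybertConfig = CybertConfig(),
) -> tuple[pd.Series, pd.Series]:
    """Threshold grids for the lowest- and highest-CRP patient tertiles.

    Baseline patients are sorted by CRP (ties broken by sample id, logged
    when the count is not divisible by three); the lowest and highest
    floor(n/3) are each tested against all baseline controls with the
    regularized t on the given gene set.  Returns (grid_low, grid_high).
    """
    meta = matrix.sample_meta.loc[matrix.sample_ids]
    patients = meta[(meta["group"] == "patient") & (meta["timepoint"] == "baseline")]
    controls = matrix.samples_where(group="control", timepoint="baseline")
    if patients["crp"].isna().any():
        missing = list(patients.index[patients["crp"].isna()])
        raise ValueError(f"CRP missing for samples: {missing}")
    n = len(patients)
    size = n // 3
    if n % 3:
        logger.info("patient count %d not divisible by 3; tertile size %d "
                    "(ties broken by sample id)", n, size)
    ranked = patients.assign(_sid=patients.index).sort_values(
        ["crp", "_sid"], kind="stable")
    low = list(ranked.index[:size])
    high = list(ranked.index[-size:])
    grid_low = threshold_count_table(
        de_table(matrix, low, controls, "cybert_unpaired", genes, cfg))
    grid_high = threshold_count_table(
        de_table(matrix, high, controls, "cybert_unpaired", genes, cfg))
    return grid_low, grid_high
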