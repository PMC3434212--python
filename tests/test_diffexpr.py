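"""Normalization, regularized and paired tests, fold changes, grids."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from beadpipe import (CybertConfig, ExpressionMatrix, crp_tertile_contrast,
                      cybert_unpaired, de_table, fold_change,
                      log2_quantile_normalize, paired_t,
                      threshold_count_table)


def _raw_matrix(values, samples=None, meta=None):
    values = pd.DataFrame(values)
    values.index = [f"G{i}" for i in range(len(values))]
    values.index.name = "probe_id"
    if samples is not None:
        values.columns = samples
    if meta is None:
        meta = pd.DataFrame({
            "subject_id": list(values.columns),
            "group": "control", "timepoint": "baseline", "treated": 0,
            "crp": 1.0}, index=values.columns)
    presence = pd.DataFrame(True, index=values.index, columns=values.columns)
    return ExpressionMatrix(values, meta, presence, scale="raw")


class TestLog2QuantileNormalize:
    def test_single_sample_is_log2_passthrough(self):
        m = _raw_matrix({"s1": [2.0, 8.0, 4.0]})
        out = log2_quantile_normalize(m)
        assert out.scale == "log2-quantile"
        assert np.allclose(out.values["s1"], [1.0, 3.0, 2.0])

    def test_two_sample_rank_alignment(self):
        # log2: s1=(1,2,3), s2=(2,3,4) -> rank-wise means (1.5, 2.5, 3.5)
        m = _raw_matrix({"s1": [2.0, 4.0, 8.0], "s2": [4.0, 8.0, 16.0]})
        out = log2_quantile_normalize(m)
        assert np.allclose(out.values["s1"], [1.5, 2.5, 3.5])
        assert np.allclose(out.values["s2"], [1.5, 2.5, 3.5])

    def test_tied_values_share_spanned_reference_mean(self):
        # s1 log2 = (1, 1, 2): tie spans ranks 1-2 of reference (1, 1.5, 2.5)
        m = _raw_matrix({"s1": [2.0, 2.0, 4.0], "s2": [2.0, 4.0, 8.0]})
        out = log2_quantile_normalize(m)
        assert np.allclose(out.values["s1"], [1.25, 1.25, 2.5])
        assert np.allclose(out.values["s2"], [1.0, 1.5, 2.5])

    def test_identical_sorted_columns_and_rank_preservation(self):
        rng = np.random.default_rng(0)
        vals = rng.lognormal(5, 1, (50, 6))
        m = _raw_matrix(pd.DataFrame(vals, columns=[f"s{j}" for j in range(6)]))
        out = log2_quantile_normalize(m)
        ref = np.sort(out.values.iloc[:, 0].to_numpy())
        for col in out.values:
            assert np.allclose(np.sort(out.values[col].to_numpy()), ref)
            assert (np.argsort(out.values[col].to_numpy(), kind="stable")
                    == np.argsort(np.log2(m.values[col].to_numpy()),
                                  kind="stable")).all()

    def test_nonpositive_cell_named_in_error(self):
        m = _raw_matrix({"s1": [2.0, 4.0], "s2": [4.0, 8.0]})
        m.values.iloc[1, 0] = -1.0
        with pytest.raises(ValueError, match="G1.*s1"):
            log2_quantile_normalize(m)


class TestCybert:
    def test_zero_confidence_limit_equals_pooled_t(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, (300, 12))
        b = rng.normal(0, 1, (300, 18))
        t_reg, _ = cybert_unpaired(a, b, CybertConfig(101, 1e-9))
        t_ref = stats.ttest_ind(a, b, axis=1, equal_var=True).statistic
        assert np.max(np.abs(t_reg - t_ref)) < 1e-6

    def test_constant_gene_with_background_variance(self):
        rng = np.random.default_rng(2)
        a = rng.normal(5, 1, (51, 4))
        b = rng.normal(5, 1, (51, 4))
        a[0], b[0] = 3.0, 3.0  # constant, equal means
        t_reg, p = cybert_unpaired(a, b, CybertConfig(51, 10))
        assert t_reg[0] == 0.0 and p[0] == 1.0

    def test_regularization_shrinks_extreme_t(self):
        # a gene with spuriously tiny variance gets a larger (regularized)
        # denominator, so |t_reg| < |t_ordinary|
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, (101, 6))
        b = rng.normal(0, 1, (101, 6))
        a[0] = [0.001, 0.002, 0.001, 0.002, 0.001, 0.002]
        b[0] = [-0.001, -0.002, -0.001, -0.002, -0.001, -0.002]
        t_reg, _ = cybert_unpaired(a, b, CybertConfig(101, 10))
        t_ord = stats.ttest_ind(a[0], b[0], equal_var=True).statistic
        assert abs(t_reg[0]) < abs(t_ord)

    def test_window_size_error(self):
        a = np.zeros((10, 3))
        with pytest.raises(ValueError, match="window_size"):
            cybert_unpaired(a, a, CybertConfig(101, 10))

    def test_small_null_calibration(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, (2000, 12))
        b = rng.normal(0, 1, (2000, 18))
        _, p = cybert_unpaired(a, b, CybertConfig(101, 10))
        frac = (p < 0.05).mean()
        assert 0.03 < frac < 0.07

    def test_power_on_planted_shift(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 0.6, (500, 18))
        b = rng.normal(0, 0.6, (500, 12))
        a[:100] += 0.6  # planted DE genes
        _, p = cybert_unpaired(a, b, CybertConfig(101, 10))
        sensitivity = (p[:100] < 0.05).mean()
        fpr = (p[100:] < 0.05).mean()
        assert sensitivity >= 5 * max(fpr, 0.01)


class TestPairedT:
    def test_identical_timepoints(self):
        pre = np.array([[1.0, 2.0, 3.0]])
        t, p = paired_t(pre, pre)
        assert t[0] == 0.0 and p[0] == 1.0

    def test_constant_nonzero_differences_degenerate(self):
        pre = np.array([[1.0, 2.0, 3.0, 4.0]])
        t, p = paired_t(pre, pre + 1.0)
        assert p[0] == 0.0 and np.isinf(t[0])

    def test_hand_computed_example(self):
        pre = np.array([[1.0, 2.0, 3.0, 4.0]])
        post = np.array([[2.0, 3.0, 5.0, 6.0]])
        t, p = paired_t(pre, post)
        assert t[0] == pytest.approx(5.196152, abs=1e-5)
        assert p[0] == pytest.approx(0.0138, abs=5e-4)
        ref = stats.ttest_rel(post[0], pre[0])
        assert p[0] == pytest.approx(ref.pvalue, rel=1e-12)

    def test_null_uniformity(self):
        rng = np.random.default_rng(6)
        pre = rng.normal(0, 1, (3000, 12))
        post = rng.normal(0, 1, (3000, 12))
        _, p = paired_t(pre, post)
        assert stats.kstest(p, "uniform").pvalue > 0.01


class TestFoldChange:
    @pytest.mark.parametrize("a,b,expected", [
        (5.0, 5.0, 1.0), (6.0, 5.0, 2.0), (3.25, 5.0, 2.0 ** -1.75)])
    def test_examples(self, a, b, expected):
        assert fold_change(a, b) == pytest.approx(expected, rel=1e-12)
        assert expected != 2.0 ** -1.75 or \
            fold_change(a, b) == pytest.approx(0.2973, abs=1e-4)

    def test_reciprocal(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(8, 2, 100), rng.normal(8, 2, 100)
        assert np.allclose(fold_change(a, b) * fold_change(b, a), 1.0)


# 20-gene fixture with hand-computed grid counts (strict inequalities).
GRID_FIXTURE = [
    (0.04, 1.40), (0.04, 1.30), (0.009, 0.70), (0.0009, 1.25),
    (0.00009, 1.05), (0.00009, 0.90), (0.05, 2.0), (0.2, 0.5),
    (0.001, 0.81), (0.0005, 0.80), (0.04, 0.74), (0.04, 1.35),
    (0.008, 1.36), (0.00005, 1.12), (0.5, 1.0), (0.03, 0.60),
    (0.002, 1.5), (0.0002, 0.73), (0.9, 3.0), (0.0099, 1.0),
]
GRID_EXPECTED = [16, 11, 6, 3, 6, 3, 2]


class TestThresholdGrid:
    def test_empty_table(self):
        de = pd.DataFrame({"p_value": [], "fold_change": []})
        assert (threshold_count_table(de) == 0).all()

    def test_single_gene_membership(self):
        de = pd.DataFrame({"p_value": [0.04], "fold_change": [1.4]})
        grid = threshold_count_table(de)
        assert grid["p<0.05"] == 1
        assert grid["p<0.05 & FC<0.74 or >1.35"] == 1
        assert grid["p<0.01"] == 0 and grid["p<0.001"] == 0

    def test_boundary_p_counted_nowhere(self):
        de = pd.DataFrame({"p_value": [0.05], "fold_change": [2.0]})
        assert (threshold_count_table(de) == 0).all()

    def test_hand_computed_fixture(self):
        p, fc = zip(*GRID_FIXTURE)
        de = pd.DataFrame({"p_value": p, "fold_change": fc})
        grid = threshold_count_table(de)
        assert list(grid) == GRID_EXPECTED

    def test_pure_p_column_non_increasing(self, small_norm, baseline_groups):
        de = de_table(small_norm, baseline_groups["patient"],
                      baseline_groups["control"], "cybert_unpaired",
                      cfg=CybertConfig(101, 10))
        grid = threshold_count_table(de)
        pure = [grid["p<0.05"], grid["p<0.01"], grid["p<0.001"],
                grid["p<0.0001"]]
        assert pure == sorted(pure, reverse=True)


class TestDeTable:
    def test_fold_change_consistent_with_means(self, small_norm,
                                               baseline_groups):
        de = de_table(small_norm, baseline_groups["patient"],
                      baseline_groups["control"], "cybert_unpaired",
                      cfg=CybertConfig(101, 10))
        assert np.allclose(
            de["fold_change"],
            2.0 ** (de["mean_log2_groupA"] - de["mean_log2_groupB"]))
        assert de["p_value"].is_monotonic_increasing
        assert de["p_value"].between(0, 1).all()

    def test_optional_fdr_column(self, small_norm, baseline_groups):
        de = de_table(small_norm, baseline_groups["patient"],
                      baseline_groups["control"], "cybert_unpaired",
                      cfg=CybertConfig(101, 10), add_fdr=True)
        assert (de["fdr_bh"] >= de["p_value"] - 1e-12).all()


class TestCrpTertiles:
    def test_tertile_sizes_and_grids(self, small_norm):
        low, high = crp_tertile_contrast(small_norm, cfg=CybertConfig(101, 10))
        assert set(low.index) == set(high.index)
        assert (low >= 0).all() and (high >= 0).all()

    def test_planted_high_crp_signal_raises_high_grid(self):
        from beadpipe import (SimConfig, build_expression_matrix,
                              generate_cohort)
        wins = 0
        for seed in range(3):
            cfg = SimConfig(n_probes=400, n_neg_controls=40,
                            beads_per_probe=10, n_de_genes=0,
                            n_crp_linked_genes=60, crp_linked_log2fc=1.0,
                            patient_effect_sd=0.2, rng_seed=100 + seed)
            arrays, meta, truth = generate_cohort(cfg)
            norm = log2_quantile_normalize(
                build_expression_matrix(arrays, meta))
            low, high = crp_tertile_contrast(norm, cfg=CybertConfig(101, 10))
            if high["p<0.05"] > low["p<0.05"]:
                wins += 1
        assert wins >= 2

    def test_missing_crp_errors(self, small_norm):
        import copy
        m = ExpressionMatrix(small_norm.values, small_norm.sample_meta.copy(),
                             small_norm.presence, scale=small_norm.scale)
        m.sample_meta.loc[m.samples_where(group="patient")[0], "crp"] = np.nan
        with pytest.raises(ValueError, match="CRP"):
            crp_tertile_contrast(m, cfg=CybertConfig(101, 10))
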