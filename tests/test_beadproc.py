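"""Bead-level preprocessing: outlier removal, detection, presence calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from beadpipe import beadproc
from beadpipe.beadproc import (BeadArray, build_expression_matrix,
                               detection_call, group_presence,
                               presence_threshold, process_bead_array,
                               remove_bead_outliers, summarize_probe)
from conftest import mad_oracle


class TestRemoveBeadOutliers:
    def test_constant_beads_all_retained(self):
        retained, removed = remove_bead_outliers([5, 5, 5, 5])
        assert retained == [5, 5, 5, 5] and removed == []

    def test_hand_computed_example(self):
        # median 10.5, MAD 1.5, bounds [7.5, 13.5]
        retained, removed = remove_bead_outliers([8, 9, 10, 11, 12, 30])
        assert retained == [8, 9, 10, 11, 12]
        assert removed == [30]
        assert summarize_probe(retained) == 10.0

    def test_zero_mad_strict_keeps_only_median(self):
        retained, removed = remove_bead_outliers([10, 10, 10, 100])
        assert retained == [10, 10, 10] and removed == [100]

    def test_zero_mad_retain_all_policy(self):
        retained, removed = remove_bead_outliers(
            [10, 10, 10, 100], mad_zero_policy="retain_all")
        assert removed == [] and len(retained) == 4

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            remove_bead_outliers([])

    def test_boundary_values_retained(self):
        # bounds are inclusive: values exactly at median +/- 2*MAD stay
        values = [1.0, 2.0, 3.0, 4.0, 5.0]  # median 3, MAD 1, bounds [1, 5]
        retained, removed = remove_bead_outliers(values)
        assert retained == values and removed == []

    @given(st.lists(st.floats(min_value=0.01, max_value=1e5,
                              allow_nan=False), min_size=1, max_size=40),
           st.floats(min_value=0.5, max_value=4.0))
    @settings(max_examples=300, derandomize=True, deadline=None)
    def test_matches_definitional_oracle(self, values, multiplier):
        got = remove_bead_outliers(values, multiplier)
        assert got == mad_oracle(values, multiplier)

    def test_retained_inside_removed_outside_bounds(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            values = rng.lognormal(3, 1, rng.integers(2, 30))
            retained, removed = remove_bead_outliers(values)
            med = np.median(values)
            mad = np.median(np.abs(values - med))
            lo, hi = med - 2 * mad, med + 2 * mad
            assert all(lo <= v <= hi for v in retained)
            assert all(v < lo or v > hi for v in removed)
            assert len(retained) + len(removed) == len(values)


class TestSummarizeProbe:
    @pytest.mark.parametrize("beads,expected", [([2, 4], 3.0), ([7], 7.0)])
    def test_mean(self, beads, expected):
        assert summarize_probe(beads) == expected

    def test_all_removed_errors(self):
        with pytest.raises(ValueError):
            summarize_probe([])


class TestDetectionCall:
    def test_identical_to_controls_absent(self):
        neg = [1.0, 2.0, 1.0, 2.0, 1.0, 2.0]
        p, present = detection_call(neg, neg)
        assert not present and p > 0.4

    def test_large_shift_present(self):
        neg = [1.0, 2.0, 1.0, 2.0, 1.0, 2.0]
        p, present = detection_call([v + 100 for v in neg], neg)
        assert present and p < 1e-4

    def test_hand_example_against_welch_oracle(self):
        probe, neg = [10, 11, 12, 13], [1, 2, 1, 2, 1, 2]
        p, present = detection_call(probe, neg)
        expected = stats.ttest_ind(probe, neg, equal_var=False,
                                   alternative="greater").pvalue
        assert present and p == pytest.approx(expected, rel=1e-12)
        assert p < 0.05

    def test_degenerate_equal_constant_samples(self):
        p, present = detection_call([3.0, 3.0], [3.0, 3.0, 3.0])
        assert p == 1.0 and not present

    def test_monotone_under_positive_shift(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            probe = rng.lognormal(2, 0.5, 10)
            neg = rng.lognormal(2, 0.5, 50)
            p0, present0 = detection_call(probe, neg)
            p1, present1 = detection_call(probe + rng.uniform(0.1, 50), neg)
            assert p1 <= p0 + 1e-12
            assert present1 or not present0


class TestGroupPresence:
    def test_printed_thresholds(self):
        assert presence_threshold(12) == 8
        assert presence_threshold(18) == 13

    def test_group_activity_rules(self):
        assert group_presence([True] * 8 + [False] * 4)          # 8 of 12
        assert not group_presence([True] * 7 + [False] * 5)      # 7 of 12
        assert not group_presence([True] * 12 + [False] * 6)     # 12 of 18
        assert group_presence([True] * 13 + [False] * 5)         # 13 of 18
        assert not group_presence([False] * 12)

    def test_z_rule_fallback_hand_computed(self):
        # n=6: k=5 gives z=1.633 (p>0.05); k=6 gives z=2.449 -> k(6)=6
        assert presence_threshold(6) == 6
        # n=20: smallest k with (k/20-0.5)/sqrt(0.25/20) > 1.6449 is 14
        assert presence_threshold(20) == 14

    def test_monotone_in_presence_count(self):
        for n in (5, 12, 18, 25):
            active = [group_presence([True] * k + [False] * (n - k))
                      for k in range(n + 1)]
            assert active == sorted(active)  # once active, stays active


def _array_from_levels(sample_id, levels, neg_levels, beads, rng, sd=0.4):
    probes = {}
    for i, mu in enumerate(levels):
        probes[f"G{i:04d}"] = 2.0 ** rng.normal(mu, sd, beads)
    for i, mu in enumerate(neg_levels):
        probes[f"N{i:04d}"] = 2.0 ** rng.normal(mu, sd, beads)
    return BeadArray(sample_id, probes,
                     frozenset(f"N{i:04d}" for i in range(len(neg_levels))))


class TestProcessBeadArray:
    def test_null_arrays_presence_rate_near_alpha(self):
        # probes drawn from the negative-control distribution: the presence
        # fraction should match the nominal detection level.  All probes of
        # one array share the same negative-control reference, so the
        # per-array fraction fluctuates beyond binomial noise; the mean over
        # arrays is the calibrated quantity.
        rng = np.random.default_rng(21)
        n_probes, n_arrays = 1000, 10
        fracs = []
        for i in range(n_arrays):
            arr = _array_from_levels(f"null{i}", [7.0] * n_probes,
                                     [7.0] * 100, 20, rng)
            calls = process_bead_array(arr)
            genes = [p for p in calls.index if p.startswith("G")]
            fracs.append(calls.loc[genes, "present"].mean())
        assert 0.035 < np.mean(fracs) < 0.065
        assert all(f < 0.15 for f in fracs)

    def test_matches_scalar_operations(self):
        rng = np.random.default_rng(3)
        arr = _array_from_levels("s", [9.0, 7.0, 8.0], [7.0] * 10, 15, rng)
        calls = process_bead_array(arr)
        neg_means = [summarize_probe(remove_bead_outliers(arr.beads[p])[0])
                     for p in sorted(arr.negative_control_ids)]
        for probe in ["G0000", "G0001", "G0002"]:
            retained, removed = remove_bead_outliers(arr.beads[probe])
            assert calls.at[probe, "n_beads_retained"] == len(retained)
            assert calls.at[probe, "n_beads_removed"] == len(removed)
            mean = summarize_probe(retained)
            assert calls.at[probe, "mean_intensity"] == pytest.approx(mean)
            p_exp, present_exp = beadproc.detection_call_summary(mean,
                                                                 neg_means)
            assert calls.at[probe, "detection_p"] == pytest.approx(
                p_exp, rel=1e-9)
            assert calls.at[probe, "present"] == present_exp


class TestBuildExpressionMatrix:
    def test_single_array_passthrough(self):
        rng = np.random.default_rng(1)
        arr = _array_from_levels("only", [9.0, 8.0], [7.0] * 5, 10, rng)
        meta = pd.DataFrame({"sample_id": ["only"], "subject_id": ["only"],
                             "group": ["control"], "timepoint": ["baseline"],
                             "treated": [0], "crp": [1.0]})
        m = build_expression_matrix([arr], meta)
        assert m.values.shape == (2, 1)
        calls = process_bead_array(arr)
        assert np.allclose(m.values["only"].to_numpy(),
                           calls.loc[["G0000", "G0001"],
                                     "mean_intensity"].to_numpy())

    def test_union_rule_assessed_set(self, small_matrix, baseline_groups):
        active = small_matrix.group_active(baseline_groups)
        assessed = small_matrix.assessed_probes(baseline_groups)
        only_one_group = active.index[active.sum(axis=1) == 1]
        assert set(only_one_group) <= set(assessed)
        assert set(assessed) == set(active.index[active.any(axis=1)])

    def test_probe_universe_mismatch_errors(self):
        rng = np.random.default_rng(2)
        a = _array_from_levels("a", [9.0, 8.0], [7.0] * 4, 8, rng)
        b = _array_from_levels("b", [9.0], [7.0] * 4, 8, rng)
        meta = pd.DataFrame({"sample_id": ["a", "b"], "subject_id": ["a", "b"],
                             "group": ["control"] * 2,
                             "timepoint": ["baseline"] * 2,
                             "treated": [0, 0], "crp": [1.0, 1.0]})
        with pytest.raises(ValueError, match="G0001"):
            build_expression_matrix([a, b], meta)

    def test_assessed_fraction_tracks_expressed_fraction(self, small_cohort,
                                                         small_matrix,
                                                         baseline_groups):
        _, _, truth = small_cohort
        assessed = small_matrix.assessed_probes(baseline_groups)
        frac = len(assessed) / small_matrix.values.shape[0]
        expected = len(truth.expressed_gene_ids) / small_matrix.values.shape[0]
        assert abs(frac - expected) < 0.1
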