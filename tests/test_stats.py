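"""Performance statistics: 2x2 points, exact CIs, PPV/accuracy, chi-squared."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from serodx.calling import CallResult
from serodx.stats import (
    OperatingPoint,
    PrevalenceScenario,
    StatsError,
    accuracy,
    binomial_ci,
    compare_proportions,
    one_in_n,
    operating_point,
    ppv,
    present_percent,
    reduction_in_false_positives,
    round_half_up,
    subgroup_table,
)


def make_calls(tp, fn, fp, tn):
    calls, truth = [], {}
    for label, count, positive, diseased in (
        ("tp", tp, True, True), ("fn", fn, False, True),
        ("fp", fp, True, False), ("tn", tn, False, False),
    ):
        for i in range(count):
            sid = f"{label}{i}"
            calls.append(CallResult(subject_id=sid, per_antigen={}, panel_positive=positive))
            truth[sid] = diseased
    return calls, truth


class TestOperatingPoint:
    @pytest.mark.parametrize(
        "tp, fn, fp, tn, sens, spec",
        [
            (10, 15, 135, 616, 40, 82),  # six-assay audit table
            (9, 10, 78, 739, 47, 90),    # seven-assay audit table
        ],
    )
    def test_audit_tables(self, tp, fn, fp, tn, sens, spec):
        point = operating_point(*make_calls(tp, fn, fp, tn))
        assert present_percent(point.sensitivity) == sens
        assert present_percent(point.specificity) == spec

    def test_positive_test_cancer_fraction(self):
        point = operating_point(*make_calls(9, 10, 78, 739))
        assert round_half_up(point.positive_cancer_fraction, 1) == 10.3

    def test_all_negative_calls(self):
        point = operating_point(*make_calls(0, 5, 0, 10))
        assert point.sensitivity == 0.0 and point.specificity == 100.0

    def test_counts_sum_to_cohort(self):
        calls, truth = make_calls(3, 4, 5, 6)
        point = operating_point(calls, truth)
        assert point.tp + point.fn + point.fp + point.tn == len(calls)

    def test_missing_truth_rejected(self):
        calls, truth = make_calls(1, 1, 1, 1)
        del truth["tp0"]
        with pytest.raises(StatsError, match="tp0"):
            operating_point(calls, truth)

    def test_ci_bounds_contain_point_estimate(self):
        point = operating_point(*make_calls(9, 10, 78, 739))
        low, high = point.sensitivity_ci
        assert low <= point.sensitivity <= high


class TestBinomialCI:
    @pytest.mark.parametrize(
        "k, n, low, high",
        [
            (9, 53, 8, 30),    # small-cell p53 positivity row
            (31, 235, 9, 18),  # all-cancer p53 positivity row
        ],
    )
    def test_whole_percent_bounds(self, k, n, low, high):
        bounds = binomial_ci(k, n)
        assert tuple(present_percent(x) for x in bounds) == (low, high)

    def test_matches_direct_binomial_cdf_inversion(self):
        # Independent oracle: bisection on the binomial tail probabilities.
        from scipy.optimize import brentq

        for k, n in ((9, 53), (31, 235), (1, 10), (199, 200)):
            low, high = binomial_ci(k, n)
            oracle_low = brentq(lambda p: sps.binom.sf(k - 1, n, p) - 0.025, 1e-12, 1 - 1e-12)
            oracle_high = brentq(lambda p: sps.binom.cdf(k, n, p) - 0.025, 1e-12, 1 - 1e-12)
            assert low == pytest.approx(100 * oracle_low, abs=1e-6)
            assert high == pytest.approx(100 * oracle_high, abs=1e-6)

    def test_zero_successes_has_zero_lower_bound(self):
        low, high = binomial_ci(0, 10)
        assert low == 0.0 and high > 0.0

    def test_width_shrinks_with_n_at_fixed_rate(self):
        widths = [np.subtract(*reversed(binomial_ci(k, 10 * k))) for k in (2, 8, 32, 128)]
        assert all(b < a for a, b in zip(widths, widths[1:]))

    def test_invalid_counts_rejected(self):
        with pytest.raises(StatsError):
            binomial_ci(5, 4)


class TestPrevalenceScenarios:
    @pytest.mark.parametrize(
        "s, sp, pi, ppv_pct, n",
        [
            (0.41, 0.93, 0.024, 13, 8),
            (0.41, 0.93, 0.013, 7, 14),
            (0.39, 0.90, 0.024, 9, 11),
            (0.47, 0.90, 0.024, 10, 10),
            (0.40, 0.82, 0.031, 7, 15),
        ],
    )
    def test_ppv_and_one_in_n(self, s, sp, pi, ppv_pct, n):
        value = ppv(PrevalenceScenario(prevalence=pi, sensitivity=s, specificity=sp))
        assert present_percent(value) == ppv_pct
        assert one_in_n(value) == n

    def test_perfect_test(self):
        scenario = PrevalenceScenario(prevalence=0.024, sensitivity=1.0, specificity=1.0)
        assert ppv(scenario) == 100.0
        assert accuracy(scenario) == pytest.approx(100.0)

    @pytest.mark.parametrize(
        "s, sp, pi, expected",
        [(0.41, 0.93, 0.024, 92), (0.39, 0.90, 0.024, 89)],
    )
    def test_accuracy(self, s, sp, pi, expected):
        assert present_percent(accuracy(PrevalenceScenario(pi, s, sp))) == expected

    @settings(derandomize=True, max_examples=200)
    @given(
        s=st.floats(0.05, 0.95), sp=st.floats(0.05, 0.95),
        pi=st.floats(0.005, 0.2), bump=st.floats(0.01, 0.04),
    )
    def test_ppv_strictly_increasing_in_each_argument(self, s, sp, pi, bump):
        base = ppv(PrevalenceScenario(pi, s, sp))
        assert ppv(PrevalenceScenario(pi + bump, s, sp)) > base
        assert ppv(PrevalenceScenario(pi, s + bump, sp)) > base
        assert ppv(PrevalenceScenario(pi, s, sp + bump)) > base


class TestCompareProportions:
    def test_specificity_comparison_is_highly_significant(self):
        result = compare_proportions(135, 751, 78, 817)
        assert result["p"] < 1e-4

    def test_sensitivity_comparison_is_not_significant(self):
        result = compare_proportions(10, 25, 9, 19)
        assert result["p"] == pytest.approx(0.63, abs=0.01)

    def test_identical_proportions(self):
        result = compare_proportions(7, 20, 7, 20)
        assert result["chi2"] == pytest.approx(0.0)
        assert result["p"] == pytest.approx(1.0)

    def test_matches_expected_count_oracle(self):
        # Pearson statistic recomputed from first principles.
        for k1, n1, k2, n2 in ((10, 25, 9, 19), (135, 751, 78, 817), (3, 11, 8, 13)):
            observed = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
            expected = np.outer(observed.sum(1), observed.sum(0)) / observed.sum()
            chi2 = ((observed - expected) ** 2 / expected).sum()
            result = compare_proportions(k1, n1, k2, n2)
            assert result["chi2"] == pytest.approx(chi2)
            assert result["p"] == pytest.approx(sps.chi2.sf(chi2, 1))

    def test_empty_margin_rejected(self):
        with pytest.raises(StatsError, match="margin"):
            compare_proportions(0, 10, 0, 12)


class TestSubgroupTable:
    def test_single_group_equals_overall(self):
        calls, truth = make_calls(29, 24, 5, 95)
        grouping = {sid: "all" for sid in truth}
        table = subgroup_table(calls, truth, grouping).set_index("group")
        assert table.loc["all", "n"] == 53
        assert table.loc["all", "k"] == 29
        assert (table.loc["all"] == table.loc["overall"]).all()

    def test_row_matches_binomial_ci(self):
        calls, truth = make_calls(29, 24, 0, 1)
        table = subgroup_table(calls, truth, {sid: "SCLC" for sid in truth}).set_index("group")
        low, high = binomial_ci(29, 53)
        assert table.loc["SCLC", "ci_low"] == pytest.approx(low)
        assert table.loc["SCLC", "ci_high"] == pytest.approx(high)

    def test_empty_subgroup_flagged_without_ci(self):
        calls, truth = make_calls(2, 2, 1, 1)
        grouping = {sid: "present" for sid in truth}
        grouping["ghost-subject"] = "absent"
        table = subgroup_table(calls, truth, grouping).set_index("group")
        assert table.loc["absent", "n"] == 0
        assert math.isnan(table.loc["absent", "ci_low"])

    def test_equal_signal_subgroups_have_overlapping_intervals(self, default_cohort, true_panel7):
        from serodx.calling import call_panel
        from serodx.optimize import label_truth

        truth = label_truth(default_cohort)
        grouping = {s.subject_id: s.stage_group for s in default_cohort.subjects
                    if s.cohort == "cancer"}
        table = subgroup_table(call_panel(default_cohort, true_panel7), truth, grouping)
        rows = table[table["group"].isin(["early", "late"])]
        assert len(rows) == 2
        (low_a, high_a), (low_b, high_b) = rows[["ci_low", "ci_high"]].to_numpy()
        assert low_a <= high_b and low_b <= high_a  # intervals overlap


class TestFalsePositiveReduction:
    @pytest.mark.parametrize("old, new, expected", [(90, 93, 30), (82, 90, 44), (75, 75, 0)])
    def test_reduction_examples(self, old, new, expected):
        assert present_percent(reduction_in_false_positives(old, new)) == expected

    def test_undefined_at_perfect_specificity(self):
        with pytest.raises(StatsError, match="undefined"):
            reduction_in_false_positives(100, 99)


@settings(derandomize=True, max_examples=100)
@given(st.integers(0, 500), st.integers(1, 500))
def test_clopper_pearson_covers_point_estimate(k, n):
    k = min(k, n)
    low, high = binomial_ci(k, n)
    assert low <= 100.0 * k / n <= high


def test_half_up_rounding_convention():
    assert present_percent(8.75) == 9 and present_percent(12.5) == 13
    assert round_half_up(0.625, 2) == 0.63
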