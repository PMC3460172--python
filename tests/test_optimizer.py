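"""Monte-Carlo cutoff search: oracles, determinism, occult adjustment."""

import itertools
import math

import numpy as np
import pytest

from serodx.calling import CallResult, _panel_matrices, call_panel
from serodx.cohort import PANEL7_ANTIGENS, PanelDefinition
from serodx.optimize import (
    SearchConfig,
    SearchError,
    adjusted_specificity,
    label_truth,
    mc_search,
    validate_cutoffs,
)
from serodx.simulate import CohortSimConfig, generate_cohort
from serodx.stats import operating_point


def exhaustive_search(ru_cancer, ru_control, grids, mode, target, tolerance):
    """Enumerate every cutoff combination with the search's own tie-break."""
    best = None
    for combo in itertools.product(*grids):
        c = np.asarray(combo)
        sens = 100.0 * (ru_cancer > c).any(axis=1).mean()
        spec = 100.0 * (1.0 - (ru_control > c).any(axis=1).mean())
        constrained, free = (spec, sens) if mode == "fix_specificity" else (sens, spec)
        if abs(constrained - target) > tolerance:
            continue
        item = (free, constrained, combo)
        if best is None or (item[0], item[1]) > (best[0], best[1]):
            best = item
        elif (item[0], item[1]) == (best[0], best[1]) and combo < best[2]:
            best = item
    return best


@pytest.fixture(scope="module")
def search_cohort():
    return generate_cohort(CohortSimConfig(n_cancer=150, n_control=250, occult_rate=0.0, seed=5))


def ru_matrices(cohort, antigens):
    ru, _ = _panel_matrices(cohort, antigens, 0.8)
    truth = label_truth(cohort)
    is_cancer = np.array([truth[sid] for sid in cohort.subject_ids()])
    return ru[is_cancer], ru[~is_cancer]


def test_single_antigen_reduces_to_control_quantile(search_cohort):
    antigens = ("MAGEA4",)
    config = SearchConfig(mode="fix_specificity", target=90.0, tolerance=0.5,
                          n_candidates=5000, seed=3, dose_response_required=False)
    result = mc_search(search_cohort, antigens, config)
    ru_cancer, ru_control = ru_matrices(search_cohort, antigens)
    # Direct quantile oracle: the sensitivity-maximizing feasible cutoff is
    # the lowest grid point whose specificity lands in the band, i.e. the
    # empirical 90th percentile of control RU (strict-> convention).
    grid = np.percentile(ru_control[:, 0], np.arange(80.0, 100.0, 0.1))
    oracle = exhaustive_search(ru_cancer, ru_control, [grid], "fix_specificity", 90.0, 0.5)
    assert result.best_cutoffs["MAGEA4"] == pytest.approx(oracle[2][0])
    spec_at_quantile = 100.0 * (ru_control[:, 0] <= np.percentile(ru_control[:, 0], 90)).mean()
    assert abs(result.achieved.specificity - spec_at_quantile) <= 0.5


def test_small_grid_matches_exhaustive_enumeration(search_cohort):
    antigens = ("p53", "NY-ESO-1", "MAGEA4")
    ru_cancer, ru_control = ru_matrices(search_cohort, antigens)
    grids = {
        a: np.percentile(ru_control[:, j], [85, 90, 95, 98, 99.5])
        for j, a in enumerate(antigens)
    }
    config = SearchConfig(mode="fix_specificity", target=90.0, tolerance=2.0,
                          n_candidates=10_000, seed=11, candidate_grid=grids,
                          dose_response_required=False)
    result = mc_search(search_cohort, antigens, config)
    oracle = exhaustive_search(ru_cancer, ru_control, [grids[a] for a in antigens],
                               "fix_specificity", 90.0, 2.0)
    assert oracle is not None
    assert tuple(result.best_cutoffs[a] for a in antigens) == pytest.approx(oracle[2])
    assert result.achieved.sensitivity == pytest.approx(oracle[0])


def test_search_is_deterministic(search_cohort):
    config = SearchConfig(mode="fix_sensitivity", target=40.0, tolerance=2.0,
                          n_candidates=2000, seed=21)
    a = mc_search(search_cohort, PANEL7_ANTIGENS, config)
    b = mc_search(search_cohort, PANEL7_ANTIGENS, config)
    assert a.best_cutoffs == b.best_cutoffs
    assert a.achieved == b.achieved
    assert a.n_feasible == b.n_feasible


def test_infeasible_target_reports_nearest_miss(search_cohort):
    config = SearchConfig(mode="fix_sensitivity", target=99.5, tolerance=0.1,
                          n_candidates=500, seed=2)
    with pytest.raises(SearchError, match="nearest miss"):
        mc_search(search_cohort, PANEL7_ANTIGENS, config)


def test_achieved_point_is_recomputable_from_cutoffs(search_cohort):
    config = SearchConfig(mode="fix_specificity", target=90.0, tolerance=1.0,
                          n_candidates=3000, seed=13)
    result = mc_search(search_cohort, PANEL7_ANTIGENS, config)
    panel = PanelDefinition("check", PANEL7_ANTIGENS, result.best_cutoffs)
    again = validate_cutoffs(search_cohort, panel)
    assert (again.tp, again.fn, again.fp, again.tn) == (
        result.achieved.tp, result.achieved.fn, result.achieved.fp, result.achieved.tn)


def test_raising_all_cutoffs_weakly_lowers_sensitivity_and_false_positives(search_cohort):
    truth = label_truth(search_cohort)
    cutoffs = CohortSimConfig().true_cutoffs()
    panel_7 = {a: cutoffs[a] for a in PANEL7_ANTIGENS}
    previous = None
    for scale in (0.5, 1.0, 2.0, 4.0):
        panel = PanelDefinition("s", PANEL7_ANTIGENS, {a: c * scale for a, c in panel_7.items()})
        point = operating_point(call_panel(search_cohort, panel), truth)
        if previous is not None:
            assert point.sensitivity <= previous.sensitivity
            assert point.fp <= previous.fp
        previous = point


def test_degenerate_panel_with_unreachable_cutoffs(search_cohort):
    panel = PanelDefinition("inf", PANEL7_ANTIGENS, {a: math.inf for a in PANEL7_ANTIGENS})
    point = validate_cutoffs(search_cohort, panel)
    assert point.sensitivity == 0.0 and point.specificity == 100.0


def test_overlapping_validation_cohort_warns(search_cohort):
    panel = PanelDefinition("inf", PANEL7_ANTIGENS, {a: math.inf for a in PANEL7_ANTIGENS})
    with pytest.warns(UserWarning, match="overlap"):
        validate_cutoffs(search_cohort, panel, search_subject_ids=search_cohort.subject_ids())


class TestAdjustedSpecificity:
    @staticmethod
    def calls(n, n_positive):
        return [
            CallResult(subject_id=f"N{i}", per_antigen={}, panel_positive=i < n_positive)
            for i in range(n)
        ]

    def test_stated_arithmetic_example(self):
        value = adjusted_specificity(self.calls(266, 24), [0.027] * 266, 0.41)
        expected = 100.0 * (1.0 - (24 - 0.41 * 266 * 0.027) / (266 - 266 * 0.027))
        assert value == pytest.approx(expected)
        assert value == pytest.approx(91.86, abs=0.01)

    def test_zero_risk_is_identity(self):
        calls = self.calls(100, 12)
        assert adjusted_specificity(calls, [0.0] * 100, 0.5) == pytest.approx(88.0)

    def test_zero_sensitivity_can_lower_specificity(self):
        calls = self.calls(100, 12)
        value = adjusted_specificity(calls, [0.05] * 100, 0.0)
        assert value == pytest.approx(100.0 * (1.0 - 12 / 95.0))
        assert value < 88.0

    def test_strictly_increasing_in_sensitivity_while_fp_remain(self):
        calls = self.calls(200, 30)
        risks = [0.04] * 200
        values = [adjusted_specificity(calls, risks, s) for s in np.linspace(0.0, 1.0, 11)]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_expected_occult_exceeding_population_rejected(self):
        with pytest.raises(SearchError, match="exceed"):
            adjusted_specificity(self.calls(4, 1), [1.0] * 4, 0.5)
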