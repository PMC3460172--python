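"""Diagnostic performance statistics.

2x2 operating points with exact Clopper-Pearson intervals, prevalence-based
positive predictive value and accuracy, two-proportion Pearson chi-squared
tests (no continuity correction), subgroup sensitivity tables for forest
plots, and false-positive reduction arithmetic.

All internal math is full precision; presentation rounding is half-up to
whole percent and applied only in the reporting helpers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats as sps

from serodx.calling import CallResult


class StatsError(ValueError):
    pass


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Half-up rounding (0.5 always rounds away from zero toward +inf)."""
    scale = 10.0**ndigits
    return math.floor(x * scale + 0.5) / scale


def present_percent(x: float) -> int:
    """Whole-percent presentation value."""
    return int(round_half_up(x))


def binomial_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval, in percent."""
    if n < 1 or not 0 <= k <= n:
        raise StatsError(f"invalid binomial counts k={k}, n={n}")
    alpha = 1.0 - level
    lower = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2.0, k, n - k + 1))
    upper = 1.0 if k == n else float(sps.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return 100.0 * lower, 100.0 * upper


@dataclass(frozen=True)
class OperatingPoint:
    """A 2x2 diagnostic table with derived rates and exact 95% CIs."""

    tp: int
    fn: int
    fp: int
    tn: int
    adjusted_specificity: float | None = None

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise StatsError("2x2 counts must be non-negative")
        if self.tp + self.fn == 0 or self.fp + self.tn == 0:
            raise StatsError("operating point needs at least one diseased and one non-diseased subject")

    @property
    def n_diseased(self) -> int:
        return self.tp + self.fn

    @property
    def n_non_diseased(self) -> int:
        return self.fp + self.tn

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / self.n_diseased

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / self.n_non_diseased

    @property
    def sensitivity_ci(self) -> tuple[float, float]:
        return binomial_ci(self.tp, self.n_diseased)

    @property
    def specificity_ci(self) -> tuple[float, float]:
        return binomial_ci(self.tn, self.n_non_diseased)

    @property
    def positive_cancer_fraction(self) -> float:
        """Percent of test positives with confirmed disease (in-sample PPV)."""
        if self.tp + self.fp == 0:
            raise StatsError("no test positives")
        return 100.0 * self.tp / (self.tp + self.fp)

    def presentation(self) -> dict:
        out = {
            "tp": self.tp,
            "fn": self.fn,
            "fp": self.fp,
            "tn": self.tn,
            "sensitivity": present_percent(self.sensitivity),
            "sensitivity_ci": tuple(present_percent(x) for x in self.sensitivity_ci),
            "specificity": present_percent(self.specificity),
            "specificity_ci": tuple(present_percent(x) for x in self.specificity_ci),
        }
        if self.adjusted_specificity is not None:
            out["adjusted_specificity"] = present_percent(self.adjusted_specificity)
        return out


def _truth_positive(value) -> bool:
    if isinstance(value, bool):
        return value
    if value in ("cancer", "confirmed", 1):
        return True
    if value in ("none", 0):
        return False
    raise StatsError(f"unrecognized truth label {value!r}")


def operating_point(calls: Sequence[CallResult], truth: Mapping[str, object]) -> OperatingPoint:
    """Exact 2x2 counts from panel calls against a truth mapping."""
    tp = fn = fp = tn = 0
    for call in calls:
        if call.subject_id not in truth:
            raise StatsError(f"subject {call.subject_id!r} has no truth label")
        diseased = _truth_positive(truth[call.subject_id])
        if diseased:
            tp += call.panel_positive
            fn += not call.panel_positive
        else:
            fp += call.panel_positive
            tn += not call.panel_positive
    return OperatingPoint(tp=int(tp), fn=int(fn), fp=int(fp), tn=int(tn))


@dataclass(frozen=True)
class PrevalenceScenario:
    """Sensitivity/specificity applied at an assumed disease prevalence."""

    prevalence: float
    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise StatsError("prevalence must be in (0, 1)")
        for name in ("sensitivity", "specificity"):
            if not 0.0 < getattr(self, name) <= 1.0:
                raise StatsError(f"{name} must be in (0, 1]")


def ppv(scenario: PrevalenceScenario) -> float:
    """Positive predictive value, percent, via Bayes' rule."""
    s, sp, pi = scenario.sensitivity, scenario.specificity, scenario.prevalence
    return 100.0 * s * pi / (s * pi + (1.0 - sp) * (1.0 - pi))


def one_in_n(ppv_percent: float) -> int:
    """Express a PPV as 'one positive in N is a cancer' (nearest integer)."""
    if ppv_percent <= 0:
        raise StatsError("one_in_n undefined for PPV <= 0")
    return int(round_half_up(100.0 / ppv_percent))


def accuracy(scenario: PrevalenceScenario) -> float:
    """Prevalence-weighted percent of correct classifications."""
    s, sp, pi = scenario.sensitivity, scenario.specificity, scenario.prevalence
    return 100.0 * (s * pi + sp * (1.0 - pi))


def compare_proportions(k1: int, n1: int, k2: int, n2: int) -> dict[str, float]:
    """Pearson chi-squared (no continuity correction) on k1/n1 vs k2/n2."""
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1 or not 0 <= k <= n:
            raise StatsError(f"invalid counts k={k}, n={n}")
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    if k1 + k2 == 0 or (n1 - k1) + (n2 - k2) == 0:
        raise StatsError("chi-squared undefined: a column margin is empty")
    result = sps.chi2_contingency(table, correction=False)
    return {"chi2": float(result.statistic), "p": float(result.pvalue)}


def subgroup_table(
    calls: Sequence[CallResult],
    truth: Mapping[str, object],
    grouping: Mapping[str, str],
) -> pd.DataFrame:
    """Per-subgroup sensitivity with exact CIs (forest-plot table).

    Rows cover diseased subjects only, one per subgroup label plus an
    "overall" row.  Empty subgroups get n=0 and no interval.
    """
    positives: dict[str, int] = {}
    totals: dict[str, int] = {}
    overall_k = overall_n = 0
    for call in calls:
        if call.subject_id not in truth:
            raise StatsError(f"subject {call.subject_id!r} has no truth label")
        if not _truth_positive(truth[call.subject_id]):
            continue
        group = grouping.get(call.subject_id, "ungrouped")
        totals[group] = totals.get(group, 0) + 1
        positives[group] = positives.get(group, 0) + int(call.panel_positive)
        overall_n += 1
        overall_k += int(call.panel_positive)
    rows = []
    labels = sorted(set(grouping.values()) | set(totals))
    for group in labels + ["overall"]:
        k = overall_k if group == "overall" else positives.get(group, 0)
        n = overall_n if group == "overall" else totals.get(group, 0)
        if n == 0:
            rows.append({"group": group, "n": 0, "k": 0, "sensitivity": math.nan,
                         "ci_low": math.nan, "ci_high": math.nan})
            continue
        low, high = binomial_ci(k, n)
        rows.append({"group": group, "n": n, "k": k, "sensitivity": 100.0 * k / n,
                     "ci_low": low, "ci_high": high})
    return pd.DataFrame(rows, columns=["group", "n", "k", "sensitivity", "ci_low", "ci_high"])


def reduction_in_false_positives(spec_old: float, spec_new: float) -> float:
    """Percent reduction in the false-positive rate between two specificities.

    Inputs are specificities in percent at presentation precision.
    """
    if not (0.0 <= spec_old <= 100.0 and 0.0 <= spec_new <= 100.0):
        raise StatsError("specificities must be in [0, 100]")
    if spec_old == 100.0:
        raise StatsError("false-positive reduction undefined at specificity 100%")
    return 100.0 * ((100.0 - spec_old) - (100.0 - spec_new)) / (100.0 - spec_old)
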