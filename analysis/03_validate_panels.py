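#!/usr/bin/env python
"""Held-out validation of the optimized panels.

Evaluates both optimized panels on an independent synthetic case--control
cohort: operating points with exact CIs (occult-adjusted specificity for the
seven-assay panel), the two-panel chi-squared comparison, SOX2-B/SOX2-N
substitution concordance, and a subgroup (forest-plot) sensitivity table.
"""

import json
from pathlib import Path

from serodx.calling import call_panel, concordance
from serodx.cohort import read_cohort, read_panel
from serodx.optimize import label_truth, validate_cutoffs
from serodx.risk import default_risk_config
from serodx.stats import compare_proportions, subgroup_table

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cohorts"
RESULTS = ROOT / "results"


def main() -> None:
    cohort = read_cohort(SCRATCH / "optimization_heldout_subjects.csv",
                         SCRATCH / "optimization_heldout_measurements.csv")
    panel6 = read_panel(RESULTS / "panel6_fix_specificity90.yaml")
    panel7 = read_panel(RESULTS / "panel7_fix_sensitivity40_adjusted.yaml")

    point6 = validate_cutoffs(cohort, panel6)
    point7 = validate_cutoffs(cohort, panel7, adjust_occult=True,
                              risk_config=default_risk_config())
    report = {
        "panel6_held_out": point6.presentation(),
        "panel7_held_out": point7.presentation(),
        "sensitivity_comparison": compare_proportions(
            point6.tp, point6.n_diseased, point7.tp, point7.n_diseased),
        "false_positive_comparison": compare_proportions(
            point6.fp, point6.n_non_diseased, point7.fp, point7.n_non_diseased),
    }
    print("panel6 held-out:", point6.presentation())
    print("panel7 held-out:", point7.presentation())

    # SOX2 substitution: swap SOX2-B for SOX2-N at the same cutoff.
    swapped_antigens = tuple("SOX2-N" if a == "SOX2-B" else a for a in panel7.antigens)
    swapped_cutoffs = {("SOX2-N" if a == "SOX2-B" else a): c for a, c in panel7.cutoffs.items()}
    swapped = type(panel7)(name="panel7_sox2n", antigens=swapped_antigens,
                           cutoffs=swapped_cutoffs,
                           dose_response_required=panel7.dose_response_required)
    calls_b = call_panel(cohort, panel7)
    calls_n = call_panel(cohort, swapped)
    report["sox2_substitution_concordance_pct"] = round(concordance(calls_b, calls_n), 1)
    print("SOX2-B vs SOX2-N concordance:", report["sox2_substitution_concordance_pct"], "%")

    # Subgroup sensitivity table for the seven-assay panel.
    truth = label_truth(cohort)
    grouping = {s.subject_id: f"{s.subtype}/{s.stage_group}"
                for s in cohort.subjects if s.cohort == "cancer"}
    table = subgroup_table(calls_b, truth, grouping)
    table.to_csv(RESULTS / "forest_table.csv", index=False)
    print(table.to_string(index=False))

    (RESULTS / "validation.json").write_text(json.dumps(report, indent=2) + "\n")
    print(f"wrote {RESULTS / 'validation.json'} and {RESULTS / 'forest_table.csv'}")


if __name__ == "__main__":
    main()
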