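#!/usr/bin/env python
"""Predictive value and accuracy under screening prevalence scenarios.

Translates the held-out operating points (and, for reference, the published
ones) into PPV, "1 in N", and accuracy at high-risk (2.4%) and lower (1.3%)
lung-cancer prevalences, plus the false-positive reduction from the
six-assay to the seven-assay panel.
"""

import json
from pathlib import Path

from serodx.stats import (
    PrevalenceScenario,
    accuracy,
    one_in_n,
    ppv,
    present_percent,
    reduction_in_false_positives,
)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def scenario_block(sensitivity_pct: float, specificity_pct: float, prevalences) -> list[dict]:
    rows = []
    for pi in prevalences:
        scenario = PrevalenceScenario(prevalence=pi, sensitivity=sensitivity_pct / 100.0,
                                      specificity=specificity_pct / 100.0)
        value = ppv(scenario)
        rows.append({
            "prevalence_pct": round(100 * pi, 1),
            "ppv_pct": present_percent(value),
            "one_in_n": one_in_n(value),
            "accuracy_pct": present_percent(accuracy(scenario)),
        })
    return rows


def main() -> None:
    validation = json.loads((RESULTS / "validation.json").read_text())
    p6 = validation["panel6_held_out"]
    p7 = validation["panel7_held_out"]
    spec7 = p7.get("adjusted_specificity", p7["specificity"])

    report = {
        "held_out_panel6": scenario_block(p6["sensitivity"], p6["specificity"], (0.024, 0.013)),
        "held_out_panel7": scenario_block(p7["sensitivity"], spec7, (0.024, 0.013)),
        "held_out_fp_reduction_pct": present_percent(
            reduction_in_false_positives(p6["specificity"], spec7)),
        "published_panel6": scenario_block(39, 90, (0.024,)),
        "published_panel7": scenario_block(41, 93, (0.024, 0.013)),
        "published_fp_reduction_pct": present_percent(reduction_in_false_positives(90, 93)),
    }
    for key in ("held_out_panel6", "held_out_panel7", "published_panel6", "published_panel7"):
        for row in report[key]:
            print(f"{key} @ {row['prevalence_pct']}%: PPV {row['ppv_pct']}% "
                  f"(1 in {row['one_in_n']}), accuracy {row['accuracy_pct']}%")
    print("held-out FP reduction:", report["held_out_fp_reduction_pct"], "%")

    (RESULTS / "predictive_value.json").write_text(json.dumps(report, indent=2) + "\n")
    print(f"wrote {RESULTS / 'predictive_value.json'}")


if __name__ == "__main__":
    main()
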