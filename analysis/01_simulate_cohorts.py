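#!/usr/bin/env python
"""Generate the synthetic study populations.

Builds a case--control "optimization" cohort (235 cancers, 266 matched
controls) and a prospective-style "audit" cohort (836 at-risk subjects) with
the default demographic and serology structure, writes them under scratch/
(regenerable; not a deliverable), and records cohort summaries — counts,
occult burden, and the risk-model distribution — under results/.
"""

import json
from pathlib import Path

from serodx.cohort import write_cohort
from serodx.pipeline import write_truth_csv
from serodx.risk import cohort_risk_summary, default_risk_config
from serodx.simulate import CohortSimConfig, generate_cohort, truth_table

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cohorts"
RESULTS = ROOT / "results"

CONFIGS = {
    "optimization": CohortSimConfig(n_cancer=235, n_control=266, id_prefix="opt-", seed=2001),
    "optimization_heldout": CohortSimConfig(n_cancer=235, n_control=266, id_prefix="val-", seed=2010),
    "audit": CohortSimConfig(n_cancer=0, n_control=0, n_at_risk=836, id_prefix="aud-", seed=2003),
}


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    summary = {}
    for name, config in CONFIGS.items():
        cohort = generate_cohort(config)
        write_cohort(cohort, SCRATCH / f"{name}_subjects.csv", SCRATCH / f"{name}_measurements.csv")
        write_truth_csv(cohort, SCRATCH / f"{name}_truth.csv")
        truth = truth_table(cohort)
        occult = sum(
            truth[s.subject_id] == "cancer" and s.cohort != "cancer" for s in cohort.subjects
        )
        entry = {
            "n": len(cohort),
            "n_cancer_labelled": sum(s.cohort == "cancer" for s in cohort.subjects),
            "n_occult": occult,
            "seed": config.seed,
        }
        if any(s.smoking != "unknown" for s in cohort.subjects):
            entry["risk_summary_pct"] = {
                k: round(v, 2)
                for k, v in cohort_risk_summary(cohort, default_risk_config()).items()
            }
        summary[name] = entry
        print(f"{name}: {entry['n']} subjects, {occult} occult cancers seeded")

    (RESULTS / "cohort_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    print(f"wrote {RESULTS / 'cohort_summary.json'}")


if __name__ == "__main__":
    main()
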