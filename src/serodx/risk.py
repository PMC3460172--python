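"""Individual 5-year absolute lung-cancer risk from gender, age, and smoking.

The model is a configurable parametric family in the spirit of published
demographic risk models (Spitz-style):

    risk = min(cap, baseline(gender, age_band) * multiplier(smoking)
                     * exp(duration_coefficient * smoking_years))

The baseline is a step function over 5-year age bands (40-84, clamped
outside); smoking multipliers are ordered never <= ex <= current.  The
published coefficient sets for such models are not freely reusable, so the
default configuration here is an illustrative fixture chosen so that a
typical high-risk screening demographic mix yields mean 5-year risk in the
2-3% range; the 5-year horizon is a label on the configuration, not a
survival-analysis derivation.

These per-subject risks drive the occult-cancer adjustment of specificity:
summed over a control population they estimate the expected number of
undiagnosed cancers hiding among nominal negatives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from serodx.cohort import Cohort, CohortValidationError, SubjectRecord

AGE_BANDS = tuple(range(40, 85, 5))  # band lower edges: 40-44 ... 80-84


class RiskModelError(ValueError):
    pass


def _band(age: int) -> int:
    clamped = min(max(age, AGE_BANDS[0]), AGE_BANDS[-1] + 4)
    return AGE_BANDS[(clamped - AGE_BANDS[0]) // 5]


@dataclass(frozen=True)
class RiskModelConfig:
    """Parameters of the absolute-risk model.

    ``baseline[(gender, band_lower_edge)]`` is the 5-year absolute risk for a
    never-smoker in that band; ``smoking_multiplier`` maps smoking status to
    a relative factor; ``duration_coefficient`` is the per-year log-risk
    increment for years smoked; ``cap`` bounds the final risk.
    """

    baseline: Mapping[tuple[str, int], float]
    smoking_multiplier: Mapping[str, float] = field(
        default_factory=lambda: {"never": 1.0, "ex": 4.0, "current": 8.0}
    )
    duration_coefficient: float = 0.015
    cap: float = 0.12
    horizon_years: int = 5  # descriptive label only

    def __post_init__(self) -> None:
        object.__setattr__(self, "baseline", dict(self.baseline))
        object.__setattr__(self, "smoking_multiplier", dict(self.smoking_multiplier))
        for gender in ("male", "female"):
            previous = -1.0
            for band in AGE_BANDS:
                if (gender, band) not in self.baseline:
                    raise RiskModelError(f"baseline missing ({gender}, {band})")
                value = self.baseline[(gender, band)]
                if not 0.0 <= value <= 1.0:
                    raise RiskModelError(f"baseline[({gender}, {band})] must be in [0, 1]")
                if value < previous:
                    raise RiskModelError(f"baseline must be non-decreasing in age ({gender}, {band})")
                previous = value
        mult = self.smoking_multiplier
        if not 0.0 <= mult.get("never", -1.0) <= mult.get("ex", -1.0) <= mult.get("current", -1.0):
            raise RiskModelError("smoking multipliers must satisfy 0 <= never <= ex <= current")
        if not 0.0 < self.cap <= 1.0:
            raise RiskModelError("cap must be in (0, 1]")


def default_risk_config() -> RiskModelConfig:
    """Illustrative default configuration (see module docstring)."""
    male = {40: 0.0008, 45: 0.0012, 50: 0.0018, 55: 0.0024, 60: 0.0030, 65: 0.0038, 70: 0.0048, 75: 0.0058, 80: 0.0070}
    baseline = {("male", band): value for band, value in male.items()}
    baseline.update({("female", band): 0.75 * value for band, value in male.items()})
    return RiskModelConfig(baseline=baseline)


def read_risk_config(path) -> RiskModelConfig:
    """Load a risk configuration from YAML (baseline nested by gender)."""
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    baseline = {
        (gender, int(band)): float(value)
        for gender, bands in doc["baseline"].items()
        for band, value in bands.items()
    }
    return RiskModelConfig(
        baseline=baseline,
        smoking_multiplier={k: float(v) for k, v in doc.get(
            "smoking_multiplier", {"never": 1.0, "ex": 4.0, "current": 8.0}).items()},
        duration_coefficient=float(doc.get("duration_coefficient", 0.015)),
        cap=float(doc.get("cap", 0.12)),
    )


def write_risk_config(config: RiskModelConfig, path) -> None:
    import yaml

    baseline: dict[str, dict[int, float]] = {"male": {}, "female": {}}
    for (gender, band), value in config.baseline.items():
        baseline[gender][int(band)] = float(value)
    doc = {
        "baseline": baseline,
        "smoking_multiplier": dict(config.smoking_multiplier),
        "duration_coefficient": config.duration_coefficient,
        "cap": config.cap,
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def absolute_risk(subject: SubjectRecord, config: RiskModelConfig) -> float:
    """5-year absolute lung-cancer risk for one subject, in [0, 1].

    Deterministic in (gender, age, smoking history) only.  Subjects with
    unknown smoking status are not evaluable: callers must impute or exclude
    them (see :func:`cohort_risk_summary`, which excludes and reports).
    """
    if subject.smoking == "unknown":
        raise RiskModelError(
            f"subject {subject.subject_id}: smoking status unknown; impute or exclude before scoring"
        )
    base = config.baseline[(subject.gender, _band(subject.age))]
    multiplier = config.smoking_multiplier[subject.smoking]
    years = subject.smoking_years or 0.0
    return min(config.cap, base * multiplier * math.exp(config.duration_coefficient * years))


def _nearest_rank(sorted_values: list[float], pct: float) -> float:
    n = len(sorted_values)
    rank = max(1, math.ceil(pct / 100.0 * n))
    return sorted_values[rank - 1]


def cohort_risk_summary(cohort: Cohort, config: RiskModelConfig) -> dict[str, float]:
    """Distribution summary of per-subject risks, in percent.

    Evaluates every subject with known smoking status; returns mean, min,
    5th percentile, median, 95th percentile, max (nearest-rank percentiles)
    plus the evaluable count ``n`` and ``n_excluded``.
    """
    risks = sorted(
        absolute_risk(s, config) for s in cohort.subjects if s.smoking != "unknown"
    )
    n_excluded = len(cohort.subjects) - len(risks)
    if not risks:
        raise CohortValidationError("no evaluable subjects (all smoking statuses unknown)")
    return {
        "mean": 100.0 * sum(risks) / len(risks),
        "min": 100.0 * risks[0],
        "p5": 100.0 * _nearest_rank(risks, 5.0),
        "median": 100.0 * _nearest_rank(risks, 50.0),
        "p95": 100.0 * _nearest_rank(risks, 95.0),
        "max": 100.0 * risks[-1],
        "n": len(risks),
        "n_excluded": n_excluded,
    }
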