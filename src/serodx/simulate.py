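"""Synthetic serology cohort generator.

Emulates the statistical structure a case--control autoantibody study
assumes, so every downstream stage (calling, cutoff search, adjustment,
reporting) is testable without real sera:

* Per-antigen RU values follow a two-component log-normal mixture: a
  background component (seronegative) and an elevated component
  (seropositive) that stochastically dominates it.  Elevation prevalence is
  configurable per (population, antigen); defaults follow the printed
  per-antigen positivity percentages of the optimization case--control set.
* Between-antigen elevation is correlated through one shared latent Gaussian
  "immunogenicity" factor thresholded per antigen (a Gaussian copula on the
  elevation indicators), so panel-level positivity can fall below the
  independence closed form 1 - prod(1 - p_i) without moving the marginals.
* Elevated titration series decay geometrically from the reference coat
  level (dose response); background series are flat.  Both carry
  multiplicative log-normal noise at the non-reference levels.
* A configurable fraction of nominally disease-free subjects harbor occult
  cancer: they keep their "control"/"at_risk" label but draw antigen
  elevations at the cancer rates, and are flagged in the truth table.

Demographics are sampled independently of antigen status except through
occult status, mirroring the absence of any reported autoantibody-
demographic association.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats as sps

from serodx.cohort import (
    ANTIGENS,
    AntigenMeasurement,
    Cohort,
    CohortValidationError,
    SubjectRecord,
)

#: Default per-antigen elevation prevalence (fraction) for cancer subjects:
#: the printed all-lung-cancer per-antigen positivity of the optimization set.
DEFAULT_CANCER_RATES: dict[str, float] = {
    "AnnexinI": 0.00,
    "p53": 0.13,
    "CAGE": 0.09,
    "NY-ESO-1": 0.10,
    "GBU4-5": 0.03,
    "MAGEA4": 0.12,
    "SOX2-B": 0.04,
    "SOX2-N": 0.04,
    "HuD": 0.05,
}

#: Default per-antigen elevation prevalence for disease-free subjects: the
#: printed normal-population positivity (complement of per-antigen specificity).
DEFAULT_CONTROL_RATES: dict[str, float] = {
    "AnnexinI": 0.00,
    "p53": 0.03,
    "CAGE": 0.01,
    "NY-ESO-1": 0.02,
    "GBU4-5": 0.02,
    "MAGEA4": 0.04,
    "SOX2-B": 0.01,
    "SOX2-N": 0.01,
    "HuD": 0.01,
}


@dataclass(frozen=True)
class Demographics:
    """Age, gender, and smoking mix for one simulated population."""

    age_mean: float
    age_sd: float
    male_fraction: float
    smoking_mix: Mapping[str, float]  # keys: current, ex, never, unknown
    age_min: int = 40
    age_max: int = 90

    def __post_init__(self) -> None:
        mix = {k: float(self.smoking_mix.get(k, 0.0)) for k in ("current", "ex", "never", "unknown")}
        object.__setattr__(self, "smoking_mix", mix)
        if abs(sum(mix.values()) - 1.0) > 1e-6:
            raise CohortValidationError("smoking_mix must sum to 1")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise CohortValidationError("male_fraction must be in [0, 1]")


# Demographic defaults follow the printed cohort tables: the case--control
# optimization populations for cancer/control, the at-risk audit population
# (seven-assay series) for at_risk.
DEFAULT_DEMOGRAPHICS: dict[str, Demographics] = {
    "cancer": Demographics(64.8, 9.0, 0.73, {"current": 0.46, "ex": 0.29, "never": 0.10, "unknown": 0.15}),
    "control": Demographics(64.5, 9.0, 0.70, {"current": 0.35, "ex": 0.54, "never": 0.11, "unknown": 0.0}),
    "at_risk": Demographics(60.0, 11.0, 0.36, {"current": 0.434, "ex": 0.443, "never": 0.123, "unknown": 0.0}),
}


@dataclass(frozen=True)
class CohortSimConfig:
    """All generator parameters; the seed fully determines the output.

    ``antigen_rates[(population, antigen)]`` is the elevation prevalence for
    that antigen in that population, where population is "cancer" (true
    cancers, including occult) or "control" (truly disease-free).
    ``elevation_correlation`` is the share of the latent elevation variance
    carried by the common immunogenicity factor.  ``occult_rate`` is the
    fraction of control/at-risk subjects who truly harbor cancer, defaulting
    to the 2.7% prevalence-round figure for high-risk screening populations.
    ``titration_decay`` is the fractional RU drop per coat-level step below
    the reference level for elevated series.
    """

    n_cancer: int = 235
    n_control: int = 266
    n_at_risk: int = 0
    antigen_rates: Mapping[tuple[str, str], float] = field(default_factory=dict)
    elevation_correlation: float = 0.3
    background_ru: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    elevated_ru: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    occult_rate: float = 0.027
    demographics: Mapping[str, Demographics] = field(default_factory=dict)
    titration_decay: float = 0.4
    titration_noise_sd: float = 0.05
    n_coat_levels: int = 4
    id_prefix: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        rates = dict(self.antigen_rates)
        for antigen in ANTIGENS:
            rates.setdefault(("cancer", antigen), DEFAULT_CANCER_RATES[antigen])
            rates.setdefault(("control", antigen), DEFAULT_CONTROL_RATES[antigen])
        background = {a: tuple(map(float, self.background_ru.get(a, (0.0, 0.5)))) for a in ANTIGENS}
        elevated = {a: tuple(map(float, self.elevated_ru.get(a, (3.0, 0.5)))) for a in ANTIGENS}
        demographics = dict(DEFAULT_DEMOGRAPHICS, **dict(self.demographics))
        object.__setattr__(self, "antigen_rates", rates)
        object.__setattr__(self, "background_ru", background)
        object.__setattr__(self, "elevated_ru", elevated)
        object.__setattr__(self, "demographics", demographics)

        if min(self.n_cancer, self.n_control, self.n_at_risk) < 0:
            raise CohortValidationError("population counts must be >= 0")
        for key, p in rates.items():
            if not 0.0 <= p <= 1.0:
                raise CohortValidationError(f"antigen_rates[{key}] must be in [0, 1]")
            if key[0] not in ("cancer", "control"):
                raise CohortValidationError(f"antigen_rates population must be cancer/control, got {key[0]!r}")
        if not 0.0 <= self.elevation_correlation < 1.0:
            raise CohortValidationError("elevation_correlation must be in [0, 1)")
        if not 0.0 <= self.occult_rate <= 1.0:
            raise CohortValidationError("occult_rate must be in [0, 1]")
        if not 0.0 < self.titration_decay < 1.0:
            raise CohortValidationError("titration_decay must be in (0, 1)")
        if self.titration_noise_sd < 0:
            raise CohortValidationError("titration_noise_sd must be >= 0")
        if self.n_coat_levels < 3:
            raise CohortValidationError("n_coat_levels must be >= 3 (dose-response check needs 3 points)")
        for antigen in ANTIGENS:
            if elevated[antigen][0] <= background[antigen][0]:
                raise CohortValidationError(
                    f"elevated log-mean must exceed background log-mean for {antigen}"
                )

    def true_cutoffs(self) -> dict[str, float]:
        """Geometric-midpoint RU cutoff between the two mixture components.

        With well-separated components, per-antigen positivity at these
        cutoffs equals the configured elevation prevalence up to the small
        component overlap.
        """
        return {
            a: float(np.exp(0.5 * (self.background_ru[a][0] + self.elevated_ru[a][0])))
            for a in ANTIGENS
        }


def _sample_block(
    rng: np.random.Generator,
    config: CohortSimConfig,
    population: str,
    prefix: str,
    n: int,
) -> tuple[list[SubjectRecord], dict[tuple[str, str], AntigenMeasurement], dict[str, str]]:
    if n == 0:
        return [], {}, {}
    demo = config.demographics[population]
    antigens = ANTIGENS
    n_antigens = len(antigens)
    k = config.n_coat_levels

    ids = [f"{config.id_prefix}{prefix}{i:06d}" for i in range(1, n + 1)]
    if population == "cancer":
        occult = np.zeros(n, dtype=bool)
        true_cancer = np.ones(n, dtype=bool)
    else:
        occult = rng.random(n) < config.occult_rate
        true_cancer = occult

    # Elevation indicators via a single shared latent factor (Gaussian copula).
    rho = config.elevation_correlation
    g = rng.standard_normal(n)
    eps = rng.standard_normal((n, n_antigens))
    z = np.sqrt(rho) * g[:, None] + np.sqrt(1.0 - rho) * eps
    p = np.empty((n, n_antigens))
    for j, antigen in enumerate(antigens):
        p[true_cancer, j] = config.antigen_rates[("cancer", antigen)]
        p[~true_cancer, j] = config.antigen_rates[("control", antigen)]
    with np.errstate(divide="ignore"):
        thresholds = sps.norm.ppf(1.0 - p)
    elevated = z > thresholds

    # Reference-level RU from the selected mixture component.
    mu = np.empty((n, n_antigens))
    sd = np.empty((n, n_antigens))
    for j, antigen in enumerate(antigens):
        b_mu, b_sd = config.background_ru[antigen]
        e_mu, e_sd = config.elevated_ru[antigen]
        mu[:, j] = np.where(elevated[:, j], e_mu, b_mu)
        sd[:, j] = np.where(elevated[:, j], e_sd, b_sd)
    ru_ref = np.exp(mu + sd * rng.standard_normal((n, n_antigens)))

    # Titration: elevated series decay geometrically below the reference
    # level; background series are flat.  Noise only off the reference level
    # so the reference-RU marginal stays exactly the mixture draw.
    series = np.empty((n, n_antigens, k))
    series[:, :, k - 1] = ru_ref
    retain = 1.0 - config.titration_decay
    for level in range(k - 1):
        steps_below = (k - 1) - level
        trend = np.where(elevated, retain**steps_below, 1.0)
        noise = np.exp(config.titration_noise_sd * rng.standard_normal((n, n_antigens)))
        series[:, :, level] = ru_ref * trend * noise

    # Demographics, independent of antigen status.
    ages = np.clip(np.rint(rng.normal(demo.age_mean, demo.age_sd, n)), demo.age_min, demo.age_max)
    genders = np.where(rng.random(n) < demo.male_fraction, "male", "female")
    smoking_states = ("current", "ex", "never", "unknown")
    smoking_probs = [demo.smoking_mix[s] for s in smoking_states]
    smoking = rng.choice(smoking_states, size=n, p=smoking_probs)
    years_current = np.clip(rng.normal(35.0, 10.0, n), 1.0, None)
    years_ex = np.clip(rng.normal(30.0, 10.0, n), 1.0, None)
    quit = np.clip(rng.normal(10.0, 8.0, n), 0.0, 40.0)

    if population == "cancer":
        subtypes = rng.choice(("NSCLC", "SCLC", "other"), size=n, p=(0.757, 0.226, 0.017))
        stages = rng.choice(("early", "late"), size=n, p=(0.5, 0.5))
    else:
        subtypes = np.full(n, "none")
        stages = np.full(n, "unknown")

    subjects: list[SubjectRecord] = []
    truth: dict[str, str] = {}
    for i, sid in enumerate(ids):
        smoke = str(smoking[i])
        if smoke == "current":
            s_years, q_years = round(float(years_current[i]), 1), None
        elif smoke == "ex":
            s_years, q_years = round(float(years_ex[i]), 1), round(float(quit[i]), 1)
        elif smoke == "never":
            s_years, q_years = 0.0, None
        else:
            s_years, q_years = None, None
        s_years = None if s_years is None else min(s_years, float(ages[i]) - 18.0)
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                cohort=population,
                cancer_status={"cancer": "confirmed", "control": "none", "at_risk": "unknown"}[population],
                subtype=str(subtypes[i]),
                stage_group=str(stages[i]),
                age=int(ages[i]),
                gender=str(genders[i]),
                smoking=smoke,
                smoking_years=s_years,
                quit_years=q_years,
            )
        )
        truth[sid] = "cancer" if true_cancer[i] else "none"

    measurements: dict[tuple[str, str], AntigenMeasurement] = {}
    levels = tuple(range(k))
    for i, sid in enumerate(ids):
        for j, antigen in enumerate(antigens):
            measurements[(sid, antigen)] = AntigenMeasurement(
                subject_id=sid,
                antigen=antigen,
                titration=tuple(zip(levels, series[i, j, :].tolist())),
            )
    return subjects, measurements, truth


def generate_cohort(config: CohortSimConfig) -> Cohort:
    """Generate a synthetic cohort; the config seed fully determines it.

    The returned cohort carries a truth table in its metadata (see
    :func:`truth_table`) flagging occult cancers seeded into the
    control/at-risk populations.
    """
    rng = np.random.default_rng(config.seed)
    subjects: list[SubjectRecord] = []
    measurements: dict[tuple[str, str], AntigenMeasurement] = {}
    truth: dict[str, str] = {}
    for population, prefix, n in (
        ("cancer", "C", config.n_cancer),
        ("control", "N", config.n_control),
        ("at_risk", "R", config.n_at_risk),
    ):
        block_subjects, block_measurements, block_truth = _sample_block(rng, config, population, prefix, n)
        subjects.extend(block_subjects)
        measurements.update(block_measurements)
        truth.update(block_truth)
    meta = {
        "synthetic": True,
        "seed": config.seed,
        "n_coat_levels": config.n_coat_levels,
        "occult_rate": config.occult_rate,
        "truth": truth,
    }
    return Cohort(subjects=subjects, measurements=measurements, meta=meta)


def truth_table(cohort: Cohort) -> dict[str, str]:
    """True disease status per subject ("cancer" or "none"), occult included.

    Only defined for generator output; raises for cohorts without simulation
    provenance, where true status beyond the recorded labels is unknowable.
    """
    if not cohort.meta.get("synthetic"):
        raise CohortValidationError("truth_table is only available for synthetic cohorts")
    return dict(cohort.meta["truth"])
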