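"""Domain types and delimited-text IO for serology cohorts and panels.

A cohort pairs a subjects table (demographics, smoking history, disease
status) with a measurements table (one titration series of calibrated
reference units, RU, per subject x antigen).  RU values are taken as already
calibrated; no optical-density conversion happens here.

Formats are plain comma-delimited UTF-8 with a header row; panel definitions
are YAML.  Row order on write is deterministic (subject_id, antigen, coat
level) so identical cohorts serialize byte-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

#: Canonical antigen codes.  SOX2-B and SOX2-N are the same protein with
#: different expression tags and are carried as distinct codes.
ANTIGENS: tuple[str, ...] = (
    "p53",
    "NY-ESO-1",
    "CAGE",
    "GBU4-5",
    "AnnexinI",
    "SOX2-B",
    "SOX2-N",
    "MAGEA4",
    "HuD",
)

#: Original six-antigen panel.
PANEL6_ANTIGENS: tuple[str, ...] = ("p53", "NY-ESO-1", "CAGE", "GBU4-5", "AnnexinI", "SOX2-N")
#: Updated seven-antigen panel (MAGE A4 and HuD in, Annexin I out, SOX2-B for SOX2-N).
PANEL7_ANTIGENS: tuple[str, ...] = ("p53", "NY-ESO-1", "CAGE", "GBU4-5", "MAGEA4", "SOX2-B", "HuD")

COHORTS = ("cancer", "control", "at_risk")
CANCER_STATUSES = ("confirmed", "none", "unknown")
SUBTYPES = ("NSCLC", "SCLC", "other", "none")
STAGE_GROUPS = ("early", "late", "unknown")
GENDERS = ("male", "female")
SMOKING = ("current", "ex", "never", "unknown")

SUBJECT_COLUMNS = [
    "subject_id",
    "cohort",
    "cancer_status",
    "subtype",
    "stage_group",
    "age",
    "gender",
    "smoking",
    "smoking_years",
    "quit_years",
]
MEASUREMENT_COLUMNS = ["subject_id", "antigen", "coat_level", "ru"]


class CohortValidationError(ValueError):
    """A cohort, panel, or input table violates a documented invariant."""


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise CohortValidationError(message)


@dataclass(frozen=True)
class SubjectRecord:
    """One person: demographics, smoking history, and disease status.

    ``stage_group`` groups stage I/II NSCLC and limited-disease SCLC as
    "early"; stage III/IV NSCLC and extensive-disease SCLC as "late".
    """

    subject_id: str
    cohort: str
    cancer_status: str
    subtype: str = "none"
    stage_group: str = "unknown"
    age: int = 60
    gender: str = "male"
    smoking: str = "unknown"
    smoking_years: float | None = None
    quit_years: float | None = None

    def __post_init__(self) -> None:
        sid = self.subject_id
        _require(bool(sid), "subject_id must be non-empty")
        _require(self.cohort in COHORTS, f"subject {sid}: cohort {self.cohort!r} not in {COHORTS}")
        _require(
            self.cancer_status in CANCER_STATUSES,
            f"subject {sid}: cancer_status {self.cancer_status!r} not in {CANCER_STATUSES}",
        )
        _require(self.subtype in SUBTYPES, f"subject {sid}: subtype {self.subtype!r} not in {SUBTYPES}")
        _require(
            self.stage_group in STAGE_GROUPS,
            f"subject {sid}: stage_group {self.stage_group!r} not in {STAGE_GROUPS}",
        )
        _require(self.gender in GENDERS, f"subject {sid}: gender {self.gender!r} not in {GENDERS}")
        _require(self.smoking in SMOKING, f"subject {sid}: smoking {self.smoking!r} not in {SMOKING}")
        _require(int(self.age) == self.age and self.age >= 18, f"subject {sid}: age must be an integer >= 18")
        for name in ("smoking_years", "quit_years"):
            value = getattr(self, name)
            if value is not None:
                _require(value >= 0, f"subject {sid}: {name} must be >= 0")
        if self.cohort == "cancer":
            _require(
                self.cancer_status == "confirmed" and self.subtype != "none",
                f"subject {sid}: cancer-cohort subjects need confirmed status and a subtype",
            )
        elif self.cohort == "control":
            _require(
                self.cancer_status == "none",
                f"subject {sid}: control-cohort subjects must have cancer_status 'none'",
            )


@dataclass(frozen=True)
class AntigenMeasurement:
    """One subject x antigen titration series of calibrated RU values.

    ``titration`` is ordered by coat level; higher coat level means more
    antigen on the plate, so a genuine autoantibody signal rises with coat
    level.  ``reference_index`` designates the coat level whose RU is scored
    against the cutoff (default: the highest coat level).
    """

    subject_id: str
    antigen: str
    titration: tuple[tuple[int, float], ...]
    reference_index: int = -1

    def __post_init__(self) -> None:
        _require(self.antigen in ANTIGENS, f"unknown antigen {self.antigen!r} for subject {self.subject_id}")
        tit = tuple((int(level), float(ru)) for level, ru in self.titration)
        object.__setattr__(self, "titration", tit)
        _require(len(tit) > 0, f"{self.subject_id}/{self.antigen}: titration must be non-empty")
        levels = [level for level, _ in tit]
        _require(
            all(b > a for a, b in zip(levels, levels[1:])),
            f"{self.subject_id}/{self.antigen}: coat levels must be strictly increasing",
        )
        _require(
            all(ru >= 0 and math.isfinite(ru) for _, ru in tit),
            f"{self.subject_id}/{self.antigen}: RU values must be finite and >= 0",
        )
        ref = self.reference_index if self.reference_index >= 0 else len(tit) + self.reference_index
        _require(0 <= ref < len(tit), f"{self.subject_id}/{self.antigen}: reference_index out of range")
        object.__setattr__(self, "reference_index", ref)

    @property
    def ru_reference(self) -> float:
        """RU at the designated reference coat level."""
        return self.titration[self.reference_index][1]

    @property
    def ru_values(self) -> tuple[float, ...]:
        return tuple(ru for _, ru in self.titration)


@dataclass(frozen=True)
class PanelDefinition:
    """Ordered antigen list with one RU cutoff per antigen.

    A subject is panel-positive when any single antigen is positive (the
    any-positive OR rule); per-antigen positivity additionally requires dose
    response when ``dose_response_required``.
    """

    name: str
    antigens: tuple[str, ...]
    cutoffs: Mapping[str, float]
    dose_response_required: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "antigens", tuple(self.antigens))
        object.__setattr__(self, "cutoffs", dict(self.cutoffs))
        _require(len(self.antigens) > 0, f"panel {self.name!r}: empty antigen list")
        _require(
            len(set(self.antigens)) == len(self.antigens),
            f"panel {self.name!r}: duplicate antigen entry",
        )
        for antigen in self.antigens:
            _require(antigen in ANTIGENS, f"panel {self.name!r}: unknown antigen {antigen!r}")
            _require(antigen in self.cutoffs, f"panel {self.name!r}: antigen {antigen!r} missing a cutoff")
        extra = set(self.cutoffs) - set(self.antigens)
        _require(not extra, f"panel {self.name!r}: cutoffs for antigens not in panel: {sorted(extra)}")
        for antigen, cutoff in self.cutoffs.items():
            _require(cutoff > 0, f"panel {self.name!r}: cutoff for {antigen} must be > 0")

    def with_cutoffs(self, cutoffs: Mapping[str, float]) -> "PanelDefinition":
        return replace(self, cutoffs=dict(cutoffs))


@dataclass
class Cohort:
    """Subjects plus their per-antigen titration measurements."""

    subjects: list[SubjectRecord]
    measurements: dict[tuple[str, str], AntigenMeasurement]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        _require(len(set(ids)) == len(ids), "duplicate subject_id in cohort")
        known = set(ids)
        for (sid, antigen), m in self.measurements.items():
            _require(sid in known, f"measurement for unknown subject {sid!r}")
            _require(
                (m.subject_id, m.antigen) == (sid, antigen),
                f"measurement key mismatch for {sid}/{antigen}",
            )

    def __len__(self) -> int:
        return len(self.subjects)

    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    def measurement(self, subject_id: str, antigen: str) -> AntigenMeasurement:
        try:
            return self.measurements[(subject_id, antigen)]
        except KeyError:
            raise CohortValidationError(
                f"missing measurement for subject {subject_id!r}, antigen {antigen!r}"
            ) from None

    def subset(self, subject_ids: Iterable[str]) -> "Cohort":
        keep = set(subject_ids)
        subjects = [s for s in self.subjects if s.subject_id in keep]
        measurements = {k: v for k, v in self.measurements.items() if k[0] in keep}
        meta = dict(self.meta)
        if "truth" in meta:
            meta["truth"] = {sid: st for sid, st in meta["truth"].items() if sid in keep}
        return Cohort(subjects=subjects, measurements=measurements, meta=meta)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return self.subjects == other.subjects and self.measurements == other.measurements


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def read_cohort(subjects_path: str | Path, measurements_path: str | Path) -> Cohort:
    """Read and validate a cohort from its two CSV tables.

    Raises :class:`CohortValidationError` naming the offending row and field
    for missing columns, unknown antigens, duplicate (subject, antigen, coat
    level) rows, or non-numeric / negative RU values.
    """
    subjects_df = pd.read_csv(subjects_path, dtype={"subject_id": str}, float_precision="round_trip")
    measurements_df = pd.read_csv(
        measurements_path, dtype={"subject_id": str, "antigen": str}, float_precision="round_trip"
    )

    missing = [c for c in SUBJECT_COLUMNS if c not in subjects_df.columns]
    _require(not missing, f"{subjects_path}: missing columns {missing}")
    missing = [c for c in MEASUREMENT_COLUMNS if c not in measurements_df.columns]
    _require(not missing, f"{measurements_path}: missing columns {missing}")

    subjects = []
    for i, row in enumerate(subjects_df.itertuples(index=False), start=2):
        try:
            subjects.append(
                SubjectRecord(
                    subject_id=row.subject_id,
                    cohort=row.cohort,
                    cancer_status=row.cancer_status,
                    subtype=row.subtype,
                    stage_group=row.stage_group,
                    age=int(row.age),
                    gender=row.gender,
                    smoking=row.smoking,
                    smoking_years=_opt_float(row.smoking_years),
                    quit_years=_opt_float(row.quit_years),
                )
            )
        except (CohortValidationError, ValueError) as exc:
            raise CohortValidationError(f"{subjects_path} row {i}: {exc}") from None

    dupes = measurements_df.duplicated(subset=["subject_id", "antigen", "coat_level"])
    if dupes.any():
        first = int(dupes.idxmax()) + 2
        raise CohortValidationError(
            f"{measurements_path} row {first}: duplicate (subject_id, antigen, coat_level)"
        )
    ru_numeric = pd.to_numeric(measurements_df["ru"], errors="coerce")
    if ru_numeric.isna().any():
        first = int(ru_numeric.isna().idxmax()) + 2
        raise CohortValidationError(f"{measurements_path} row {first}: field 'ru' is not numeric")
    negative = ru_numeric < 0
    if negative.any():
        first = int(negative.idxmax()) + 2
        raise CohortValidationError(f"{measurements_path} row {first}: field 'ru' is negative")
    measurements_df = measurements_df.assign(ru=ru_numeric)

    measurements: dict[tuple[str, str], AntigenMeasurement] = {}
    grouped = measurements_df.sort_values(["subject_id", "antigen", "coat_level"]).groupby(
        ["subject_id", "antigen"], sort=False
    )
    for (sid, antigen), grp in grouped:
        try:
            measurements[(sid, antigen)] = AntigenMeasurement(
                subject_id=sid,
                antigen=antigen,
                titration=tuple(zip(grp["coat_level"].astype(int), grp["ru"].astype(float))),
            )
        except CohortValidationError as exc:
            raise CohortValidationError(f"{measurements_path}: {exc}") from None

    return Cohort(subjects=subjects, measurements=measurements)


def write_cohort(cohort: Cohort, subjects_path: str | Path, measurements_path: str | Path) -> None:
    """Write a cohort to its two CSV tables with deterministic row order."""
    subject_rows = sorted(
        (
            {
                "subject_id": s.subject_id,
                "cohort": s.cohort,
                "cancer_status": s.cancer_status,
                "subtype": s.subtype,
                "stage_group": s.stage_group,
                "age": s.age,
                "gender": s.gender,
                "smoking": s.smoking,
                "smoking_years": s.smoking_years,
                "quit_years": s.quit_years,
            }
            for s in cohort.subjects
        ),
        key=lambda r: r["subject_id"],
    )
    pd.DataFrame(subject_rows, columns=SUBJECT_COLUMNS).to_csv(subjects_path, index=False)

    measurement_rows = []
    for (sid, antigen) in sorted(cohort.measurements):
        for level, ru in cohort.measurements[(sid, antigen)].titration:
            measurement_rows.append(
                {"subject_id": sid, "antigen": antigen, "coat_level": level, "ru": repr(float(ru))}
            )
    pd.DataFrame(measurement_rows, columns=MEASUREMENT_COLUMNS).to_csv(measurements_path, index=False)


def read_panel(path: str | Path) -> PanelDefinition:
    """Read a panel definition from a YAML document."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    _require(isinstance(doc, dict), f"{path}: panel file must be a mapping")
    for key in ("name", "antigens", "cutoffs"):
        _require(key in doc, f"{path}: panel file missing key {key!r}")
    return PanelDefinition(
        name=str(doc["name"]),
        antigens=tuple(doc["antigens"]),
        cutoffs={str(a): float(c) for a, c in doc["cutoffs"].items()},
        dose_response_required=bool(doc.get("dose_response_required", True)),
    )


def write_panel(panel: PanelDefinition, path: str | Path) -> None:
    doc = {
        "name": panel.name,
        "dose_response_required": panel.dose_response_required,
        "antigens": list(panel.antigens),
        "cutoffs": {a: float(panel.cutoffs[a]) for a in panel.antigens},
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
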